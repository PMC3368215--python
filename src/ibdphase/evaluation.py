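"""Accuracy metrics: switch errors, yield, IBD sensitivity/FDR, imputation.

Conventions
-----------
* A *switch error* is a flip of the relative orientation between
  consecutive phased heterozygous sites, compared against truth; the rate
  is normalized per Morgan of chromosome and per individual, and is
  invariant to flipping any individual's entire haplotype pair.
* IBD sensitivity and false discovery rate are computed over
  (pair, marker) cells weighted by local genetic length; truth segments
  shorter than a floor (default 1 cM) are excluded from the sensitivity
  denominator.  The headline numbers ignore the haplotype configuration
  (pair-level overlap); a configuration-resolved variant is also reported.
* Imputation error counts discordances at fully imputed masked genotypes
  only; allele yield counts imputed alleles over all masked alleles.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .io import MISSING, GeneticMap, GenotypeMatrix
from .phaser import IBDSegmentCall, PhaseResult

__all__ = [
    "MetricsReport",
    "switch_error",
    "phasing_yield",
    "ibd_metrics",
    "imputation_metrics",
    "trio_truth_phase",
]


@dataclass
class MetricsReport:
    """Flat bundle of the evaluation metrics for one run/replicate."""

    switch_errors_per_morgan: float = float("nan")
    within_segment_errors_per_morgan: float = float("nan")
    yield_fraction: float = float("nan")
    imputation_error: float = float("nan")
    allele_yield: float = float("nan")
    ibd_sensitivity: float = float("nan")
    ibd_fdr: float = float("nan")
    ibd_sensitivity_resolved: float = float("nan")
    ibd_fdr_resolved: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v:.6g}\n")


def _orientation(diplo_site: np.ndarray) -> int:
    """1 if the minor allele sits on haplotype 1, else 0."""
    return int(diplo_site[0] == 1)


def switch_error(
    truth_haps: np.ndarray,
    phase: PhaseResult,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
) -> tuple[float, float, np.ndarray]:
    """Mean switch errors per Morgan at sites where a phase was called.

    Walks, per individual, the observed heterozygous sites with an ordered
    phase call that are also heterozygous in truth, and counts flips of the
    relative orientation versus truth.  The rate divides total switches by
    (number of individuals x chromosome genetic length).  The
    within-segment variant resets the comparison whenever an intervening
    heterozygous site was left unphased, so refusals do not contribute.

    Returns
    -------
    (rate, within_segment_rate, per_individual_switches)
    """
    n, m, _ = truth_haps.shape
    L = gmap.length_morgans
    het_obs = geno.dosages == 1
    het_truth = truth_haps.sum(axis=2) == 1
    called = phase.phased & het_obs & het_truth
    unphased_het = het_obs & ~phase.phased
    switches = np.zeros(n)
    within = 0.0
    for i in range(n):
        jj = np.nonzero(called[i])[0]
        if len(jj) < 2:
            continue
        rel = (phase.diplotypes[i, jj, 0] == 1) ^ (truth_haps[i, jj, 0] == 1)
        flips = rel[1:] != rel[:-1]
        switches[i] = flips.sum()
        # a comparison is "within a phased segment" when no unphased het
        # lies between the two sites
        cum_unph = np.concatenate([[0], np.cumsum(unphased_het[i])])
        gap_clean = cum_unph[jj[1:]] == cum_unph[jj[:-1] + 1]
        within += (flips & gap_clean).sum()
    rate = switches.sum() / (n * L)
    return float(rate), float(within / (n * L)), switches


def phasing_yield(phase: PhaseResult, geno: GenotypeMatrix) -> float:
    """Fraction of observed heterozygous sites with an ordered phase call."""
    het = geno.dosages == 1
    total = int(het.sum())
    if total == 0:
        return float("nan")
    return float((het & phase.phased).sum() / total)


def _truth_marker_masks(
    truth_intervals: dict[tuple[int, int], list],
    pairs: list[tuple[int, int]],
    m: int,
    weights: np.ndarray,
    min_truth_length: float,
    gmap: GeneticMap,
) -> tuple[dict, dict]:
    """Per-pair truth masks: all truth cells, and cells of truth intervals
    at least ``min_truth_length`` Morgans long."""
    all_mask: dict[tuple[int, int], np.ndarray] = {}
    long_mask: dict[tuple[int, int], np.ndarray] = {}
    for pr in pairs:
        am = np.zeros(m, dtype=bool)
        lm = np.zeros(m, dtype=bool)
        for (i, j, s, e, *_rest) in truth_intervals.get(pr, []):
            am[s:e] = True
            if gmap.morgans[e - 1] - gmap.morgans[s] >= min_truth_length:
                lm[s:e] = True
        all_mask[pr] = am
        long_mask[pr] = lm
    return all_mask, long_mask


def ibd_metrics(
    calls: list[IBDSegmentCall],
    truth_intervals: dict[tuple[int, int], list],
    gmap: GeneticMap,
    min_truth_length_cm: float = 1.0,
    resolved: bool = True,
) -> dict:
    """Marker-length-weighted IBD sensitivity and false discovery rate.

    Parameters
    ----------
    truth_intervals : mapping (a, b) with a < b to lists of
        ``(hap_a, hap_b, start, end, ...)`` truth tuples in marker
        coordinates (half-open).
    min_truth_length_cm : truth segments shorter than this are excluded
        from the sensitivity denominator (they remain valid overlap for
        the FDR).

    Returns
    -------
    dict with ``sensitivity``, ``fdr`` (pair-level overlap, configuration
    ignored) and ``sensitivity_resolved``, ``fdr_resolved`` (haplotype
    configuration must match).  Empty calls give sensitivity 0 and NaN
    FDR.
    """
    m = gmap.n_markers
    w = gmap.marker_weights()
    min_len = min_truth_length_cm / 100.0
    pairs = sorted(set(truth_intervals.keys()) | {(c.a, c.b) for c in calls})
    all_mask, long_mask = _truth_marker_masks(
        truth_intervals, pairs, m, w, min_len, gmap
    )
    call_mask: dict[tuple[int, int], np.ndarray] = {
        pr: np.zeros(m, dtype=bool) for pr in pairs
    }
    # configuration-resolved masks: 4 slots per pair
    if resolved:
        truth_cfg: dict = {pr: np.zeros((2, 2, m), dtype=bool) for pr in pairs}
        call_cfg: dict = {pr: np.zeros((2, 2, m), dtype=bool) for pr in pairs}
        truth_cfg_long: dict = {pr: np.zeros((2, 2, m), dtype=bool) for pr in pairs}
        for pr in pairs:
            for (i, j, s, e, *_rest) in truth_intervals.get(pr, []):
                truth_cfg[pr][i - 1, j - 1, s:e] = True
                if gmap.morgans[e - 1] - gmap.morgans[s] >= min_len:
                    truth_cfg_long[pr][i - 1, j - 1, s:e] = True
    for c in calls:
        pr = (c.a, c.b)
        call_mask[pr][c.start : c.end] = True
        if resolved:
            call_cfg[pr][c.hap_a - 1, c.hap_b - 1, c.start : c.end] = True

    truth_len = covered_len = called_len = false_len = 0.0
    t_len_r = cov_r = call_r = false_r = 0.0
    for pr in pairs:
        tl = long_mask[pr]
        cm_ = call_mask[pr]
        truth_len += w[tl].sum()
        covered_len += w[tl & cm_].sum()
        called_len += w[cm_].sum()
        false_len += w[cm_ & ~all_mask[pr]].sum()
        if resolved:
            tc, cc, tcl = truth_cfg[pr], call_cfg[pr], truth_cfg_long[pr]
            t_len_r += (tcl * w).sum()
            cov_r += ((tcl & cc) * w).sum()
            call_r += (cc * w).sum()
            false_r += ((cc & ~tc) * w).sum()
    sens = covered_len / truth_len if truth_len > 0 else float("nan")
    fdr = false_len / called_len if called_len > 0 else float("nan")
    sens_r = cov_r / t_len_r if t_len_r > 0 else float("nan")
    fdr_r = false_r / call_r if call_r > 0 else float("nan")
    return {
        "sensitivity": float(sens) if truth_len > 0 else float("nan"),
        "fdr": float(fdr),
        "sensitivity_resolved": float(sens_r),
        "fdr_resolved": float(fdr_r),
    }


def imputation_metrics(
    masked_truth: np.ndarray,
    phase: PhaseResult,
    mask: np.ndarray,
) -> tuple[float, float]:
    """Imputation error over fully imputed masked genotypes + allele yield.

    Parameters
    ----------
    masked_truth : (n, m) dosages hidden before phasing (the pre-mask
        observed genotypes).
    mask : (n, m) boolean, the hidden cells.

    Returns
    -------
    (imputation_error, allele_yield) : the error is NaN when nothing was
    fully imputed; a half-imputed genotype is excluded from the error
    denominator but its called allele still counts toward the yield.
    """
    n_masked = int(mask.sum())
    if n_masked == 0:
        return float("nan"), 0.0
    imput_count = phase.imputed.sum(axis=2)
    full = mask & (imput_count == 2)
    allele_yield = float(phase.imputed[mask].sum() / (2.0 * n_masked))
    if not np.any(full):
        return float("nan"), allele_yield
    called_dos = phase.diplotypes[..., 0].astype(int) + phase.diplotypes[..., 1]
    errors = int((called_dos[full] != masked_truth[full]).sum())
    return errors / int(full.sum()), allele_yield


def trio_truth_phase(
    offspring: np.ndarray,
    father: np.ndarray,
    mother: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Partial truth haplotypes of an offspring from genotyped parents.

    At sites where the offspring is heterozygous and at least one parent
    is homozygous, the offspring allele matching the homozygous parent is
    assigned to that parent's haplotype (haplotype 1 paternal, haplotype 2
    maternal).  Mendelian-inconsistent sites are excluded and counted.

    Returns
    -------
    ((m, 2) partial haplotypes with -1 where unresolved, n_mendel_errors)
    """
    m = offspring.shape[0]
    haps = np.full((m, 2), MISSING, dtype=np.int8)
    mendel = 0
    for j in range(m):
        o, fa, mo = int(offspring[j]), int(father[j]), int(mother[j])
        if o == MISSING:
            continue
        # Mendelian check on homozygous parents
        for par in (fa, mo):
            if par == 0 and o == 2 or par == 2 and o == 0:
                mendel += 1
                break
        else:
            if o != 1:
                continue
            if fa in (0, 2) and mo in (0, 2):
                if fa == mo:  # both hom same allele cannot yield a het
                    mendel += 1
                    continue
                haps[j, 0] = fa // 2
                haps[j, 1] = mo // 2
            elif fa in (0, 2):
                haps[j, 0] = fa // 2
                haps[j, 1] = 1 - fa // 2
            elif mo in (0, 2):
                haps[j, 1] = mo // 2
                haps[j, 0] = 1 - mo // 2
    return haps, mendel
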