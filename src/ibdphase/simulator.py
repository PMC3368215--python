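"""Founder-population simulator with full truth tracking.

Generates genotype data emulating an isolated founder population: a small
founder set grows exponentially under random mating, gametes recombine
according to a genetic map (Haldane model: Poisson crossover counts, no
interference), and alleles are transmitted without mutation.  Every sampled
haplotype is stored as an ancestry mosaic — an ordered list of breakpoints
on the genetic scale with a founder-haplotype label per piece — from which
genotypes, true phase and true IBD relationships are all derived.

Founder haplotypes are synthetic: alleles drawn independently per site from
a minor-allele-frequency spectrum.  Long-range IBD structure, which is what
drives IBD-based phasing, is created by the simulated generations rather
than by founder linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GeneticMap, GenotypeMatrix

__all__ = [
    "DemographyConfig",
    "AncestryMosaic",
    "default_map",
    "make_founder_haplotypes",
    "evolve",
    "realize_genotypes",
    "true_ibd",
    "all_true_ibd",
    "add_noise",
    "simulate_cohort",
    "SimulatedCohort",
]


@dataclass
class DemographyConfig:
    """Exponential-growth demography of the simulated founder population.

    Defaults follow the canonical scenario: 100 founders growing to 18,000
    in 12 generations, with 190 individuals sampled from the final
    generation.
    """

    n_founders: int = 100
    final_size: int = 18_000
    generations: int = 12
    sample_size: int = 190

    @property
    def growth(self) -> float:
        """Per-generation census multiplier."""
        if self.generations == 0:
            return 1.0
        return (self.final_size / self.n_founders) ** (1.0 / self.generations)

    def census(self) -> list[int]:
        """Population size at each generation 0..generations."""
        return [
            int(round(self.n_founders * self.growth**k))
            for k in range(self.generations + 1)
        ]

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.final_size < self.n_founders:
            raise ValueError("need >= 2 founders and final_size >= n_founders")
        if self.generations == 0 and self.final_size != self.n_founders:
            raise ValueError("zero generations requires final_size == n_founders")
        if self.sample_size > self.final_size:
            raise ValueError("cannot sample more individuals than the final census")


@dataclass
class AncestryMosaic:
    """One haplotype as a tiling of founder-haplotype pieces.

    ``breaks`` holds the right edge of every piece on the genetic scale
    (Morgans), ending exactly at the chromosome length; ``labels[k]`` is
    the founder haplotype (in ``[0, 2*n_founders)``) carried on
    ``[breaks[k-1], breaks[k])``.
    """

    breaks: np.ndarray
    labels: np.ndarray

    def labels_at(self, positions: np.ndarray) -> np.ndarray:
        """Founder label at each genetic position (vectorized lookup)."""
        idx = np.searchsorted(self.breaks, positions, side="right")
        idx = np.minimum(idx, len(self.labels) - 1)
        return self.labels[idx]


def default_map(
    m: int = 7505,
    length_morgans: float = 1.09,
    chrom: str = "20",
    seed: int = 0,
    bp_per_morgan: float = 62e6 / 1.09,
) -> GeneticMap:
    """Synthetic single-chromosome genetic map.

    Mimics a dense genotyping array on a ~1 Morgan chromosome: marker bp
    positions are uniform draws, and the cM/Mb recombination rate varies
    piecewise along the chromosome (hot and cold stretches) so inter-marker
    genetic distances are non-constant.  Defaults give 7,505 markers over
    1.09 Morgans (~62 Mbp), a density of ~6,885 markers per Morgan.
    """
    rng = np.random.default_rng(seed)
    total_bp = int(round(length_morgans * bp_per_morgan))
    bp = np.sort(rng.choice(np.arange(1, total_bp), size=m, replace=False))
    # piecewise-variable recombination density over ~50 blocks
    n_blocks = 50
    edges = np.linspace(0, total_bp, n_blocks + 1)
    rates = rng.gamma(shape=0.8, scale=1.0, size=n_blocks) + 0.05
    # cumulative genetic position at every block edge, scaled to total length
    block_g = rates * np.diff(edges)
    cum_edges = np.concatenate([[0.0], np.cumsum(block_g)])
    cum_edges *= length_morgans / cum_edges[-1]
    morgans = np.interp(bp, edges, cum_edges)
    morgans -= morgans[0]
    return GeneticMap(chrom, bp, morgans)


def make_founder_haplotypes(
    m: int,
    n_founders: int,
    freq_spec=("uniform", 0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw founder haplotypes from a site-frequency spectrum.

    Site minor-allele frequencies come from ``freq_spec`` (``("uniform",
    lo, hi)`` or ``("constant", f)``); alleles are drawn independently per
    founder haplotype per site.

    Returns
    -------
    (haps, freqs) : (2*n_founders, m) 0/1 alleles and the (m,) site
    frequencies the alleles were drawn from.
    """
    if m < 2:
        raise ValueError("need at least 2 markers")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kind = freq_spec[0]
    if kind == "uniform":
        lo, hi = freq_spec[1], freq_spec[2]
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("uniform frequency bounds must lie in (0, 1)")
        freqs = rng.uniform(lo, hi, size=m)
    elif kind == "constant":
        f = float(freq_spec[1])
        if not (0.0 < f < 1.0):
            raise ValueError("constant frequency must lie in (0, 1)")
        freqs = np.full(m, f)
    else:
        raise ValueError(f"unknown frequency spec {kind!r}")
    haps = (rng.random((2 * n_founders, m)) < freqs).astype(np.int8)
    return haps, freqs


def _meiosis(
    parent: tuple[AncestryMosaic, AncestryMosaic],
    length: float,
    rng: np.random.Generator,
) -> AncestryMosaic:
    """One transmitted gamete: Poisson(length) crossovers placed uniformly
    on the genetic scale, alternating between the parent's two mosaics
    starting from a random one."""
    n_x = rng.poisson(length)
    start = rng.integers(2)
    if n_x == 0:
        src = parent[start]
        return AncestryMosaic(src.breaks.copy(), src.labels.copy())
    xs = np.sort(rng.random(n_x) * length)
    edges = np.concatenate([xs, [length]])
    breaks_out: list[float] = []
    labels_out: list[int] = []
    left = 0.0
    cur = start
    for right in edges:
        src = parent[cur]
        # pieces of src overlapping [left, right)
        i0 = int(np.searchsorted(src.breaks, left, side="right"))
        i0 = min(i0, len(src.labels) - 1)
        pos = left
        while pos < right:
            piece_end = min(src.breaks[i0], right)
            lab = int(src.labels[i0])
            if labels_out and labels_out[-1] == lab:
                breaks_out[-1] = piece_end
            else:
                breaks_out.append(piece_end)
                labels_out.append(lab)
            pos = piece_end
            i0 += 1
        left = right
        cur = 1 - cur
    breaks_out[-1] = length
    return AncestryMosaic(np.array(breaks_out), np.array(labels_out, dtype=np.int32))


def evolve(
    demography: DemographyConfig,
    gmap: GeneticMap,
    seed: int | np.random.Generator = 0,
) -> list[tuple[AncestryMosaic, AncestryMosaic]]:
    """Run the forward-in-time demography and return the sampled mosaics.

    Each generation every offspring draws two distinct uniform-random
    parents from the previous generation and receives one recombinant
    gamete from each; the final generation is sampled without replacement
    down to ``sample_size`` individuals.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = gmap.length_morgans
    census = demography.census()
    pop = [
        (
            AncestryMosaic(np.array([L]), np.array([2 * i], dtype=np.int32)),
            AncestryMosaic(np.array([L]), np.array([2 * i + 1], dtype=np.int32)),
        )
        for i in range(demography.n_founders)
    ]
    for size in census[1:]:
        prev = pop
        n_prev = len(prev)
        pop = []
        for _ in range(size):
            i, j = rng.choice(n_prev, size=2, replace=False)
            pop.append(
                (_meiosis(prev[i], L, rng), _meiosis(prev[j], L, rng))
            )
    idx = rng.choice(len(pop), size=demography.sample_size, replace=False)
    return [pop[i] for i in idx]


def realize_genotypes(
    mosaics: list[tuple[AncestryMosaic, AncestryMosaic]],
    founder_haps: np.ndarray,
    gmap: GeneticMap,
    drop_monomorphic: bool = True,
) -> tuple[np.ndarray, GenotypeMatrix, GeneticMap, np.ndarray]:
    """Materialize alleles and genotypes from ancestry mosaics.

    Each marker's allele is copied from the founder haplotype whose mosaic
    piece covers the marker's genetic position.  Markers monomorphic in the
    sample (drift) are dropped from genotypes, truth and map alike.

    Returns
    -------
    (truth_haps, genotypes, gmap, kept) : (n, m, 2) truth alleles aligned
    to the emitted matrix, the genotype matrix (minor-allele oriented), the
    matching map, and the retained-marker mask on the input marker set.
    """
    n = len(mosaics)
    pos = gmap.morgans - gmap.morgans[0]
    labels = np.empty((n, 2, gmap.n_markers), dtype=np.int32)
    for i, (h1, h2) in enumerate(mosaics):
        labels[i, 0] = h1.labels_at(pos)
        labels[i, 1] = h2.labels_at(pos)
    alleles = founder_haps[labels, np.arange(gmap.n_markers)]  # (n, 2, m)
    dosages = alleles.sum(axis=1).astype(np.int8)
    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    geno, kept = GenotypeMatrix.from_raw_dosages(
        sample_ids, gmap.marker_ids, dosages, drop_monomorphic=drop_monomorphic
    )
    # orient truth alleles to the minor allele like the genotype matrix
    # (no missing data here, so the flip rule is simply sample frequency > 0.5)
    alleles = alleles[:, :, kept]
    raw_f = dosages[:, kept].sum(axis=0) / (2.0 * n)
    flip_cols = raw_f > 0.5
    alleles[:, :, flip_cols] = 1 - alleles[:, :, flip_cols]
    truth = np.transpose(alleles, (0, 2, 1)).astype(np.int8)  # (n, m, 2)
    return truth, geno, gmap.subset(kept), kept


def true_ibd(
    mosaics: list[tuple[AncestryMosaic, AncestryMosaic]],
    pair: tuple[int, int],
    gmap: GeneticMap,
) -> list[tuple[int, int, int, int, int]]:
    """Truth IBD intervals for one pair, in marker coordinates.

    For each of the four haplotype pairings, returns maximal marker runs on
    which both haplotypes carry the same founder label (a label-changing
    breakpoint ends a run; crossovers that rejoin the same label do not).

    Returns
    -------
    list of ``(i, j, start, end, n_markers)`` tuples with ``i, j`` in
    {1, 2} and ``[start, end)`` half-open marker indices.
    """
    a, b = pair
    pos = gmap.morgans - gmap.morgans[0]
    out = []
    for i in (0, 1):
        la = mosaics[a][i].labels_at(pos)
        for j in (0, 1):
            lb = mosaics[b][j].labels_at(pos)
            out.extend(_label_runs(la, lb, i, j))
    return out


def _label_runs(la: np.ndarray, lb: np.ndarray, i: int, j: int) -> list:
    """Maximal runs of shared, breakpoint-free founder labels (vectorized)."""
    m = la.shape[0]
    eq = la == lb
    # marker k continues the run at k-1 iff both equal and neither label moved
    cont = eq[1:] & eq[:-1] & (np.diff(la) == 0) & (np.diff(lb) == 0)
    newrun = np.empty(m, dtype=bool)
    newrun[0] = True
    newrun[1:] = ~cont
    bounds = np.concatenate([np.nonzero(newrun)[0], [m]])
    rid = np.cumsum(newrun) - 1
    starts = np.nonzero(newrun & eq)[0]
    return [
        (i + 1, j + 1, int(s), int(bounds[rid[s] + 1]), int(bounds[rid[s] + 1] - s))
        for s in starts
    ]


def all_true_ibd(
    mosaics: list[tuple[AncestryMosaic, AncestryMosaic]],
    gmap: GeneticMap,
    min_markers: int = 1,
) -> dict[tuple[int, int], list]:
    """Truth IBD intervals for every unordered pair, keyed by (a, b).

    Founder labels are materialized once per haplotype, so the pairwise
    comparison is a cheap vectorized scan.  Runs shorter than
    ``min_markers`` markers are omitted.
    """
    n = len(mosaics)
    pos = gmap.morgans - gmap.morgans[0]
    labels = np.empty((n, 2, gmap.n_markers), dtype=np.int32)
    for idx, (h1, h2) in enumerate(mosaics):
        labels[idx, 0] = h1.labels_at(pos)
        labels[idx, 1] = h2.labels_at(pos)
    out: dict[tuple[int, int], list] = {}
    for a in range(n):
        for b in range(a + 1, n):
            runs = []
            for i in (0, 1):
                for j in (0, 1):
                    runs.extend(
                        r
                        for r in _label_runs(labels[a, i], labels[b, j], i, j)
                        if r[4] >= min_markers
                    )
            if runs:
                out[(a, b)] = runs
    return out


def add_noise(
    geno: GenotypeMatrix,
    missing_rate: float = 0.0,
    error_rate: float | np.ndarray = 0.0,
    seed: int | np.random.Generator = 0,
    two_tier: tuple[float, float, float] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Degrade genotypes with random missingness and genotyping errors.

    Errors replace a genotype with one of the two other dosages uniformly.
    ``error_rate`` may be a scalar or a per-marker vector; alternatively
    ``two_tier=(p_bad, rate_bad, rate_good)`` assigns a fraction ``p_bad``
    of markers a high error rate and the rest a low one (e.g. 20% of
    markers at 10% and 80% at 0.1%).

    Returns
    -------
    (degraded, missing_mask, error_mask) : masks mark the perturbed cells.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, m = geno.dosages.shape
    if two_tier is not None:
        p_bad, r_bad, r_good = two_tier
        bad = rng.random(m) < p_bad
        error_rate = np.where(bad, r_bad, r_good)
    rate = np.broadcast_to(np.asarray(error_rate, dtype=float), (m,))
    if missing_rate < 0 or missing_rate > 1 or np.any(rate < 0) or np.any(rate > 1):
        raise ValueError("rates must lie in [0, 1]")
    dosages = geno.dosages.copy()
    observed = dosages != MISSING
    err_mask = observed & (rng.random((n, m)) < rate[None, :])
    if np.any(err_mask):
        shift = rng.integers(1, 3, size=int(err_mask.sum()))
        dosages[err_mask] = ((dosages[err_mask] + shift) % 3).astype(np.int8)
    miss_mask = observed & (rng.random((n, m)) < missing_rate)
    dosages[miss_mask] = MISSING
    out = GenotypeMatrix(geno.sample_ids, geno.marker_ids, dosages, geno.freqs)
    return out, miss_mask, err_mask


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation replicate produces."""

    genotypes: GenotypeMatrix
    gmap: GeneticMap
    truth_haps: np.ndarray  # (n, m, 2) minor-allele-oriented truth alleles
    mosaics: list
    demography: DemographyConfig

    def truth_ibd_pair(self, a: int, b: int):
        return true_ibd(self.mosaics, (a, b), self.gmap)


def simulate_cohort(
    demography: DemographyConfig | None = None,
    gmap: GeneticMap | None = None,
    freq_spec=("uniform", 0.05, 0.5),
    seed: int = 0,
) -> SimulatedCohort:
    """Run one full replicate: founders -> demography -> genotypes + truth."""
    demography = demography or DemographyConfig()
    rng = np.random.default_rng(seed)
    gmap = gmap if gmap is not None else default_map(seed=seed)
    founders, _ = make_founder_haplotypes(
        gmap.n_markers, demography.n_founders, freq_spec, rng
    )
    mosaics = evolve(demography, gmap, rng)
    truth, geno, gmap_kept, _ = realize_genotypes(mosaics, founders, gmap)
    return SimulatedCohort(geno, gmap_kept, truth, mosaics, demography)
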