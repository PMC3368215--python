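"""Forward-Backward prescan for plausible IBD segments.

Full message passing over every pair at every marker is prohibitively
expensive, so a scaled Forward-Backward pass is first run over the pair HMM
of every unordered pair of individuals; maximal marker runs whose combined
IBD posterior (the sum over the four one-haplotype-shared states) exceeds a
threshold are called *plausible IBD segments*, and the Min-Sum phase is
restricted to those.  The per-marker observation term marginalizes the
state emissions over all ordered diplotype pairs compatible with the
observed unordered genotypes, weighted by the genotype error model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GeneticMap, GenotypeMatrix
from .model_core import (
    ModelParams,
    N_STATES,
    build_rate_matrix,
    emission_table,
    genotype_likelihood_table,
    stationary_distribution,
    transition_matrix,
)

logger = logging.getLogger("ibdphase")

__all__ = ["PlausibleSegment", "pair_posteriors", "call_segments", "scan_all_pairs",
           "write_segments", "precompute_tables"]


@dataclass(frozen=True)
class PlausibleSegment:
    """Candidate IBD interval for a pair (a < b), half-open in markers."""

    a: int
    b: int
    start: int
    end: int
    peak_posterior: float
    genetic_length: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("segment marker interval must be nonempty")

    @property
    def n_markers(self) -> int:
        return self.end - self.start


def precompute_tables(
    gmap: GeneticMap, freqs: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared per-marker tables: transition matrices for every inter-marker
    interval, the emission table, and the initial distribution.

    Returns
    -------
    (trans, emit, pi) : (m-1, 5, 5) capped transition matrices,
    (m, 5, 4, 4) emissions, (5,) stationary initial distribution.
    """
    Q = build_rate_matrix(params)
    dts = gmap.intervals()
    if np.any(dts < 0):
        raise ValueError("genetic map positions must be nondecreasing")
    trans = np.empty((len(dts), N_STATES, N_STATES))
    # cache repeated interval lengths (common with rounded maps)
    cache: dict[float, np.ndarray] = {}
    for k, t in enumerate(dts):
        key = float(t)
        if key not in cache:
            cache[key] = transition_matrix(Q, key, params.kappa)
        trans[k] = cache[key]
    emit = emission_table(freqs)
    pi = stationary_distribution(params)
    return trans, emit, pi


def _obs_terms(
    geno_rows_a: np.ndarray,
    geno_rows_b: np.ndarray,
    emit: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Per-marker observation likelihood P(g_a, g_b | state) for a batch of
    pairs: emissions marginalized over compatible ordered diplotype pairs.

    Parameters
    ----------
    geno_rows_a, geno_rows_b : (p, m) dosage rows for p pairs.
    emit : (m, 5, 4, 4) emission table.

    Returns
    -------
    (p, m, 5) observation terms.
    """
    gla = genotype_likelihood_table(geno_rows_a, epsilon)  # (p, m, 4)
    glb = genotype_likelihood_table(geno_rows_b, epsilon)
    w = np.einsum("pjd,pje->pjde", gla, glb)
    return np.einsum("pjde,jsde->pjs", w, emit)


def _batch_forward_backward(
    obs: np.ndarray, trans: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Scaled Forward-Backward for a batch of chains sharing transitions.

    Parameters
    ----------
    obs : (p, m, 5) observation terms; trans : (m-1, 5, 5); pi : (5,).

    Returns
    -------
    (p, m, 5) posterior state probabilities (each row sums to 1).
    """
    p, m, S = obs.shape
    alpha = np.empty((p, m, S))
    a = pi[None, :] * obs[:, 0, :]
    norm = a.sum(axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    alpha[:, 0] = a / norm
    for j in range(1, m):
        a = (alpha[:, j - 1] @ trans[j - 1]) * obs[:, j]
        norm = a.sum(axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        alpha[:, j] = a / norm
    post = np.empty((p, m, S))
    beta = np.ones((p, S))
    post[:, m - 1] = alpha[:, m - 1]
    for j in range(m - 2, -1, -1):
        beta = (beta * obs[:, j + 1]) @ trans[j].T
        norm = beta.sum(axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        beta = beta / norm
        g = alpha[:, j] * beta
        post[:, j] = g / g.sum(axis=1, keepdims=True)
    return post


def pair_posteriors(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    gmap: GeneticMap,
    params: ModelParams,
    freqs: np.ndarray,
    tables: tuple | None = None,
) -> np.ndarray:
    """Per-marker 5-state posteriors for one pair of individuals.

    The chain is initialized at the stationary distribution of the capped
    process; computation is in the scaled domain so long chromosomes do not
    underflow.  Returns an (m, 5) matrix whose rows sum to one.
    """
    geno_a = np.asarray(geno_a)
    geno_b = np.asarray(geno_b)
    if geno_a.shape != geno_b.shape or geno_a.shape[0] != gmap.n_markers:
        raise ValueError("genotype rows and map must cover the same markers")
    trans, emit, pi = tables if tables is not None else precompute_tables(
        gmap, freqs, params
    )
    obs = _obs_terms(geno_a[None, :], geno_b[None, :], emit, params.epsilon)
    return _batch_forward_backward(obs, trans, pi)[0]


def call_segments(
    posteriors: np.ndarray,
    gmap: GeneticMap,
    params: ModelParams,
    a: int = 0,
    b: int = 1,
) -> list[PlausibleSegment]:
    """Threshold the combined IBD posterior into plausible segments.

    Maximal runs of markers with combined IBD posterior (sum of the four
    shared states) above ``posterior_threshold``; runs separated by fewer
    than ``gap_merge`` markers are merged, and merged runs shorter than
    ``min_markers`` markers are dropped.
    """
    ibd = posteriors[:, 1:].sum(axis=1)
    above = ibd > params.posterior_threshold
    if not np.any(above):
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    runs = list(zip(starts, ends))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < params.gap_merge:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s < params.min_markers:
            continue
        out.append(
            PlausibleSegment(
                a=a,
                b=b,
                start=s,
                end=e,
                peak_posterior=float(ibd[s:e].max()),
                genetic_length=float(gmap.morgans[e - 1] - gmap.morgans[s]),
            )
        )
    return out


def scan_all_pairs(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    params: ModelParams,
    chunk_pairs: int = 512,
) -> list[PlausibleSegment]:
    """Prescan every unordered pair of individuals.

    Pairs are processed in batches that share the per-marker transition and
    emission tables, so the Forward-Backward recursion is a sequence of
    small matrix products over all pairs at once.  If ``max_depth`` is set,
    segments covering an (individual, marker) cell beyond that depth are
    dropped, keeping the highest peak posterior first.
    """
    n = geno.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals to scan for IBD")
    tables = precompute_tables(gmap, geno.freqs, params)
    trans, emit, pi = tables
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    segments: list[PlausibleSegment] = []
    for lo in range(0, len(pairs), chunk_pairs):
        chunk = pairs[lo : lo + chunk_pairs]
        ia = np.array([p[0] for p in chunk])
        ib = np.array([p[1] for p in chunk])
        obs = _obs_terms(geno.dosages[ia], geno.dosages[ib], emit, params.epsilon)
        post = _batch_forward_backward(obs, trans, pi)
        for k, (a, b) in enumerate(chunk):
            segments.extend(call_segments(post[k], gmap, params, a=a, b=b))
        logger.debug(
            "prescan %d/%d pairs, %d segments so far",
            min(lo + chunk_pairs, len(pairs)), len(pairs), len(segments),
        )
    if params.max_depth is not None:
        segments = _cap_depth(segments, n, gmap.n_markers, params.max_depth)
    logger.info(
        "prescan: %d plausible segments over %d pairs (%.1f per pair)",
        len(segments), len(pairs), len(segments) / max(len(pairs), 1),
    )
    return segments


def _cap_depth(
    segments: list[PlausibleSegment], n: int, m: int, max_depth: int
) -> list[PlausibleSegment]:
    """Greedy per-cell coverage cap, highest peak posterior first."""
    depth = np.zeros((n, m), dtype=np.int32)
    kept = []
    for seg in sorted(segments, key=lambda s: -s.peak_posterior):
        da = depth[seg.a, seg.start : seg.end]
        db = depth[seg.b, seg.start : seg.end]
        if da.max(initial=0) >= max_depth or db.max(initial=0) >= max_depth:
            continue
        da += 1
        db += 1
        kept.append(seg)
    kept.sort(key=lambda s: (s.a, s.b, s.start))
    return kept


def write_segments(
    path: str, segments: list[PlausibleSegment], geno: GenotypeMatrix, gmap: GeneticMap
) -> None:
    """Dump plausible segments as TSV (marker interval half-open, 0-based;
    bp positions of the first and last covered marker)."""
    with open(path, "w") as fh:
        fh.write(
            "a_id\tb_id\tchrom\tstart_bp\tend_bp\tstart_marker\tend_marker\t"
            "genetic_length_cM\tpeak_posterior\n"
        )
        for s in segments:
            fh.write(
                f"{geno.sample_ids[s.a]}\t{geno.sample_ids[s.b]}\t{gmap.chrom}\t"
                f"{int(gmap.bp[s.start])}\t{int(gmap.bp[s.end - 1])}\t"
                f"{s.start}\t{s.end}\t{100.0 * s.genetic_length:.4f}\t"
                f"{s.peak_posterior:.4f}\n"
            )
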