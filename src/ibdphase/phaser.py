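"""Min-Sum phasing over the Bayesian network of pairwise IBD processes.

The network couples, for every plausible IBD segment found by the prescan,
a chain of five-valued IBD indicator variables with the four-valued
diplotype variables of the two individuals.  The genotype of individual
*a* at marker *j* depends on its diplotype; the IBD indicator at marker
*j* depends on the two diplotypes at *j* and on the indicator at *j - 1*
through the Bayes-rule inversion of the pair-HMM emission model, realized
as a likelihood-ratio factor (transition times the emission odds against
the non-IBD baseline) so that shared rare alleles raise the joint score.
Diplotypes carry a uniform prior.

Approximate MAP inference runs damped, attenuated Min-Sum (max-product in
the negative-log domain) restricted to the plausible segments; phase
calls, IBD segment calls and imputed alleles are read off the converged
max-marginals, with calls refused whenever the max-marginal margin is
below a threshold.

The joint distribution is invariant under flipping either individual's
haplotype labels (with the matching relabelling of the IBD states), so
exact max-marginals tie at every heterozygous site.  The gauge is fixed
before inference by clamping one observed heterozygous site per
(individual, connected component) to minor-allele-on-haplotype-1, placed
at an interior, deeply covered cell with a homozygous covering partner
(see :func:`build_graph`); margins are then flip costs relative to that
anchoring, and reported switch errors are invariant to the choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._minsum import sweep
from .io import MISSING, GeneticMap, GenotypeMatrix
from .model_core import (
    DIPLOTYPE_DOSAGE,
    ModelParams,
    N_DIPLOTYPES,
    N_STATES,
    emission_table,
    genotype_likelihood_table,
    stationary_distribution,
    transition_matrix,
    build_rate_matrix,
)
from .prescan import PlausibleSegment, precompute_tables

logger = logging.getLogger("ibdphase")

__all__ = [
    "ibd_cpt",
    "FactorGraph",
    "build_graph",
    "min_sum",
    "MinSumResult",
    "PhaseResult",
    "IBDSegmentCall",
    "call_phase",
    "impute",
    "extract_ibd_calls",
    "write_ibd_calls",
    "write_margins",
]

#: cost standing in for -log(0) in factor tables (impossible outcomes)
BIG = 1e3
#: clamp cost used to anchor the per-individual flip gauge
CLAMP = 1e7


def ibd_cpt(
    d_a: int,
    d_b: int,
    prev: int | None,
    t: float,
    f: float,
    params: ModelParams,
) -> np.ndarray:
    """P(p_j = s | diplotypes at j, p_{j-1}) for the five IBD states.

    Proportional to the transition probability from ``prev`` over an
    interval of ``t`` Morgans times the emission probability of the
    diplotype pair under state ``s``.  ``prev=None`` denotes the first
    marker of a segment, which conditions on the stationary distribution
    instead of a predecessor.  When every IBD emission is zero (the shared
    haplotype would violate identity-by-state) the mass concentrates on
    NONIBD.
    """
    emit = emission_table(np.array([f]))[0, :, d_a, d_b]
    if prev is None:
        trow = stationary_distribution(params)
    else:
        Q = build_rate_matrix(params)
        trow = transition_matrix(Q, t, params.kappa)[prev]
    w = trow * emit
    z = w.sum()
    if z <= 0.0:  # cannot happen for 0 < f < 1 (NONIBD emission positive)
        raise AssertionError("degenerate IBD conditional")
    return w / z


# ---------------------------------------------------------------------------
# factor graph


@dataclass
class FactorGraph:
    """Array-of-struct factor graph restricted to plausible segments.

    Diplotype variables exist for every (individual, marker) cell covered
    by at least one segment; IBD variables exist per segment per covered
    marker ("cells", concatenated segment after segment).  Factor tables
    are stored as per-marker negative-log cost tensors shared by all
    segments, since they depend only on the map interval and the allele
    frequency at the marker.
    """

    n_individuals: int
    n_markers: int
    segments: list[PlausibleSegment]
    # diplotype variables
    hvar_ind: np.ndarray  # (n_h,) individual of each diplotype variable
    hvar_marker: np.ndarray  # (n_h,)
    cell_to_hvar: np.ndarray  # (n, m) int32, -1 where uncovered
    hunary: np.ndarray  # (n_h, 4) genotype factor costs (+ anchor clamps)
    component: np.ndarray  # (n_h,) connected-component label
    anchors: np.ndarray  # hvar ids clamped to fix the flip gauge
    # IBD chain cells
    seg_ptr: np.ndarray  # (n_seg + 1,) offsets into cell arrays
    cell_marker: np.ndarray  # (n_cells,)
    cell_ha: np.ndarray  # (n_cells,) hvar id of individual a
    cell_hb: np.ndarray  # (n_cells,)
    # shared per-marker factor cost tensors
    cost_t: np.ndarray  # (m, 5, 5, 4, 4); entry [j, pp, p, da, db]
    cost_0: np.ndarray  # (m, 5, 4, 4) first-cell variant (stationary prior)

    @property
    def n_hvars(self) -> int:
        return self.hvar_ind.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cell_marker.shape[0]

    def factor_cost(self, s: int, k_local: int, pp: int, p: int, da: int, db: int) -> float:
        """Negative-log CPT value of one factor (for enumeration oracles)."""
        k = self.seg_ptr[s] + k_local
        j = self.cell_marker[k]
        if k_local == 0:
            return float(self.cost_0[j, p, da, db])
        return float(self.cost_t[j, pp, p, da, db])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _neg_log(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, BIG, dtype=float)
    pos = x > 0.0
    out[pos] = -np.log(x[pos])
    return np.minimum(out, BIG)


def build_graph(
    geno: GenotypeMatrix,
    segments: list[PlausibleSegment],
    gmap: GeneticMap,
    params: ModelParams,
    tables: tuple | None = None,
) -> FactorGraph:
    """Assemble the factor graph over the plausible segments.

    Creates diplotype variables for every covered (individual, marker)
    cell, attaches genotype factors from the error model, builds the
    shared per-marker IBD-CPT cost tensors, labels connected components
    and places the gauge-fixing anchors.
    """
    n, m = geno.dosages.shape
    if not segments:
        logger.warning("empty plausible-segment list: nothing can be phased")
    segments = sorted(segments, key=lambda s: (s.a, s.b, s.start))
    covered = np.zeros((n, m), dtype=bool)
    for s in segments:
        covered[s.a, s.start : s.end] = True
        covered[s.b, s.start : s.end] = True
    hvar_ind, hvar_marker = np.nonzero(covered)
    cell_to_hvar = np.full((n, m), -1, dtype=np.int64)
    cell_to_hvar[hvar_ind, hvar_marker] = np.arange(hvar_ind.shape[0])

    # genotype factors (uniform diplotype prior contributes nothing)
    gl = genotype_likelihood_table(geno.dosages[hvar_ind, hvar_marker], params.epsilon)
    hunary = _neg_log(gl)

    seg_ptr = np.zeros(len(segments) + 1, dtype=np.int64)
    for i, s in enumerate(segments):
        seg_ptr[i + 1] = seg_ptr[i] + s.n_markers
    n_cells = int(seg_ptr[-1])
    cell_marker = np.empty(n_cells, dtype=np.int64)
    cell_ha = np.empty(n_cells, dtype=np.int64)
    cell_hb = np.empty(n_cells, dtype=np.int64)
    uf = _UnionFind(hvar_ind.shape[0])
    for i, s in enumerate(segments):
        sl = slice(seg_ptr[i], seg_ptr[i + 1])
        jj = np.arange(s.start, s.end)
        cell_marker[sl] = jj
        ha = cell_to_hvar[s.a, jj]
        hb = cell_to_hvar[s.b, jj]
        cell_ha[sl] = ha
        cell_hb[sl] = hb
        # the whole segment is one connected blob (linked through the chain)
        for v in ha[1:]:
            uf.union(ha[0], v)
        for v in hb:
            uf.union(ha[0], v)
    component = np.array([uf.find(v) for v in range(hvar_ind.shape[0])])

    # shared per-marker cost tensors.  The IBD factor is the Bayes-rule
    # inversion of the pair-HMM emissions: transition times the emission
    # *likelihood ratio* against the non-IBD (independent HWE) baseline,
    #   F_j = T(p_{j-1} -> p_j) * E(d | p_j) / E(d | NONIBD).
    # Dividing by the unconditional diplotype probability (rather than
    # renormalizing over p_j per diplotype context) leaves P(p | h)
    # untouched but is what lets sharing of rare alleles raise the joint
    # score: with a per-context normalizer the p chain would be
    # d-separated from the data and carry no phase information at all.
    trans, emit, pi = tables if tables is not None else precompute_tables(
        gmap, geno.freqs, params
    )
    baseline = emit[:, 0:1, :, :]  # (m, 1, 4, 4) non-IBD HWE probability
    ratio = emit / baseline  # >= 0; NONIBD slice is identically 1
    # cost_t[j] is the factor between markers j-1 and j; row 0 unused
    te = np.zeros((m, N_STATES, N_STATES, N_DIPLOTYPES, N_DIPLOTYPES))
    te[1:] = trans[:, :, :, None, None] * ratio[1:, None, :, :, :]
    cost_t = _neg_log(te)
    pe = pi[None, :, None, None] * ratio  # (m, 5, 4, 4)
    cost_0 = _neg_log(pe)

    # Gauge anchors: one observed het per (individual, component), clamped
    # to minor-allele-on-haplotype-1.  Placement matters:
    #  * interior, deeply covered cells — at a chain boundary the IBD
    #    process sidesteps a clamp almost for free by deferring entry one
    #    marker, leaving a near-zero-cost global flip;
    #  * prefer het sites where some covering partner is homozygous — at a
    #    het-het site both diagonal diplotype pairs are compatible with
    #    either haplotype pairing, so a joint flip of both individuals
    #    (with the chain relabelled S11<->S22) slips through the clamp.
    depth = np.zeros((n, m), dtype=np.int32)
    hom_partner = np.zeros(hvar_ind.shape[0], dtype=bool)
    dos = geno.dosages
    for s in segments:
        depth[s.a, s.start : s.end] += 1
        depth[s.b, s.start : s.end] += 1
        jj = np.arange(s.start, s.end)
        a_hom = np.isin(dos[s.a, jj], (0, 2))
        b_hom = np.isin(dos[s.b, jj], (0, 2))
        hom_partner[cell_to_hvar[s.a, jj[b_hom]]] = True
        hom_partner[cell_to_hvar[s.b, jj[a_hom]]] = True
    anchors = []
    het = dos[hvar_ind, hvar_marker] == 1
    cand: dict[tuple[int, int], tuple] = {}
    centre = {}
    for i in range(n):
        cov = np.nonzero(covered[i])[0]
        centre[i] = 0.5 * (cov[0] + cov[-1]) if len(cov) else 0.0
    for v in np.nonzero(het)[0]:
        i, j = int(hvar_ind[v]), int(hvar_marker[v])
        key = (i, int(component[v]))
        score = (bool(hom_partner[v]), int(depth[i, j]), -abs(j - centre[i]))
        if key not in cand or score > cand[key][0]:
            cand[key] = (score, v)
    for (_score, v) in cand.values():
        anchors.append(v)
        hunary[v, 1] += CLAMP  # forbid (major, minor); keep (minor, major)
    return FactorGraph(
        n_individuals=n,
        n_markers=m,
        segments=segments,
        hvar_ind=hvar_ind,
        hvar_marker=hvar_marker,
        cell_to_hvar=cell_to_hvar,
        hunary=hunary,
        component=component,
        anchors=np.array(anchors, dtype=np.int64),
        seg_ptr=seg_ptr,
        cell_marker=cell_marker,
        cell_ha=cell_ha,
        cell_hb=cell_hb,
        cost_t=cost_t,
        cost_0=cost_0,
    )


# ---------------------------------------------------------------------------
# inference


@dataclass
class MinSumResult:
    """Converged message store and derived max-marginals."""

    graph: FactorGraph
    fmsg: np.ndarray  # (n_cells, 5) message into p_k from its left factor
    bmsg: np.ndarray  # (n_cells, 5) message into p_k from its right factor
    hbelief: np.ndarray  # (n_h, 4) negative-log max-marginals (to a constant)
    hamsg: np.ndarray  # (n_cells, 4) factor-to-diplotype messages (a side)
    hbmsg: np.ndarray  # (n_cells, 4)
    converged: bool
    n_iters: int
    final_delta: float
    _viterbi: np.ndarray | None = None

    def pbelief(self) -> np.ndarray:
        """(n_cells, 5) negative-log max-marginals of the IBD indicators."""
        return self.fmsg + self.bmsg

    def p_map(self) -> np.ndarray:
        """(n_cells,) per-cell argmin of the IBD max-marginals.

        Near-tied beliefs can make independent per-cell argmins flip
        spuriously along a chain; :meth:`p_viterbi` gives the consistent
        joint decode used for segment calls.
        """
        return np.argmin(self.pbelief(), axis=1)

    def p_viterbi(self) -> np.ndarray:
        """(n_cells,) jointly consistent MAP IBD path per segment chain.

        Each chain is re-decoded by a Viterbi pass over its factors with
        the converged diplotype-variable messages folded in as soft
        evidence, so one chain yields one coherent path instead of
        independent per-cell argmins (which flip between near-tied
        haplotype pairings).  Ties resolve toward the lower state.
        """
        if self._viterbi is None:
            self._viterbi = _viterbi_decode(self)
        return self._viterbi


def min_sum(graph: FactorGraph, params: ModelParams) -> MinSumResult:
    """Run damped Min-Sum sweeps until message convergence.

    Each sweep passes forward then backward along every segment chain,
    refreshing the diplotype messages in place.  Updates are convex
    combinations ``damping * old + (1 - damping) * new`` in the cost
    domain; iteration stops when the largest absolute message change drops
    below ``convergence_tol`` or after ``max_iters`` sweeps (the result is
    still returned, flagged unconverged).
    """
    nc = graph.n_cells
    fmsg = np.zeros((nc, N_STATES))
    bmsg = np.zeros((nc, N_STATES))
    hamsg = np.zeros((nc, N_DIPLOTYPES))
    hbmsg = np.zeros((nc, N_DIPLOTYPES))
    htot = graph.hunary.copy()
    converged = False
    it = 0
    delta = np.inf
    for it in range(1, params.max_iters + 1):
        delta = sweep(
            graph.seg_ptr,
            graph.cell_marker,
            graph.cell_ha,
            graph.cell_hb,
            graph.cost_t,
            graph.cost_0,
            fmsg,
            bmsg,
            hamsg,
            hbmsg,
            htot,
            params.damping,
            params.attenuation,
        )
        if delta < params.convergence_tol:
            converged = True
            break
    if not converged and nc > 0:
        logger.warning(
            "Min-Sum did not converge in %d iterations (last delta %.2e)",
            params.max_iters, delta,
        )
    return MinSumResult(
        graph=graph,
        fmsg=fmsg,
        bmsg=bmsg,
        hbelief=htot,
        hamsg=hamsg,
        hbmsg=hbmsg,
        converged=converged or nc == 0,
        n_iters=it,
        final_delta=float(delta) if nc else 0.0,
    )


def _viterbi_decode(result: "MinSumResult") -> np.ndarray:
    """Per-segment Viterbi over the IBD chain with diplotype messages as
    soft evidence; returns the jointly consistent MAP state per cell."""
    g = result.graph
    out = np.zeros(g.n_cells, dtype=np.int8)
    in_a = result.hbelief[g.cell_ha] - result.hamsg  # (n_cells, 4)
    in_b = result.hbelief[g.cell_hb] - result.hbmsg
    # small per-state bias keeps tie-breaking aligned with the message pass
    bias = 1e-6 * np.arange(N_STATES)
    for s_idx in range(len(g.segments)):
        k0, k1 = int(g.seg_ptr[s_idx]), int(g.seg_ptr[s_idx + 1])
        jj = g.cell_marker[k0:k1]
        # W[k, pp, p]: factor cost minimized over the two diplotypes
        w = np.min(
            g.cost_t[jj]
            + in_a[k0:k1][:, None, None, :, None]
            + in_b[k0:k1][:, None, None, None, :],
            axis=(3, 4),
        )
        w0 = np.min(
            g.cost_0[jj[0]]
            + in_a[k0][None, :, None]
            + in_b[k0][None, None, :],
            axis=(1, 2),
        )
        nk = k1 - k0
        back = np.zeros((nk, N_STATES), dtype=np.int8)
        v = w0 + bias
        for k in range(1, nk):
            tot = v[:, None] + w[k] + bias[None, :]
            back[k] = np.argmin(tot, axis=0)
            v = np.min(tot, axis=0)
        path = np.empty(nk, dtype=np.int8)
        path[-1] = int(np.argmin(v))
        for k in range(nk - 1, 0, -1):
            path[k - 1] = back[k, path[k]]
        out[k0:k1] = path
    return out


# ---------------------------------------------------------------------------
# calling


@dataclass
class PhaseResult:
    """Phase, imputation and confidence calls per individual per marker.

    ``diplotypes[i, j]`` holds the ordered alleles (haplotype 1, haplotype
    2) with -1 for no-call; ``phased[i, j]`` marks sites with a full
    ordered call; ``imputed[i, j, c]`` marks alleles called at missing
    genotypes through IBD sharing; ``margins`` holds the max-marginal
    margin (negative-log units) where a comparison was made.
    """

    diplotypes: np.ndarray  # (n, m, 2) int8
    phased: np.ndarray  # (n, m) bool
    margins: np.ndarray  # (n, m) float
    imputed: np.ndarray  # (n, m, 2) bool
    corrections: list  # (ind, marker, observed, called_dosage)
    converged: bool
    n_iters: int

    def het_phase_mask(self, geno: GenotypeMatrix) -> np.ndarray:
        """Observed-het sites that received an ordered phase call."""
        return (geno.dosages == 1) & self.phased


def call_phase(
    result: MinSumResult, geno: GenotypeMatrix, params: ModelParams
) -> PhaseResult:
    """Turn max-marginals into phase calls, refusing uncertain sites.

    At each observed heterozygous site with a diplotype variable, the two
    orientations are compared; the better one is called iff the margin is
    at least ``phase_margin``.  Heterozygous sites outside every plausible
    segment stay unphased.  Observed homozygous sites are trivially
    phased.  MAP diplotypes contradicting an observed genotype (possible
    when epsilon > 0) are reported as genotype corrections, not applied.
    """
    graph = result.graph
    n, m = geno.dosages.shape
    diplo = np.full((n, m, 2), MISSING, dtype=np.int8)
    phased = np.zeros((n, m), dtype=bool)
    margins = np.zeros((n, m))
    corrections: list[tuple[int, int, int, int]] = []

    dos = geno.dosages
    hom0 = dos == 0
    hom2 = dos == 2
    diplo[hom0] = 0
    diplo[hom2] = 1
    phased |= hom0 | hom2

    hb = result.hbelief
    ind = graph.hvar_ind
    mk = graph.hvar_marker
    het = dos[ind, mk] == 1
    b1 = hb[:, 1]  # (major, minor)
    b2 = hb[:, 2]  # (minor, major)
    margin = np.abs(b1 - b2)
    # anchored sites carry the clamp in their belief; their margin is the
    # clamp itself, so recompute against the unclamped alternative
    for v in graph.anchors:
        margin[v] = np.abs((b1[v] - CLAMP) - b2[v])
    call = het & (margin >= params.phase_margin)
    margins[ind[het], mk[het]] = margin[het]
    minor_first = b2 <= b1
    iv, jv = ind[call], mk[call]
    diplo[iv, jv, 0] = np.where(minor_first[call], 1, 0)
    diplo[iv, jv, 1] = np.where(minor_first[call], 0, 1)
    phased[iv, jv] = True

    # genotype corrections: MAP diplotype dosage differs from observation
    obs = dos[ind, mk] != MISSING
    map_d = np.argmin(hb, axis=1)
    map_dos = DIPLOTYPE_DOSAGE[map_d]
    for v in np.nonzero(obs & (map_dos != dos[ind, mk]))[0]:
        sortb = np.sort(hb[v])
        if sortb[1] - sortb[0] >= params.phase_margin:
            corrections.append(
                (int(ind[v]), int(mk[v]), int(dos[ind[v], mk[v]]), int(map_dos[v]))
            )
    if corrections:
        logger.info("flagged %d genotype corrections (not applied)", len(corrections))
    return PhaseResult(
        diplotypes=diplo,
        phased=phased,
        margins=margins,
        imputed=np.zeros((n, m, 2), dtype=bool),
        corrections=corrections,
        converged=result.converged,
        n_iters=result.n_iters,
    )


# IBD states linking haplotype h (0/1) of the first / second individual
_LINK_A = {0: (1, 2), 1: (3, 4)}  # S1j / S2j
_LINK_B = {0: (1, 3), 1: (2, 4)}  # Si1 / Si2


def impute(
    result: MinSumResult,
    geno: GenotypeMatrix,
    params: ModelParams,
    phase: PhaseResult,
) -> PhaseResult:
    """Impute alleles at missing genotypes through MAP IBD sharing.

    A haplotype's allele at a missing site is called iff some segment's
    MAP IBD chain links that haplotype to a partner at the marker and the
    max-marginal margin between the two alleles on that haplotype passes
    the threshold.  A genotype is fully imputed iff both alleles are
    called.  Updates ``phase`` in place and returns it.
    """
    graph = result.graph
    dos = geno.dosages
    pmap = result.p_viterbi()
    hb = result.hbelief
    # which haplotypes of which cells are linked by a MAP IBD state
    linked = np.zeros((graph.n_hvars, 2), dtype=bool)
    for s_idx, seg in enumerate(graph.segments):
        sl = slice(graph.seg_ptr[s_idx], graph.seg_ptr[s_idx + 1])
        states = pmap[sl]
        ha = graph.cell_ha[sl]
        hbv = graph.cell_hb[sl]
        for hap in (0, 1):
            la = np.isin(states, _LINK_A[hap])
            lb = np.isin(states, _LINK_B[hap])
            linked[ha[la], hap] = True
            linked[hbv[lb], hap] = True
    # allele max-marginals per haplotype: diplotype codes with allele x on
    # haplotype c ({0: major, 1: minor})
    cost_h = np.empty((graph.n_hvars, 2, 2))
    cost_h[:, 0, 0] = np.minimum(hb[:, 0], hb[:, 1])  # hap1 major (codes 0, 1)
    cost_h[:, 0, 1] = np.minimum(hb[:, 2], hb[:, 3])  # hap1 minor
    cost_h[:, 1, 0] = np.minimum(hb[:, 0], hb[:, 2])  # hap2 major
    cost_h[:, 1, 1] = np.minimum(hb[:, 1], hb[:, 3])  # hap2 minor
    miss = dos[graph.hvar_ind, graph.hvar_marker] == MISSING
    for v in np.nonzero(miss)[0]:
        i, j = int(graph.hvar_ind[v]), int(graph.hvar_marker[v])
        called = 0
        for c in (0, 1):
            if not linked[v, c]:
                continue
            margin = abs(cost_h[v, c, 0] - cost_h[v, c, 1])
            if margin < params.phase_margin:
                continue
            phase.diplotypes[i, j, c] = 1 if cost_h[v, c, 1] < cost_h[v, c, 0] else 0
            phase.imputed[i, j, c] = True
            called += 1
        if called == 2:
            phase.phased[i, j] = True
            phase.margins[i, j] = min(
                abs(cost_h[v, 0, 0] - cost_h[v, 0, 1]),
                abs(cost_h[v, 1, 0] - cost_h[v, 1, 1]),
            )
    return phase


@dataclass(frozen=True)
class IBDSegmentCall:
    """Final IBD call: haplotype ``hap_a`` of *a* IBD with ``hap_b`` of *b*
    over the half-open marker interval [start, end)."""

    a: int
    b: int
    hap_a: int  # 1 or 2
    hap_b: int
    start: int
    end: int
    genetic_length: float  # Morgans

    @property
    def n_markers(self) -> int:
        return self.end - self.start


def extract_ibd_calls(
    result: MinSumResult,
    gmap: GeneticMap,
    phase: PhaseResult | None = None,
) -> list[IBDSegmentCall]:
    """Maximal runs of constant MAP IBD state within each segment chain,
    split at flips between IBD states and at NONIBD stretches.

    When ``phase`` is given, calls are additionally split at markers where
    both linked haplotypes carry a phase call but with *different* alleles:
    approximate inference can decode the chain and the diplotypes slightly
    inconsistently, and an IBD claim that contradicts the emitted phase is
    not reported.
    """
    graph = result.graph
    pmap = result.p_viterbi().copy()
    if phase is not None:
        pmap = _enforce_phase_coherence(graph, pmap, phase)
    calls: list[IBDSegmentCall] = []
    for s_idx, seg in enumerate(graph.segments):
        k0, k1 = graph.seg_ptr[s_idx], graph.seg_ptr[s_idx + 1]
        states = pmap[k0:k1]
        jj = graph.cell_marker[k0:k1]
        k = 0
        while k < len(states):
            st = states[k]
            if st == 0:
                k += 1
                continue
            run0 = k
            while k < len(states) and states[k] == st:
                k += 1
            start, end = int(jj[run0]), int(jj[k - 1]) + 1
            calls.append(
                IBDSegmentCall(
                    a=seg.a,
                    b=seg.b,
                    hap_a=(int(st) - 1) // 2 + 1,
                    hap_b=(int(st) - 1) % 2 + 1,
                    start=start,
                    end=end,
                    genetic_length=float(gmap.morgans[end - 1] - gmap.morgans[start]),
                )
            )
    return calls


def _enforce_phase_coherence(
    graph: FactorGraph, pmap: np.ndarray, phase: PhaseResult
) -> np.ndarray:
    """Set chain cells whose IBD claim contradicts the called alleles of
    the linked haplotypes to NONIBD (in a copy of the decoded path)."""
    for s_idx, seg in enumerate(graph.segments):
        sl = slice(int(graph.seg_ptr[s_idx]), int(graph.seg_ptr[s_idx + 1]))
        states = pmap[sl]
        jj = graph.cell_marker[sl]
        shared = states > 0
        if not np.any(shared):
            continue
        hap_a = (states - 1) // 2  # 0-based haplotype index, valid where shared
        hap_b = (states - 1) % 2
        jjs = jj[shared]
        aa = phase.diplotypes[seg.a, jjs, hap_a[shared]]
        bb = phase.diplotypes[seg.b, jjs, hap_b[shared]]
        both = phase.phased[seg.a, jjs] & phase.phased[seg.b, jjs]
        conflict = both & (aa >= 0) & (bb >= 0) & (aa != bb)
        if np.any(conflict):
            idx = np.nonzero(shared)[0][conflict]
            states[idx] = 0
            pmap[sl] = states
    return pmap


def write_ibd_calls(
    path: str, calls: list[IBDSegmentCall], geno: GenotypeMatrix, gmap: GeneticMap
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "a_id\ta_hap\tb_id\tb_hap\tchrom\tstart_bp\tend_bp\tn_markers\t"
            "genetic_length_cM\n"
        )
        for c in calls:
            fh.write(
                f"{geno.sample_ids[c.a]}\t{c.hap_a}\t{geno.sample_ids[c.b]}\t"
                f"{c.hap_b}\t{gmap.chrom}\t{int(gmap.bp[c.start])}\t"
                f"{int(gmap.bp[c.end - 1])}\t{c.n_markers}\t"
                f"{100.0 * c.genetic_length:.4f}\n"
            )


def write_margins(path: str, phase: PhaseResult, geno: GenotypeMatrix, gmap: GeneticMap) -> None:
    """Auxiliary per-site margins for phased heterozygous/imputed sites."""
    with open(path, "w") as fh:
        fh.write("sample\tmarker\tmargin\tphased\n")
        n, m = phase.margins.shape
        for i in range(n):
            jj = np.nonzero(phase.margins[i] > 0)[0]
            for j in jj:
                fh.write(
                    f"{geno.sample_ids[i]}\t{geno.marker_ids[j]}\t"
                    f"{phase.margins[i, j]:.4f}\t{int(phase.phased[i, j])}\n"
                )
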