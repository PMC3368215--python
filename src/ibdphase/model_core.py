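"""Five-state continuous-time IBD process for a pair of diploid individuals.

The hidden process along a chromosome takes one of five values: the pair
shares no haplotype identical-by-descent (NONIBD), or haplotype ``i`` of
individual *a* is IBD with haplotype ``j`` of individual *b* (states ``Sij``,
``i, j`` in {1, 2}).  Of the 15 ways four labelled haplotypes can be
partitioned into IBD classes, only these five are modelled: configurations
with two shared pairs contain one of the four single-share cases as a
sub-case carrying all the phase information, and within-individual sharing
(homozygosity-by-descent) is deliberately ignored.

Transitions are governed by a rate matrix with entry rate ``g`` (per Morgan,
NONIBD -> IBD, split uniformly over the four IBD states) and exit rate ``l``
(IBD -> NONIBD).  Per-interval transition probabilities are ``expm(t*Q)``
with the probability of entering IBD between adjacent markers capped at the
population kinship coefficient.  Emissions are ordered allele pairs
(diplotypes) for both individuals, following sample allele frequencies and
Hardy-Weinberg equilibrium subject to the identity-by-state constraint of
the hidden state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.linalg import expm

__all__ = [
    "IBDState",
    "ModelParams",
    "N_STATES",
    "N_DIPLOTYPES",
    "build_rate_matrix",
    "transition_matrix",
    "stationary_distribution",
    "emission_prob",
    "emission_table",
    "genotype_likelihood",
    "genotype_likelihood_table",
    "diplotype_dosage",
    "enumerate_ibd_configurations",
]


class IBDState(IntEnum):
    """Hidden IBD state for an ordered pair of individuals (a, b).

    ``Sij`` means haplotype ``i`` of *a* is IBD with haplotype ``j`` of *b*.
    """

    NONIBD = 0
    S11 = 1
    S12 = 2
    S21 = 3
    S22 = 4


N_STATES = 5

#: Diplotypes are ordered allele pairs, encoded 0..3 as 2*h1 + h2 with
#: allele 1 = minor, allele 0 = major.  Index 1 = (major, minor) etc.
N_DIPLOTYPES = 4

# allele of haplotype 1 / haplotype 2 for each diplotype code
_D_H1 = np.array([0, 0, 1, 1], dtype=np.int8)
_D_H2 = np.array([0, 1, 0, 1], dtype=np.int8)

#: dosage (minor-allele count) of each diplotype code
DIPLOTYPE_DOSAGE = (_D_H1 + _D_H2).astype(np.int8)


def diplotype_dosage(d: int) -> int:
    """Minor-allele count of diplotype code ``d``."""
    return int(DIPLOTYPE_DOSAGE[d])


@dataclass
class ModelParams:
    """Tunable parameters of the pairwise IBD model and its inference.

    Rates are per Morgan.  The defaults correspond to an expected non-IBD
    (identical-by-state) segment length of 1 cM and an expected IBD segment
    length of 10 cM.

    Attributes
    ----------
    g : entry rate into IBD (per Morgan); 1/g is the expected non-IBD length.
    l : exit rate out of IBD (per Morgan); 1/l is the expected IBD length.
    kappa : kinship coefficient capping the per-interval probability of
        entering an IBD state; unconditional probability that a random
        haplotype pair from two individuals is IBD.
    epsilon : per-genotype error probability of the assay.
    damping : convex-combination weight on the old message in Min-Sum
        updates (0 = undamped).
    attenuation : scale on factor-to-diplotype messages (normalized
        Min-Sum); values below 1 counteract evidence recirculation through
        the short cycles of the loopy graph.
    max_iters : Min-Sum sweep cap.
    posterior_threshold : prescan combined-IBD posterior cutoff for calling
        plausible IBD segments.
    phase_margin : minimum max-marginal margin, in negative-log units, for
        calling a phase or an imputed allele.
    gap_merge : plausible-segment runs separated by fewer than this many
        markers are merged.
    min_markers : plausible-segment runs shorter than this are dropped.
    max_depth : cap on plausible segments covering one (individual, marker)
        cell; ``None`` = unlimited.
    seed : random seed for any stochastic component.
    """

    g: float = 100.0
    l: float = 10.0
    kappa: float = 0.05
    epsilon: float = 1e-3
    damping: float = 0.25
    attenuation: float = 0.35
    max_iters: int = 60
    posterior_threshold: float = 0.5
    phase_margin: float = 2.0
    gap_merge: int = 2
    min_markers: int = 16
    max_depth: int | None = None
    seed: int = 0
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not (self.g > 0 and self.l > 0):
            raise ValueError("rates g and l must be positive")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must lie in [0, 0.5)")
        if not (0.0 <= self.damping < 1.0):
            raise ValueError("damping must lie in [0, 1)")
        if not (0.0 < self.attenuation <= 1.0):
            raise ValueError("attenuation must lie in (0, 1]")
        if not (0.0 < self.posterior_threshold < 1.0):
            raise ValueError("posterior_threshold must lie in (0, 1)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @classmethod
    def from_expected_lengths(
        cls, nonibd_cm: float = 1.0, ibd_cm: float = 10.0, **kwargs
    ) -> "ModelParams":
        """Build parameters from expected segment lengths in centimorgans."""
        if nonibd_cm <= 0 or ibd_cm <= 0:
            raise ValueError("expected segment lengths must be positive")
        return cls(g=100.0 / nonibd_cm, l=100.0 / ibd_cm, **kwargs)


def build_rate_matrix(params: ModelParams) -> np.ndarray:
    """Rate matrix Q of the five-state IBD process.

    NONIBD exits at total rate ``g`` split equally over the four IBD states;
    each IBD state exits to NONIBD at rate ``l``.  There are no direct
    IBD -> IBD entries: flips between IBD states across an interval arise
    through paths via NONIBD inside ``expm(t*Q)``.
    """
    g, l = params.g, params.l
    if g <= 0 or l <= 0:
        raise ValueError("rates g and l must be positive")
    Q = np.zeros((N_STATES, N_STATES))
    Q[0, 1:] = g / 4.0
    Q[0, 0] = -g
    for s in range(1, N_STATES):
        Q[s, 0] = l
        Q[s, s] = -l
    return Q


def transition_matrix(Q: np.ndarray, t: float, kappa: float = 1.0) -> np.ndarray:
    """Per-interval transition probabilities ``expm(t*Q)`` with kinship cap.

    Each NONIBD -> Sij entry is clipped to at most ``kappa/4`` (total entry
    probability at most ``kappa``) after exponentiation, the excess being
    returned to the NONIBD -> NONIBD entry so rows still sum to one.

    Parameters
    ----------
    t : genetic length of the interval, Morgans (must be >= 0).
    """
    if t < 0:
        raise ValueError("genetic distance t must be nonnegative (map mis-ordered?)")
    if t == 0.0:
        return np.eye(N_STATES)
    T = expm(t * Q)
    cap = kappa / 4.0
    entry = T[0, 1:]
    excess = np.clip(entry - cap, 0.0, None).sum()
    if excess > 0.0:
        T[0, 1:] = np.minimum(entry, cap)
        T[0, 0] += excess
    return T


def stationary_distribution(params: ModelParams) -> np.ndarray:
    """Stationary distribution of the IBD process with the kinship cap.

    The uncapped chain puts mass ``g/(g+l)`` on IBD; the cap limits the
    unconditional IBD probability to the kinship coefficient, so the chain
    is initialized with IBD mass ``min(g/(g+l), kappa)`` split equally over
    the four IBD states.
    """
    p_ibd = min(params.g / (params.g + params.l), params.kappa)
    pi = np.empty(N_STATES)
    pi[0] = 1.0 - p_ibd
    pi[1:] = p_ibd / 4.0
    return pi


def emission_prob(state: int, d_a: int, d_b: int, f: float) -> float:
    """P(ordered diplotype pair | IBD state) under HWE and the IBS constraint.

    NONIBD: product of the four per-haplotype allele frequencies.  ``Sij``:
    zero if allele ``i`` of *a* differs from allele ``j`` of *b* (the shared
    haplotype must be identical-by-state), otherwise the product of the
    three free allele frequencies with the shared allele counted once.
    """
    if not (0.0 < f < 1.0):
        raise ValueError("minor-allele frequency must lie strictly in (0, 1)")
    return float(emission_table(np.array([f]))[0, state, d_a, d_b])


def emission_table(freqs: np.ndarray) -> np.ndarray:
    """Emission probabilities for every (state, diplotype a, diplotype b).

    Parameters
    ----------
    freqs : (m,) minor-allele frequencies, each strictly in (0, 1).

    Returns
    -------
    (m, 5, 4, 4) array; ``out[j, s, da, db]`` is the probability of the
    ordered diplotype pair ``(da, db)`` under state ``s`` at marker ``j``.
    Each ``out[j, s]`` sums to one over the 16 diplotype pairs.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("minor-allele frequencies must lie strictly in (0, 1)")
    m = freqs.shape[0]
    # per-haplotype allele frequency: allele 1 has freq f, allele 0 has 1-f
    pf = np.stack([1.0 - freqs, freqs], axis=1)  # (m, 2)
    ha = {1: _D_H1, 2: _D_H2}
    out = np.empty((m, N_STATES, N_DIPLOTYPES, N_DIPLOTYPES))
    for da in range(N_DIPLOTYPES):
        for db in range(N_DIPLOTYPES):
            base = (
                pf[:, _D_H1[da]] * pf[:, _D_H2[da]] * pf[:, _D_H1[db]] * pf[:, _D_H2[db]]
            )
            out[:, 0, da, db] = base
            for i in (1, 2):
                for j in (1, 2):
                    s = 2 * (i - 1) + (j - 1) + 1  # S11=1, S12=2, S21=3, S22=4
                    ai = ha[i][da]
                    aj = ha[j][db]
                    if ai != aj:
                        out[:, s, da, db] = 0.0
                    else:
                        # shared allele's frequency counted once
                        out[:, s, da, db] = base / pf[:, ai]
    return out


def genotype_likelihood(observed: int, d: int, epsilon: float) -> float:
    """P(observed genotype | diplotype) with a symmetric error model.

    ``observed`` is a minor-allele dosage in {0, 1, 2} or -1 for missing.
    Returns ``1 - epsilon`` when the dosage of ``d`` matches, ``epsilon/2``
    for each of the two other dosages, and 1 for missing.
    """
    if not (0.0 <= epsilon < 0.5):
        raise ValueError("epsilon must lie in [0, 0.5)")
    if observed == -1:
        return 1.0
    if observed not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {observed!r}")
    return 1.0 - epsilon if DIPLOTYPE_DOSAGE[d] == observed else epsilon / 2.0


def genotype_likelihood_table(genotypes: np.ndarray, epsilon: float) -> np.ndarray:
    """Vectorized genotype likelihoods.

    Parameters
    ----------
    genotypes : integer array of dosages in {0, 1, 2} with -1 for missing.

    Returns
    -------
    array of shape ``genotypes.shape + (4,)`` giving
    P(observed | diplotype d) for every diplotype code d.
    """
    genotypes = np.asarray(genotypes)
    out = np.full(genotypes.shape + (N_DIPLOTYPES,), epsilon / 2.0)
    for d in range(N_DIPLOTYPES):
        out[..., d] = np.where(
            genotypes == DIPLOTYPE_DOSAGE[d], 1.0 - epsilon, epsilon / 2.0
        )
    out[genotypes == -1] = 1.0
    return out


def enumerate_ibd_configurations() -> tuple[list[tuple], list[tuple]]:
    """All IBD configurations of the four haplotypes of a pair, and the
    subset retained by the five-state model.

    A configuration is a set partition of the haplotypes
    ``{a1, a2, b1, b2}`` into IBD classes.  There are 15 such partitions;
    the model keeps the trivial one (no sharing) plus the four in which
    exactly one haplotype of *a* is IBD with exactly one haplotype of *b*.

    Returns
    -------
    (all_partitions, retained) : each partition is a tuple of frozensets.
    """
    items = ("a1", "a2", "b1", "b2")

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield [{head}] + part

    all_parts = [
        tuple(sorted((frozenset(b) for b in p), key=sorted))
        for p in partitions(list(items))
    ]
    all_parts = sorted(set(all_parts), key=lambda p: (len(p), [sorted(b) for b in p]))

    singletons = tuple(sorted((frozenset({x}) for x in items), key=sorted))
    retained = [singletons]
    for i, j in itertools.product(("a1", "a2"), ("b1", "b2")):
        blocks = [frozenset({i, j})] + [
            frozenset({x}) for x in items if x not in (i, j)
        ]
        retained.append(tuple(sorted(blocks, key=sorted)))
    return all_parts, retained
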