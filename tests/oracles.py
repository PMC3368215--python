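"""Independent reference implementations used to verify the package.

Everything here is deliberately brute force: explicit path enumeration,
term-by-term series, per-marker set comparison.  These never share the
inference code paths they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from ibdphase.model_core import (
    DIPLOTYPE_DOSAGE,
    N_DIPLOTYPES,
    N_STATES,
)


def taylor_expm(Q: np.ndarray, t: float, terms: int = 30) -> np.ndarray:
    """Matrix exponential by truncated Taylor series."""
    acc = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms + 1):
        term = term @ (t * Q) / k
        acc = acc + term
    return acc


def obs_terms_bruteforce(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    emit: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """P(g_a, g_b | state) per marker by explicit diplotype loops."""
    m = len(geno_a)
    out = np.zeros((m, N_STATES))
    for j in range(m):
        for s in range(N_STATES):
            tot = 0.0
            for da in range(N_DIPLOTYPES):
                for db in range(N_DIPLOTYPES):
                    la = _gl(geno_a[j], da, epsilon)
                    lb = _gl(geno_b[j], db, epsilon)
                    tot += la * lb * emit[j, s, da, db]
            out[j, s] = tot
    return out


def _gl(obs: int, d: int, eps: float) -> float:
    if obs == -1:
        return 1.0
    return 1.0 - eps if DIPLOTYPE_DOSAGE[d] == obs else eps / 2.0


def enumerate_posteriors(
    obs: np.ndarray, trans: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Exact HMM posteriors by summing over every hidden path.

    ``obs``: (m, 5) per-marker observation terms; ``trans``: (m-1, 5, 5).
    Tractable for m <= 8 (5^8 paths).
    """
    m = obs.shape[0]
    if m > 8:
        raise ValueError("path enumeration is only tractable for m <= 8")
    paths = np.array(list(itertools.product(range(N_STATES), repeat=m)), dtype=np.int8)
    probs = pi[paths[:, 0]] * obs[0, paths[:, 0]]
    for j in range(1, m):
        probs = probs * trans[j - 1][paths[:, j - 1], paths[:, j]] * obs[j, paths[:, j]]
    post = np.zeros((m, N_STATES))
    for j in range(m):
        for s in range(N_STATES):
            post[j, s] = probs[paths[:, j] == s].sum()
    return post / post.sum(axis=1, keepdims=True) if post.sum() else post


def chain_path_costs(graph, s_idx: int, ha: np.ndarray, hb: np.ndarray) -> float:
    """Min cost over every IBD path of one segment chain, diplotypes fixed.

    Enumerates all 5^m paths explicitly.
    """
    k0, k1 = int(graph.seg_ptr[s_idx]), int(graph.seg_ptr[s_idx + 1])
    nk = k1 - k0
    jj = graph.cell_marker[k0:k1]
    paths = np.array(list(itertools.product(range(N_STATES), repeat=nk)))
    costs = graph.cost_0[jj[0]][paths[:, 0], ha[0], hb[0]]
    for k in range(1, nk):
        costs = costs + graph.cost_t[jj[k]][paths[:, k - 1], paths[:, k], ha[k], hb[k]]
    return float(costs.min())


def joint_min_cost(graph, geno) -> float:
    """Global minimum of the factor-graph energy by full enumeration.

    Iterates over every diplotype assignment (4^n_h) and, per assignment,
    enumerates every IBD path of every chain.  Only for toy instances.
    """
    n_h = graph.n_hvars
    best = np.inf
    cells = list(zip(graph.hvar_ind, graph.hvar_marker))
    # no branch pruning: chain terms can be negative (likelihood ratios > 1)
    for combo in itertools.product(range(N_DIPLOTYPES), repeat=n_h):
        h = dict(zip(cells, combo))
        cost = sum(graph.hunary[v, combo[v]] for v in range(n_h))
        for s_idx, seg in enumerate(graph.segments):
            ha = np.array([h[(seg.a, j)] for j in range(seg.start, seg.end)])
            hb = np.array([h[(seg.b, j)] for j in range(seg.start, seg.end)])
            cost += chain_path_costs(graph, s_idx, ha, hb)
        best = min(best, cost)
    return float(best)


def decoded_cost(graph, result, geno) -> float:
    """Energy of the configuration decoded from a Min-Sum result."""
    hmap = np.argmin(result.hbelief, axis=1)
    pmap = result.p_viterbi()
    cost = float(sum(graph.hunary[v, hmap[v]] for v in range(graph.n_hvars)))
    c2h = graph.cell_to_hvar
    for s_idx, seg in enumerate(graph.segments):
        k0, k1 = int(graph.seg_ptr[s_idx]), int(graph.seg_ptr[s_idx + 1])
        for k in range(k0, k1):
            j = int(graph.cell_marker[k])
            da = hmap[c2h[seg.a, j]]
            db = hmap[c2h[seg.b, j]]
            if k == k0:
                cost += graph.cost_0[j, pmap[k], da, db]
            else:
                cost += graph.cost_t[j, pmap[k - 1], pmap[k], da, db]
    return cost


def switch_count_bruteforce(orient_called: np.ndarray, orient_truth: np.ndarray) -> int:
    """Pairwise recount of orientation flips between consecutive sites."""
    n = 0
    for k in range(1, len(orient_called)):
        a = orient_called[k - 1] == orient_truth[k - 1]
        b = orient_called[k] == orient_truth[k]
        if a != b:
            n += 1
    return n


def ibd_overlap_bruteforce(calls, truth_runs, weights, morgans, floor_m):
    """Marker-by-marker sensitivity/FDR for a single pair."""
    m = len(weights)
    called = np.zeros(m, bool)
    for (s, e) in calls:
        called[s:e] = True
    truth_all = np.zeros(m, bool)
    truth_long = np.zeros(m, bool)
    for (s, e) in truth_runs:
        truth_all[s:e] = True
        if morgans[e - 1] - morgans[s] >= floor_m:
            truth_long[s:e] = True
    sens_num = sum(weights[j] for j in range(m) if truth_long[j] and called[j])
    sens_den = sum(weights[j] for j in range(m) if truth_long[j])
    fdr_num = sum(weights[j] for j in range(m) if called[j] and not truth_all[j])
    fdr_den = sum(weights[j] for j in range(m) if called[j])
    return (
        sens_num / sens_den if sens_den else float("nan"),
        fdr_num / fdr_den if fdr_den else float("nan"),
    )
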