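"""Numba kernel for damped Min-Sum sweeps over plausible-segment chains.

All messages live in the negative-log (cost) domain.  For each segment the
IBD-indicator chain is swept forward then backward; during the backward
pass the factor-to-diplotype messages are refreshed and folded into the
running per-variable totals.  Messages are normalized (minimum subtracted)
before the convex damping combination, and the kernel returns the largest
absolute message change of the sweep.

Factor-to-diplotype messages are attenuated by ``alpha`` (normalized
Min-Sum, as used in LDPC decoding): the many short cycles through shared
diplotype variables otherwise recirculate and overcount evidence, letting
one chain's early haplotype-pairing choice lock in against the consensus
of the others.

Layout: cells are (segment, marker) slots, concatenated segment after
segment.  ``fmsg[k]``/``bmsg[k]`` are the messages into the IBD variable of
cell ``k`` from its left/right factor; ``hamsg``/``hbmsg`` are the
factor-to-diplotype messages at cell ``k``; ``htot[v]`` is the diplotype
variable's unary cost plus all incoming messages, so the message *into* a
factor from a diplotype variable is ``htot - own message``.
"""

import numpy as np
from numba import njit

INF = 1e30
#: tiny per-state cost splitting exact label ties (long homozygous
#: stretches leave haplotype pairings exactly tied, which otherwise feeds
#: message oscillation); ties resolve toward the lower-numbered state
TIE_BIAS = 1e-6


@njit(cache=True)
def sweep(
    seg_ptr,
    cell_marker,
    cell_ha,
    cell_hb,
    cost_t,
    cost_0,
    fmsg,
    bmsg,
    hamsg,
    hbmsg,
    htot,
    damping,
    alpha,
):
    max_delta = 0.0
    n_seg = seg_ptr.shape[0] - 1
    in_a = np.empty(4)
    in_b = np.empty(4)
    new_p = np.empty(5)
    new_a = np.empty(4)
    new_b = np.empty(4)
    for s in range(n_seg):
        k0 = seg_ptr[s]
        k1 = seg_ptr[s + 1]
        # ---- forward sweep: messages into p_k from the left factor
        for k in range(k0, k1):
            j = cell_marker[k]
            va = cell_ha[k]
            vb = cell_hb[k]
            for d in range(4):
                in_a[d] = htot[va, d] - hamsg[k, d]
                in_b[d] = htot[vb, d] - hbmsg[k, d]
            if k == k0:
                for p in range(5):
                    best = INF
                    for da in range(4):
                        ca = in_a[da]
                        for db in range(4):
                            v = cost_0[j, p, da, db] + ca + in_b[db]
                            if v < best:
                                best = v
                    new_p[p] = best
            else:
                for p in range(5):
                    best = INF
                    for pp in range(5):
                        base = fmsg[k - 1, pp]
                        for da in range(4):
                            ca = base + in_a[da]
                            for db in range(4):
                                v = cost_t[j, pp, p, da, db] + ca + in_b[db]
                                if v < best:
                                    best = v
                    new_p[p] = best
            for p in range(5):
                new_p[p] += TIE_BIAS * p  # deterministic tie-break to lower states
            mn = new_p[0]
            for p in range(1, 5):
                if new_p[p] < mn:
                    mn = new_p[p]
            for p in range(5):
                upd = damping * fmsg[k, p] + (1.0 - damping) * (new_p[p] - mn)
                d_ = abs(upd - fmsg[k, p])
                if d_ > max_delta:
                    max_delta = d_
                fmsg[k, p] = upd
        # ---- backward sweep: bmsg plus the diplotype messages
        for p in range(5):
            bmsg[k1 - 1, p] = 0.0  # no factor to the right of the last cell
        for k in range(k1 - 1, k0 - 1, -1):
            j = cell_marker[k]
            va = cell_ha[k]
            vb = cell_hb[k]
            for d in range(4):
                in_a[d] = htot[va, d] - hamsg[k, d]
                in_b[d] = htot[vb, d] - hbmsg[k, d]
            for d in range(4):
                new_a[d] = INF
                new_b[d] = INF
            if k == k0:
                for da in range(4):
                    for db in range(4):
                        best = INF
                        for p in range(5):
                            v = cost_0[j, p, da, db] + bmsg[k, p]
                            if v < best:
                                best = v
                        ta = best + in_b[db]
                        if ta < new_a[da]:
                            new_a[da] = ta
                        tb = best + in_a[da]
                        if tb < new_b[db]:
                            new_b[db] = tb
            else:
                for da in range(4):
                    for db in range(4):
                        best = INF
                        for pp in range(5):
                            base = fmsg[k - 1, pp]
                            for p in range(5):
                                v = cost_t[j, pp, p, da, db] + base + bmsg[k, p]
                                if v < best:
                                    best = v
                        ta = best + in_b[db]
                        if ta < new_a[da]:
                            new_a[da] = ta
                        tb = best + in_a[da]
                        if tb < new_b[db]:
                            new_b[db] = tb
            mna = new_a[0]
            mnb = new_b[0]
            for d in range(1, 4):
                if new_a[d] < mna:
                    mna = new_a[d]
                if new_b[d] < mnb:
                    mnb = new_b[d]
            for d in range(4):
                upd = damping * hamsg[k, d] + (1.0 - damping) * alpha * (new_a[d] - mna)
                d_ = abs(upd - hamsg[k, d])
                if d_ > max_delta:
                    max_delta = d_
                htot[va, d] += upd - hamsg[k, d]
                hamsg[k, d] = upd
                upd = damping * hbmsg[k, d] + (1.0 - damping) * alpha * (new_b[d] - mnb)
                d_ = abs(upd - hbmsg[k, d])
                if d_ > max_delta:
                    max_delta = d_
                htot[vb, d] += upd - hbmsg[k, d]
                hbmsg[k, d] = upd
            # message from factor k into p_{k-1} (note in_a/in_b are
            # unchanged by the h updates above: htot and the own message
            # moved by the same amount)
            if k > k0:
                for pp in range(5):
                    best = INF
                    for p in range(5):
                        b1 = bmsg[k, p]
                        for da in range(4):
                            b2 = b1 + in_a[da]
                            for db in range(4):
                                v = cost_t[j, pp, p, da, db] + b2 + in_b[db]
                                if v < best:
                                    best = v
                    new_p[pp] = best + TIE_BIAS * pp
                mn = new_p[0]
                for p in range(1, 5):
                    if new_p[p] < mn:
                        mn = new_p[p]
                for p in range(5):
                    upd = damping * bmsg[k - 1, p] + (1.0 - damping) * (new_p[p] - mn)
                    d_ = abs(upd - bmsg[k - 1, p])
                    if d_ > max_delta:
                        max_delta = d_
                    bmsg[k - 1, p] = upd
    return max_delta
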