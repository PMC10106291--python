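"""Compiled inner loops for two-step choice likelihoods.

The numba kernels replicate the vectorized numpy implementations in
``agents`` trial for trial (same operation order, float64), evaluating all
K parameter samples for all subjects in one call.  Trial padding must be
trailing: rows stop at the first masked trial.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["istl_twostep_ll", "typical_twostep_ll"]


@njit(cache=True)
def _softplus_neg(x):
    # log sigmoid(x) = -log(1 + e^{-x}), stable for large negative x
    if x > -30.0:
        return -np.log1p(np.exp(-x))
    return x


@njit(cache=True)
def istl_twostep_ll(a1, s2, a2, r, mask, g, al, D, bmb, bmf, b2, pst):
    S, T = a1.shape
    K = g.shape[0]
    ll = np.zeros((S, K))
    for s in range(S):
        for k in range(K):
            b0 = 0.5  # P(state 0 | action 0)
            b1 = 0.5  # P(state 0 | action 1)
            qmf0 = 0.0
            qmf1 = 0.0
            q = np.zeros(4)  # Q2[2*state + action]
            prev = -1
            acc = 0.0
            gg = g[k]
            aa = al[k]
            dd = D[k]
            wmb = bmb[k]
            wmf = bmf[k]
            w2 = b2[k]
            ws = pst[k]
            for t in range(T):
                if mask[s, t] == 0.0:
                    break
                v0 = q[0] if q[0] > q[1] else q[1]
                v1 = q[2] if q[2] > q[3] else q[3]
                n0 = wmb * (b0 * v0 + (1.0 - b0) * v1) + wmf * qmf0
                n1 = wmb * (b1 * v0 + (1.0 - b1) * v1) + wmf * qmf1
                if prev == 0:
                    n0 += ws
                elif prev == 1:
                    n1 += ws
                d = n1 - n0
                c1 = a1[s, t]
                acc += _softplus_neg(d if c1 == 1 else -d)
                st = s2[s, t]
                c2 = a2[s, t]
                rw = r[s, t]
                base = 2 * st
                d2 = w2 * (q[base + 1] - q[base])
                acc += _softplus_neg(d2 if c2 == 1 else -d2)
                obs0 = 1.0 if st == 0 else 0.0
                if c1 == 0:
                    b0 += gg * (obs0 - b0)
                    b1 += gg * (0.5 - b1)
                else:
                    b1 += gg * (obs0 - b1)
                    b0 += gg * (0.5 - b0)
                ci = base + c2
                for j in range(4):
                    if j == ci:
                        q[j] += aa * (rw - q[j])
                    else:
                        q[j] *= 1.0 - dd
                if c1 == 0:
                    qmf0 += aa * (rw - qmf0)
                    qmf1 *= 1.0 - dd
                else:
                    qmf1 += aa * (rw - qmf1)
                    qmf0 *= 1.0 - dd
                prev = c1
            ll[s, k] = acc
    return ll


@njit(cache=True)
def typical_twostep_ll(a1, s2, a2, r, mask, bpath, al, D, bmb, bmf, b2, pst):
    """Counting-model likelihood; ``bpath[s, t, a]`` is the inferred
    P(state 0 | action a) before trial t (data-determined)."""
    S, T = a1.shape
    K = al.shape[0]
    ll = np.zeros((S, K))
    for s in range(S):
        for k in range(K):
            qmf0 = 0.0
            qmf1 = 0.0
            q = np.zeros(4)
            prev = -1
            acc = 0.0
            aa = al[k]
            dd = D[k]
            wmb = bmb[k]
            wmf = bmf[k]
            w2 = b2[k]
            ws = pst[k]
            for t in range(T):
                if mask[s, t] == 0.0:
                    break
                b0 = bpath[s, t, 0]
                b1 = bpath[s, t, 1]
                v0 = q[0] if q[0] > q[1] else q[1]
                v1 = q[2] if q[2] > q[3] else q[3]
                n0 = wmb * (b0 * v0 + (1.0 - b0) * v1) + wmf * qmf0
                n1 = wmb * (b1 * v0 + (1.0 - b1) * v1) + wmf * qmf1
                if prev == 0:
                    n0 += ws
                elif prev == 1:
                    n1 += ws
                d = n1 - n0
                c1 = a1[s, t]
                acc += _softplus_neg(d if c1 == 1 else -d)
                st = s2[s, t]
                c2 = a2[s, t]
                rw = r[s, t]
                base = 2 * st
                d2 = w2 * (q[base + 1] - q[base])
                acc += _softplus_neg(d2 if c2 == 1 else -d2)
                ci = base + c2
                for j in range(4):
                    if j == ci:
                        q[j] += aa * (rw - q[j])
                    else:
                        q[j] *= 1.0 - dd
                if c1 == 0:
                    qmf0 += aa * (rw - qmf0)
                    qmf1 *= 1.0 - dd
                else:
                    qmf1 += aa * (rw - qmf1)
                    qmf0 *= 1.0 - dd
                prev = c1
            ll[s, k] = acc
    return ll
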