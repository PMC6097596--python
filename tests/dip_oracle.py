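"""Brute-force dip oracle: grid search over mode location.

For each candidate mode (each distinct data point), the nearest unimodal
cdf is found by linear programming over the cdf values at the data points:
convex (isotonic slope) constraints left of the mode, concave constraints
right of it, monotonicity, and an atom allowed at the mode.  The dip is the
smallest sup-norm band over all modes.  Independent of the package's
modal-interval algorithm; O(n) LPs of size O(n) per sample, so only meant
for small n.
"""

import numpy as np
from scipy.optimize import linprog


def _ecdf_limits(x):
    xs, counts = np.unique(np.asarray(x, float), return_counts=True)
    c = np.cumsum(counts) / counts.sum()
    p = np.concatenate(([0.0], c[:-1]))
    return xs, p, c


def _lp_mode(xs, p, c, k):
    m = len(xs)
    nv = m + 2  # g_0..g_{m-1} (g_k is the pre-atom value), atom value b, e
    ib, ie = m, m + 1
    cost = np.zeros(nv)
    cost[ie] = 1.0
    A, ub = [], []

    def row():
        return np.zeros(nv)

    for i in range(m):
        if i == k:
            for var, target in ((i, p[k]), (ib, c[k])):
                r = row(); r[var] = 1; r[ie] = -1; A.append(r); ub.append(target)
                r = row(); r[var] = -1; r[ie] = -1; A.append(r); ub.append(-target)
        else:
            r = row(); r[i] = 1; r[ie] = -1; A.append(r); ub.append(p[i])
            r = row(); r[i] = -1; r[ie] = -1; A.append(r); ub.append(-c[i])
    seq = list(range(k + 1)) + [ib] + list(range(k + 1, m))
    for u, v in zip(seq[:-1], seq[1:]):
        r = row(); r[u] = 1; r[v] = -1; A.append(r); ub.append(0.0)
    left = list(range(k + 1))
    for j in range(len(left) - 2):
        i0, i1, i2 = left[j : j + 3]
        d10, d21 = xs[i1] - xs[i0], xs[i2] - xs[i1]
        r = row(); r[i0] = -d21; r[i1] = d21 + d10; r[i2] = -d10
        A.append(r); ub.append(0.0)
    right = [ib] + list(range(k + 1, m))
    rx = xs[k:]
    for j in range(len(right) - 2):
        i0, i1, i2 = right[j : j + 3]
        d10, d21 = rx[j + 1] - rx[j], rx[j + 2] - rx[j + 1]
        r = row(); r[i0] = d21; r[i1] = -(d21 + d10); r[i2] = d10
        A.append(r); ub.append(0.0)
    bounds = [(0, 1)] * (m + 1) + [(0, 1)]
    res = linprog(cost, A_ub=np.asarray(A), b_ub=np.asarray(ub), bounds=bounds,
                  method="highs")
    assert res.success, res.message
    return res.fun


def dip_bruteforce(x):
    """Dip statistic by exhaustive mode grid + per-mode LP fit."""
    xs, p, c = _ecdf_limits(x)
    if len(xs) == 1:
        return 0.0
    return min(_lp_mode(xs, p, c, k) for k in range(len(xs)))
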