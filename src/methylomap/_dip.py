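"""Hartigan & Hartigan dip statistic for unimodality testing.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function (convex up to
the mode, concave after; an atom is allowed at the mode).  It is computed by
the classic modal-interval shrinking scheme: fit the greatest convex
minorant (GCM) and least concave majorant (LCM) of F_n on the current
interval, accumulate the ECDF deviations outside the candidate modal
interval, and recurse into it until the GCM/LCM gap no longer exceeds the
accumulated deviation.  The result is exact (up to float rounding), with
D in [1/(2n), 1/4].
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue_montecarlo"]


def _ecdf_limits(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique sorted values with ECDF left limits p and values c."""
    xs, counts = np.unique(np.asarray(x, dtype=float), return_counts=True)
    c = np.cumsum(counts) / counts.sum()
    p = np.concatenate(([0.0], c[:-1]))
    return xs, p, c


def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Indices of the lower convex hull (GCM contact points)."""
    hull = [0]
    for i in range(1, len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (ys[b] - ys[a]) * (xs[i] - xs[a]) >= (ys[i] - ys[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    return _lower_hull(xs, -np.asarray(ys))


def dip_statistic(x) -> float:
    """Exact dip statistic of a 1-D sample (ties allowed)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("dip statistic needs a 1-D sample with n >= 2")
    if np.isnan(x).any():
        raise ValueError("sample contains NaN")
    xs, p, c = _ecdf_limits(x)
    m = len(xs)
    if m == 1:
        # all values identical: a degenerate unimodal cdf fits exactly
        return 0.0
    low, high = 0, m - 1
    D = 0.0
    while True:
        xw = xs[low : high + 1]
        gidx = [low + i for i in _lower_hull(xw, p[low : high + 1])]
        lidx = [low + i for i in _upper_hull(xw, c[low : high + 1])]
        gvals = np.interp(xw, xs[gidx], p[gidx])
        lvals = np.interp(xw, xs[lidx], c[lidx])
        gap = lvals - gvals
        # the GCM/LCM difference is piecewise linear with breakpoints at the
        # hull contact points, so its maximum is attained at a contact;
        # restricting the argmax there avoids interpolation round-off
        # promoting an interior point
        verts = sorted(set(gidx) | set(lidx))
        i_star = max(verts, key=lambda j: gap[j - low])
        d = float(gap[i_star - low])
        if d <= D:
            break
        in_g = i_star in gidx
        in_l = i_star in lidx
        if in_g and in_l:
            new_low = new_high = i_star
        elif in_l:
            new_high = i_star
            new_low = max(j for j in gidx if j <= i_star)
        else:
            new_low = i_star
            new_high = min(j for j in lidx if j >= i_star)
        # ECDF deviations outside the new modal interval; the jump at the
        # modal endpoints is not charged (an atom at the mode is free).
        cl = c[low : new_low + 1].copy()
        cl[-1] = p[new_low]
        dl = float(np.max(cl - gvals[: new_low - low + 1]))
        pr = p[new_high : high + 1].copy()
        pr[0] = c[new_high]
        du = float(np.max(lvals[new_high - low :] - pr))
        D = max(D, dl, du)
        if (new_low, new_high) == (low, high):
            D = max(D, d)
            break
        low, high = new_low, new_high
        if low == high:
            break
    return D / 2.0


def dip_pvalue_montecarlo(
    d: float, n: int, n_boot: int = 2000, seed: int | None = None
) -> float:
    """Monte-Carlo p-value: share of uniform(0,1) samples of size n with
    dip at least as large as ``d`` (add-one correction keeps p in (0, 1])."""
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(size=n)) >= d - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_boot + 1)
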