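"""Per-CpG differential methylation between two sample groups.

The test is a binomial logistic regression of the methylated proportion on
the group indicator with per-sample read totals as weights.  With a single
binary covariate the maximum-likelihood fit is attained at the pooled
per-group proportions, so the likelihood-ratio chi-squared (1 df) has the
closed form of a G-test on the pooled 2x2 (group x methylated/unmethylated)
read-count table; this is what is computed, vectorised over sites.
P-values are converted to q-values with a sliding-linear-model (SLIM-style)
estimate of the null proportion pi0 applied on top of Benjamini-Hochberg,
or with plain Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SiteMatrix

__all__ = [
    "test_dmc",
    "dmc_table",
    "slim_pi0",
    "adjust_q",
    "call_dmcs",
    "dmc_overlap",
]


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    from scipy.special import xlogy

    return xlogy(x, y)


def _lr_gtest(m_t, u_t, m_c, u_c):
    """Likelihood-ratio statistic and p for pooled group counts (arrays)."""
    n_t = m_t + u_t
    n_c = m_c + u_c
    n = n_t + n_c
    m = m_t + m_c
    u = u_t + u_c
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_alt = (
            _xlogy(m_t, m_t / n_t)
            + _xlogy(u_t, u_t / n_t)
            + _xlogy(m_c, m_c / n_c)
            + _xlogy(u_c, u_c / n_c)
        )
        ll_null = _xlogy(m, m / n) + _xlogy(u, u / n)
    g2 = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(g2, df=1)
    return g2, p


def test_dmc(
    counts: pd.DataFrame | Mapping[str, Sequence[tuple[int, int]]],
) -> tuple[float, float]:
    """Differential methylation at one site.

    ``counts`` maps group label ('treat'/'ctrl') to per-sample
    ``(n_meth, n_unmeth)`` pairs.  Returns ``(meth_diff, p_value)`` where
    ``meth_diff`` is the pooled treatment level minus pooled control level in
    percent and p comes from the 1-df likelihood-ratio chi-squared of the
    binomial logistic regression on the group indicator.  Complete
    separation poses no problem: the LR deviance stays finite.
    """
    if isinstance(counts, pd.DataFrame):
        groups = {
            g: list(zip(sub["n_meth"], sub["n_unmeth"]))
            for g, sub in counts.groupby("group")
        }
    else:
        groups = {k: list(v) for k, v in counts.items()}
    if set(groups) != {"treat", "ctrl"} or any(not v for v in groups.values()):
        raise ValueError("need non-empty 'treat' and 'ctrl' groups")
    m_t = sum(m for m, _ in groups["treat"])
    u_t = sum(u for _, u in groups["treat"])
    m_c = sum(m for m, _ in groups["ctrl"])
    u_c = sum(u for _, u in groups["ctrl"])
    if m_t + u_t == 0 or m_c + u_c == 0:
        raise ValueError("one group has zero total coverage")
    _, p = _lr_gtest(
        np.array([m_t], float),
        np.array([u_t], float),
        np.array([m_c], float),
        np.array([u_c], float),
    )
    diff = 100.0 * (m_t / (m_t + u_t) - m_c / (m_c + u_c))
    return float(diff), float(p[0])


def dmc_table(
    sites: SiteMatrix,
    groups: Mapping[str, str],
    adjust: Literal["slim", "bh"] = "slim",
) -> pd.DataFrame:
    """Site-level differential methylation table for a two-group design.

    ``groups`` maps sample id to 'treat' or 'ctrl'.  Returns a frame indexed
    like the site matrix with pooled per-group levels, the methylation
    difference in percent, p and q values.
    """
    labels = pd.Series(groups)
    t_samples = labels.index[labels == "treat"]
    c_samples = labels.index[labels == "ctrl"]
    if len(t_samples) == 0 or len(c_samples) == 0:
        raise ValueError("both groups must contain samples")
    m_t = sites.meth[t_samples].sum(axis=1).to_numpy(float)
    u_t = sites.unmeth[t_samples].sum(axis=1).to_numpy(float)
    m_c = sites.meth[c_samples].sum(axis=1).to_numpy(float)
    u_c = sites.unmeth[c_samples].sum(axis=1).to_numpy(float)
    _, p = _lr_gtest(m_t, u_t, m_c, u_c)
    level_t = m_t / (m_t + u_t)
    level_c = m_c / (m_c + u_c)
    out = pd.DataFrame(
        {
            "level_treat": level_t,
            "level_ctrl": level_c,
            "meth_diff": 100.0 * (level_t - level_c),
            "p_value": p,
        },
        index=sites.meth.index,
    )
    out["q_value"] = adjust_q(out["p_value"].to_numpy(), method=adjust)
    return out


# ---------------------------------------------------------------------------
# q-values


def _bh(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def slim_pi0(
    p: np.ndarray,
    lambdas: Sequence[float] | None = None,
    window: float = 0.05,
) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    For each window start lambda, the ECDF of the p-values on [lambda, 1] is
    fitted by least squares; under uniformity of null p-values the fitted
    slope estimates pi0.  The final estimate is the median over the window
    grid, clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 1.0
    if lambdas is None:
        lambdas = np.round(np.arange(0.1, 0.9001, window), 10)
    n = p.size
    ps = np.sort(p)
    ecdf_at = lambda t: np.searchsorted(ps, t, side="right") / n
    slopes = []
    for lam in lambdas:
        xs = ps[(ps >= lam) & (ps <= 1.0)]
        # fit F(t) ~ a + b t on the tail; include the window endpoints so a
        # signal-free tail with no points still yields a slope
        ts = np.concatenate(([lam], xs, [1.0]))
        fs = ecdf_at(ts)
        if ts.size < 2 or np.ptp(ts) == 0:
            continue
        b = np.polyfit(ts, fs, 1)[0]
        slopes.append(b)
    if not slopes:
        return 1.0
    pi0 = float(np.median(slopes))
    return min(1.0, max(pi0, 1.0 / n))


def adjust_q(
    p_values, method: Literal["slim", "bh"] = "slim", **slim_kwargs
) -> np.ndarray:
    """Convert p-values to q-values (SLIM-style pi0 x BH, or plain BH)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    bh = _bh(p)
    if method == "bh":
        return bh
    if method == "slim":
        return np.minimum(slim_pi0(p, **slim_kwargs) * bh, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# DMC calling


MAGNITUDE_FLAGS = (25.0, 50.0, 90.0)


def call_dmcs(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Select DMCs at q < fdr and annotate direction and magnitude.

    Adds ``direction`` (hyper when the treatment level is higher),
    ``magnitude_gt_25/50/90`` flags on |meth_diff|, and ``hm_origin`` (the
    HM/LM class of the pooled control level).
    """
    dmc = results[results["q_value"] < fdr].copy()
    dmc["direction"] = np.where(dmc["meth_diff"] > 0, "hyper", "hypo")
    for flag in MAGNITUDE_FLAGS:
        dmc[f"magnitude_gt_{int(flag)}"] = dmc["meth_diff"].abs() > flag
    dmc["hm_origin"] = np.where(dmc["level_ctrl"] > 0.5, "HM", "LM")
    return dmc


def dmc_overlap(dmc_sets: Mapping[str, set]) -> pd.DataFrame:
    """Pairwise overlap of DMC site sets.

    Reports the Jaccard fraction |A n B| / |A u B| and the per-set shared
    fractions for every unordered pair of conditions.
    """
    rows = []
    for a, b in combinations(sorted(dmc_sets), 2):
        sa, sb = set(dmc_sets[a]), set(dmc_sets[b])
        inter = len(sa & sb)
        union = len(sa | sb)
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_a": len(sa),
                "n_b": len(sb),
                "n_shared": inter,
                "jaccard": inter / union if union else np.nan,
                "frac_of_a": inter / len(sa) if sa else np.nan,
                "frac_of_b": inter / len(sb) if sb else np.nan,
            }
        )
    return pd.DataFrame(rows)
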