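"""Distance-based CpG cluster detection with a geometric-null p-value.

Consecutive CpGs closer than the median inter-CpG distance chain into
proto-clusters; each proto-cluster is scored against a null of independent
CpG placement (per-base probability rho = total CpGs / covered genome
length), under which the span of N CpGs follows a negative-binomial law.
Clusters passing ``p < p_threshold`` are retained.
"""

from __future__ import annotations

import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["detect_cpg_clusters", "cluster_summary", "write_clusters_bed"]


def _as_position_map(cpg_positions) -> dict[str, np.ndarray]:
    if isinstance(cpg_positions, pd.DataFrame):
        return {
            str(c): np.sort(g["pos"].to_numpy())
            for c, g in cpg_positions.groupby("chrom")
        }
    return {str(c): np.sort(np.asarray(v)) for c, v in cpg_positions.items()}


def detect_cpg_clusters(
    cpg_positions: Mapping[str, Sequence[int]] | pd.DataFrame,
    p_threshold: float = 1e-5,
    median_scope: Literal["genome", "chromosome"] = "genome",
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Detect significant CpG clusters from CpG dyad positions.

    Steps: inter-CpG distances per chromosome; distance threshold = the
    median distance (genome-wide by default, per chromosome optionally);
    maximal runs of consecutive CpGs at distance <= threshold with at least
    two CpGs form proto-clusters; the negative-binomial tail probability of
    observing a span at most as compact gives the p-value, and clusters with
    ``p < p_threshold`` are returned as a BED-like frame sorted by position.

    ``genome_length``, when given, is the covered genome size used for the
    null density rho; otherwise the spanned length per chromosome is used.
    """
    pos_map = _as_position_map(cpg_positions)
    pos_map = {c: p[np.concatenate(([True], np.diff(p) > 0))] if len(p) else p
               for c, p in pos_map.items()}
    all_dists = np.concatenate(
        [np.diff(p) for p in pos_map.values() if len(p) >= 2] or [np.array([])]
    )
    if all_dists.size == 0:
        return _empty_clusters()
    n_cpgs_total = sum(len(p) for p in pos_map.values())
    if genome_length is None:
        genome_length = int(
            sum(p[-1] - p[0] + 1 for p in pos_map.values() if len(p))
        )
    rho = n_cpgs_total / genome_length
    genome_median = float(np.median(all_dists))
    rows = []
    for chrom in sorted(pos_map):
        p = pos_map[chrom]
        if len(p) < 2:
            continue
        dists = np.diff(p)
        thr = (
            genome_median
            if median_scope == "genome"
            else float(np.median(dists))
        )
        close = dists <= thr
        if close.all():
            warnings.warn(
                f"{chrom}: all inter-CpG distances at or below the median "
                "threshold; one degenerate run spans the chromosome"
            )
        # maximal runs of consecutive close gaps
        boundaries = np.flatnonzero(np.diff(close.astype(int)))
        starts = [0] if close[0] else []
        starts += [b + 1 for b in boundaries if close[b + 1]]
        for s in starts:
            e = s
            while e < len(close) and close[e]:
                e += 1
            first, last = p[s], p[e]  # run covers CpGs s..e inclusive
            n = e - s + 1
            span = int(last - first + 1)
            pval = _cluster_pvalue(n, span, rho)
            rows.append((chrom, int(first), int(last + 1), n, span, pval))
    clusters = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpgs", "length", "p_value"]
    )
    clusters = clusters[clusters["p_value"] < p_threshold]
    return clusters.sort_values(["chrom", "start"]).reset_index(drop=True)


def _cluster_pvalue(n_cpgs: int, span: int, rho: float) -> float:
    """P(span of n_cpgs independently placed CpGs <= observed span).

    Under per-base placement probability rho, the n-1 inter-CpG gaps are
    geometric (support >= 1); their sum minus (n-1) is negative binomial.
    """
    if n_cpgs < 2:
        return 1.0
    k = span - 1 - (n_cpgs - 1)  # extra bases beyond the minimum possible span
    return float(stats.nbinom.cdf(k, n_cpgs - 1, rho))


def _empty_clusters() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "n_cpgs", "length", "p_value"]
    )


def cluster_summary(
    clusters: pd.DataFrame,
    all_cpgs: pd.DataFrame,
    genes: list | None = None,
) -> dict:
    """Summary statistics of a cluster set.

    Returns cluster count, mean length, mean CpGs per cluster, the percent
    of all CpGs inside clusters, and (when gene models are given) the
    fraction of clusters overlapping each feature class.
    """
    out = {
        "n_clusters": int(len(clusters)),
        "mean_length": float(clusters["length"].mean()) if len(clusters) else np.nan,
        "mean_cpgs_per_cluster": (
            float(clusters["n_cpgs"].mean()) if len(clusters) else np.nan
        ),
    }
    in_cluster = np.zeros(len(all_cpgs), dtype=bool)
    by_chrom = {c: g for c, g in clusters.groupby("chrom")}
    pos_arr = all_cpgs["pos"].to_numpy()
    for i, (chrom, pos) in enumerate(zip(all_cpgs["chrom"], pos_arr)):
        g = by_chrom.get(chrom)
        if g is None:
            continue
        j = np.searchsorted(g["start"].to_numpy(), pos, side="right") - 1
        if j >= 0 and pos < g["end"].to_numpy()[j]:
            in_cluster[i] = True
    out["pct_cpgs_in_clusters"] = (
        100.0 * in_cluster.mean() if len(all_cpgs) else np.nan
    )
    if genes:
        from .landscape import assign_feature

        mids = clusters.assign(pos=(clusters["start"] + clusters["end"]) // 2)
        feats = assign_feature(mids[["chrom", "pos"]], genes)["feature"]
        classes = feats.str.replace(r"_\d+$", "", regex=True)
        out["feature_overlap_fractions"] = (
            classes.value_counts(normalize=True).to_dict() if len(mids) else {}
        )
    return out


def write_clusters_bed(clusters: pd.DataFrame, path) -> None:
    """BED export: chrom, start, end, name, -log10 p."""
    with open(path, "w") as fh:
        for i, row in clusters.reset_index(drop=True).iterrows():
            score = -np.log10(max(row["p_value"], 1e-300))
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"cluster_{i + 1}\t{score:.3f}\n"
            )
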