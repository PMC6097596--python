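"""Coupling of gene-body methylation with gene expression.

Gene-level feature methylation summaries (exon 1, exons 2-4, 1 kb
upstream), FPKM conversion, the methylation-quantile versus expression
regression, Kruskal-Wallis comparison of expression densities across
methylation classes, and the direction concordance of differentially
methylated CpGs with differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .landscape import feature_intervals, _overlap_join

__all__ = [
    "fpkm",
    "exclude_overlapping_genes",
    "gene_feature_methylation",
    "QuantileRegressionResult",
    "quantile_meth_expr_regression",
    "expression_density_by_meth_class",
    "dmc_expression_concordance",
]

GENE_FEATURES = ("exon1", "exons2_4", "upstream1kb")


def fpkm(count, gene_length_bp, total_counts) -> np.ndarray | float:
    """Fragments per kilobase of gene per million mapped reads.

    ``count * 1e9 / (gene_length_bp * total_counts)``; invariant to global
    rescaling of all counts together with the total.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    if np.any(length <= 0) or not np.all(np.asarray(total_counts) > 0):
        raise ValueError("gene length and total counts must be positive")
    out = count * 1e9 / (length * float(total_counts))
    return float(out) if out.ndim == 0 else out


def exclude_overlapping_genes(
    genes: list[GeneModel], include_flanks: bool = False
) -> list[GeneModel]:
    """Drop every gene whose exons intersect another gene's exons.

    With ``include_flanks`` the comparison uses the gene span extended by
    the 1 kb flanks (the stricter rule used for cross-species homolog
    analyses); both members of an overlapping pair are removed.
    """
    spans = []
    for g in genes:
        lo, hi = g.span(with_flanks=include_flanks)
        spans.append((g.chrom, lo, hi, g))
    bad: set[str] = set()
    by_chrom: dict[str, list] = {}
    for chrom, lo, hi, g in spans:
        by_chrom.setdefault(chrom, []).append((lo, hi, g))
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[0])
        # sweep keeping genes whose span is still open
        active: list[tuple[int, GeneModel]] = []
        for lo, hi, g in items:
            active = [(h, a) for h, a in active if h > lo]
            for h, a in active:
                if include_flanks or _exons_intersect(a, g):
                    bad.add(a.gene_id)
                    bad.add(g.gene_id)
            active.append((hi, g))
    return [g for g in genes if g.gene_id not in bad]


def _exons_intersect(g1: GeneModel, g2: GeneModel) -> bool:
    e1 = sorted(g1.exons)
    e2 = sorted(g2.exons)
    i = j = 0
    while i < len(e1) and j < len(e2):
        a1, b1 = e1[i]
        a2, b2 = e2[j]
        if a1 < b2 and a2 < b1:
            return True
        if b1 <= b2:
            i += 1
        else:
            j += 1
    return False


def gene_feature_methylation(
    sites: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Per-gene mean methylation of exon 1, exons 2-4 and the upstream 1 kb.

    ``sites`` needs columns chrom, pos, level.  Zero-level CpGs are excluded
    (they dominate sparsely methylated genomes); a feature with no
    qualifying CpG is missing (NaN).  Genes with fewer than four exons use
    the exons available from exon 2 on; single-exon genes have no exons 2-4
    value.  Also reports the per-feature HM class of the mean.
    """
    sites = sites[sites["level"].notna() & (sites["level"] > 0)]
    intervals = feature_intervals(genes)
    exon_feats = {"exon_2", "exon_3", "exon_4"}
    sel = intervals["feature"].isin({"exon_1", "upstream_1kb"} | exon_feats)
    intervals = intervals[sel]
    hits = _overlap_join(sites[["chrom", "pos"]], intervals)
    summaries = pd.DataFrame(
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=[f"mean_meth_{f}" for f in GENE_FEATURES],
        dtype=float,
    )
    if len(hits):
        joined = hits.join(intervals, on="interval_row")
        joined["level"] = sites["level"].to_numpy()[
            sites.index.get_indexer(joined["site_row"])
        ]
        feat_group = np.select(
            [
                joined["feature"].eq("exon_1"),
                joined["feature"].isin(exon_feats),
                joined["feature"].eq("upstream_1kb"),
            ],
            ["exon1", "exons2_4", "upstream1kb"],
            default="",
        )
        joined["feat_group"] = feat_group
        means = joined.groupby(["gene_id", "feat_group"])["level"].mean()
        for feat in GENE_FEATURES:
            col = f"mean_meth_{feat}"
            if feat in means.index.get_level_values(1):
                vals = means.xs(feat, level=1)
                summaries.loc[vals.index, col] = vals
    for feat in GENE_FEATURES:
        col = f"mean_meth_{feat}"
        summaries[f"hm_class_{feat}"] = np.where(
            summaries[col].isna(),
            None,
            np.where(summaries[col] > 0.5, "HM", "LM"),
        )
    return summaries.reset_index()


@dataclass
class QuantileRegressionResult:
    """OLS of mean expression on mean methylation over methylation quantiles."""

    n_genes: int
    n_quantiles: int
    genes_per_quantile: float
    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    quantile_table: pd.DataFrame = field(repr=False)


def quantile_meth_expr_regression(
    summaries: pd.DataFrame,
    expression: pd.Series,
    feature: str = "exons2_4",
    n_quantiles: int = 100,
) -> QuantileRegressionResult:
    """Group genes into methylation quantiles and regress expression on them.

    Genes are ranked by their ``feature`` methylation (ties broken by stable
    gene-id order) and split into ``n_quantiles`` near-equal groups; the
    group's mean methylation is regressed against the group's mean
    expression (FPKM) by ordinary least squares.
    """
    import statsmodels.api as sm

    if feature not in GENE_FEATURES:
        raise ValueError(f"feature must be one of {GENE_FEATURES}")
    col = f"mean_meth_{feature}"
    df = summaries[["gene_id", col]].copy()
    df["expr"] = df["gene_id"].map(expression)
    df = df.dropna(subset=[col, "expr"])
    df = df.sort_values([col, "gene_id"], kind="stable").reset_index(drop=True)
    n = len(df)
    if n < 2 * 2:
        raise ValueError("too few genes with methylation and expression data")
    n_q = min(n_quantiles, n)
    df["quantile"] = (np.arange(n) * n_q) // n
    grouped = df.groupby("quantile").agg(
        mean_meth=(col, "mean"), mean_expr=("expr", "mean"), n_genes=("expr", "size")
    )
    if grouped["mean_meth"].nunique() < 2:
        raise ValueError("methylation is constant across quantiles")
    X = sm.add_constant(grouped["mean_meth"].to_numpy())
    fit = sm.OLS(grouped["mean_expr"].to_numpy(), X).fit()
    return QuantileRegressionResult(
        n_genes=n,
        n_quantiles=int(grouped.shape[0]),
        genes_per_quantile=float(grouped["n_genes"].mean()),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        quantile_table=grouped.reset_index(),
    )


def expression_density_by_meth_class(
    summaries: pd.DataFrame,
    expression: pd.Series,
    feature: str = "exons2_4",
) -> dict:
    """Kruskal-Wallis comparison of expression across methylation classes.

    Genes are grouped as HM (feature mean > 0.5), LM (0 < mean <= 0.5) and
    unmethylated (no nonzero CpG in the feature); the tie-corrected
    Kruskal-Wallis H compares their expression distributions.
    """
    col = f"mean_meth_{feature}"
    df = summaries[["gene_id", col]].copy()
    df["expr"] = df["gene_id"].map(expression)
    df = df.dropna(subset=["expr"])
    hm = df.loc[df[col] > 0.5, "expr"]
    lm = df.loc[(df[col] <= 0.5) & df[col].notna(), "expr"]
    un = df.loc[df[col].isna(), "expr"]
    groups = {"HM": hm, "LM": lm, "unmethylated": un}
    nonempty = {k: v for k, v in groups.items() if len(v)}
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty methylation classes")
    H, p = stats.kruskal(*nonempty.values())
    return {
        "H": float(H),
        "p_value": float(p),
        "group_sizes": {k: int(len(v)) for k, v in groups.items()},
        "group_median_expr": {
            k: float(np.median(v)) if len(v) else np.nan for k, v in groups.items()
        },
    }


def dmc_expression_concordance(
    dmcs: pd.DataFrame,
    de_table: pd.DataFrame,
    min_abs_meth_diff: float = 50.0,
    min_abs_log2fc: float = 0.0,
    max_adj_p: float = 1.0,
) -> dict:
    """Direction concordance of exon-2-4 DMCs with expression changes.

    ``dmcs`` needs columns gene_id and meth_diff (already restricted to the
    gene features of interest); ``de_table`` is per-gene with columns
    gene_id, log2fc and adj_p.  DMCs with |meth_diff| above the threshold
    are crossed with their gene's expression direction in a 2x2 chi-squared
    independence test (no continuity correction), counted at DMC level.
    """
    de = de_table.set_index("gene_id")
    sel = dmcs[dmcs["meth_diff"].abs() > min_abs_meth_diff].copy()
    sel["log2fc"] = sel["gene_id"].map(de["log2fc"])
    if "adj_p" in de.columns and max_adj_p < 1.0:
        sel["adj_p"] = sel["gene_id"].map(de["adj_p"])
        sel = sel[sel["adj_p"] < max_adj_p]
    if min_abs_log2fc > 0:
        sel = sel[sel["log2fc"].abs() > min_abs_log2fc]
    sel = sel.dropna(subset=["log2fc"])
    sel = sel[(sel["log2fc"] != 0) & (sel["meth_diff"] != 0)]
    meth_up = sel["meth_diff"] > 0
    expr_up = sel["log2fc"] > 0
    table = np.array(
        [
            [int((meth_up & expr_up).sum()), int((meth_up & ~expr_up).sum())],
            [int((~meth_up & expr_up).sum()), int((~meth_up & ~expr_up).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a margin of the 2x2 direction table is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    concordant = (table[0, 0] + table[1, 1]) / table.sum()
    return {
        "chi2": float(chi2),
        "p_value": float(p),
        "concordant_fraction": float(concordant),
        "n_dmcs": int(table.sum()),
        "n_genes": int(sel["gene_id"].nunique()),
        "table": table,
    }
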