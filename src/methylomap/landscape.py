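"""Genome-wide methylation landscape profiling.

Covers per-site methylation levels and their HM/LM dichotomy (high
methylation strictly above 50%), global methylation, bimodality testing
with the dip statistic, assignment of CpGs to gene features, the 101-bin
scaled metagene profile, and the chi-squared enrichment of highly
methylated CpGs across feature categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._dip import dip_pvalue_montecarlo, dip_statistic
from .io_formats import GeneModel

__all__ = [
    "methylation_level",
    "classify_hm_lm",
    "global_methylation",
    "DipResult",
    "dip_test",
    "feature_intervals",
    "assign_feature",
    "MetageneProfile",
    "metagene_profile",
    "hm_feature_enrichment",
]

N_BINS = 101


def methylation_level(n_meth, n_unmeth):
    """Fraction of reads supporting methylation; undefined at zero coverage."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    cov = n_meth + n_unmeth
    if np.any(cov <= 0):
        raise ValueError("methylation level undefined at zero coverage")
    out = n_meth / cov
    return float(out) if out.ndim == 0 else out


def classify_hm_lm(level):
    """'HM' for level strictly above 0.5, otherwise 'LM' (ties are LM)."""
    arr = np.asarray(level, dtype=float)
    out = np.where(arr > 0.5, "HM", "LM")
    return str(out) if arr.ndim == 0 else out


def global_methylation(levels) -> float:
    """Unweighted mean of per-site levels, in percent."""
    arr = np.asarray(levels, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no sites with defined methylation level")
    return float(arr.mean() * 100.0)


@dataclass(frozen=True)
class DipResult:
    D: float
    p_value: float
    n: int


def dip_test(levels, n_boot: int = 2000, seed: int | None = None) -> DipResult:
    """Dip test of unimodality with a seeded Monte-Carlo p-value.

    The null distribution of the dip is simulated from uniform(0,1) samples
    of the same size, which is the least favourable unimodal null.
    """
    arr = np.asarray(levels, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        raise ValueError("dip test needs at least 4 observations")
    d = dip_statistic(arr)
    p = dip_pvalue_montecarlo(d, arr.size, n_boot=n_boot, seed=seed)
    return DipResult(D=d, p_value=p, n=int(arr.size))


# ---------------------------------------------------------------------------
# feature assignment


def feature_intervals(genes: list[GeneModel], max_exons: int | None = None) -> pd.DataFrame:
    """Flatten gene models into one row per (gene, feature) interval.

    Features are labelled in transcription order: ``upstream_1kb``,
    ``exon_k`` / ``intron_k`` (k starting at 1 at the 5' end), and
    ``downstream_1kb``.  ``feature_index`` numbers exons/introns; flanks get
    index 0.
    """
    rows = []
    for g in genes:
        rows.append((g.chrom, *g.upstream_flank, g.gene_id, "upstream_1kb", 0))
        for k, (a, b) in enumerate(g.exons, start=1):
            if max_exons is not None and k > max_exons:
                break
            rows.append((g.chrom, a, b, g.gene_id, f"exon_{k}", k))
        for k, (a, b) in enumerate(g.introns, start=1):
            if max_exons is not None and k > max_exons:
                break
            rows.append((g.chrom, a, b, g.gene_id, f"intron_{k}", k))
        rows.append((g.chrom, *g.downstream_flank, g.gene_id, "downstream_1kb", 0))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "feature", "feature_index"]
    )
    return df[df["end"] > df["start"]].reset_index(drop=True)


def _overlap_join(sites: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Join sites (chrom, pos) to all covering intervals (inner join)."""
    out = []
    ivs = {c: g.sort_values("start") for c, g in intervals.groupby("chrom")}
    for chrom, grp in sites.groupby("chrom", sort=False):
        if chrom not in ivs:
            continue
        iv = ivs[chrom]
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        pos = grp["pos"].to_numpy()
        # candidate window: intervals with start <= pos; verify end > pos.
        # intervals may nest, so scan back while starts can still cover.
        order = np.argsort(pos, kind="stable")
        hi = np.searchsorted(starts, pos, side="right")
        max_len = int((ends - starts).max()) if len(iv) else 0
        for row_i, h in zip(grp.index[order], hi[order]):
            p = sites.at[row_i, "pos"]
            j = h - 1
            while j >= 0 and starts[j] > p - max_len:
                if starts[j] <= p < ends[j]:
                    out.append((row_i, iv.index[j]))
                j -= 1
    if not out:
        return pd.DataFrame(columns=["site_row", "interval_row"])
    return pd.DataFrame(out, columns=["site_row", "interval_row"])


def assign_feature(sites: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Label each site with its gene feature, or 'intergenic'.

    Exons take precedence over introns and flanks within the same gene (an
    exon of one transcript can sit in another's intron after merging).
    Sites falling in features of more than one gene keep the label of the
    first gene encountered and are flagged ``ambiguous``.
    """
    intervals = feature_intervals(genes)
    hits = _overlap_join(sites[["chrom", "pos"]], intervals)
    feature = pd.Series("intergenic", index=sites.index, dtype=object)
    gene_id = pd.Series(pd.NA, index=sites.index, dtype=object)
    ambiguous = pd.Series(False, index=sites.index)
    if len(hits):
        joined = hits.join(intervals, on="interval_row")
        rank = joined["feature"].str.startswith("exon").map({True: 0, False: 1})
        joined = joined.assign(_rank=rank).sort_values(
            ["site_row", "_rank", "interval_row"], kind="stable"
        )
        n_genes = joined.groupby("site_row")["gene_id"].nunique()
        first = joined.drop_duplicates("site_row").set_index("site_row")
        feature.loc[first.index] = first["feature"]
        gene_id.loc[first.index] = first["gene_id"]
        ambiguous.loc[n_genes.index[n_genes > 1]] = True
    return pd.DataFrame(
        {"feature": feature, "gene_id": gene_id, "ambiguous": ambiguous}
    )


# ---------------------------------------------------------------------------
# metagene profile


@dataclass
class MetageneProfile:
    """101-bin scaled methylation profile per feature track.

    ``table`` has columns feature, bin, mean, n_cpgs, smoothed; features are
    tracks aggregated across genes by transcription-order index (upstream,
    exon_1..exon_K, intron_1.., last_exon, downstream).
    """

    table: pd.DataFrame

    def track(self, feature: str) -> pd.DataFrame:
        return self.table[self.table["feature"] == feature].reset_index(drop=True)

    @property
    def features(self) -> list[str]:
        return list(dict.fromkeys(self.table["feature"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _relative_bin(offset: np.ndarray, length: int) -> np.ndarray:
    return np.minimum((N_BINS * offset) // length, N_BINS - 1).astype(int)


def metagene_profile(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    max_exons: int = 6,
    exclude_zero: bool = True,
    loess_frac: float = 0.3,
) -> MetageneProfile:
    """Average methylation across genes in 101 bins of scaled features.

    ``sites`` must have columns chrom, pos, level.  Each feature of each
    gene is scaled to 101 relative-position bins
    (``bin = floor(101 * offset / length)`` clamped to 100, with offset
    measured in transcription orientation); levels are averaged over all
    genes' CpGs landing in the same bin of the same feature track.  Zero
    levels are excluded by default since they dominate sparsely methylated
    genomes.  A lowess curve over the bins is returned per track.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if not genes:
        raise ValueError("no gene models supplied")
    sites = sites[~sites["level"].isna()]
    if exclude_zero:
        sites = sites[sites["level"] > 0]
    intervals = feature_intervals(genes, max_exons=max_exons)
    gene_strand = {g.gene_id: g.strand for g in genes}
    gene_last_exon = {g.gene_id: g.n_exons for g in genes}
    hits = _overlap_join(sites[["chrom", "pos"]], intervals)
    acc: dict[tuple[str, int], list[float]] = {}
    if len(hits):
        joined = hits.join(intervals, on="interval_row")
        joined["level"] = sites["level"].to_numpy()[
            sites.index.get_indexer(joined["site_row"])
        ]
        pos = sites["pos"].to_numpy()[sites.index.get_indexer(joined["site_row"])]
        length = (joined["end"] - joined["start"]).to_numpy()
        fwd = joined["gene_id"].map(gene_strand).eq("+").to_numpy()
        offset = np.where(fwd, pos - joined["start"], joined["end"] - 1 - pos)
        bins = np.minimum((N_BINS * offset) // length, N_BINS - 1).astype(int)
        is_last = (
            joined["feature"].str.startswith("exon_")
            & (
                joined["feature_index"]
                == joined["gene_id"].map(gene_last_exon)
            )
        ).to_numpy()
        for feat, b, lev, last in zip(
            joined["feature"], bins, joined["level"], is_last
        ):
            acc.setdefault((feat, int(b)), []).append(float(lev))
            if last:
                acc.setdefault(("last_exon", int(b)), []).append(float(lev))
    feature_order = (
        ["upstream_1kb"]
        + [f"exon_{k}" for k in range(1, max_exons + 1)]
        + [f"intron_{k}" for k in range(1, max_exons)]
        + ["last_exon", "downstream_1kb"]
    )
    rows = []
    for feat in feature_order:
        for b in range(N_BINS):
            vals = acc.get((feat, b), [])
            rows.append(
                (feat, b, float(np.mean(vals)) if vals else np.nan, len(vals))
            )
    table = pd.DataFrame(rows, columns=["feature", "bin", "mean", "n_cpgs"])
    smoothed = np.full(len(table), np.nan)
    for feat in feature_order:
        mask = (table["feature"] == feat).to_numpy()
        sub = table[mask]
        ok = sub["mean"].notna().to_numpy()
        if ok.sum() >= 5:
            fit = lowess(
                sub["mean"].to_numpy()[ok],
                sub["bin"].to_numpy()[ok],
                frac=loess_frac,
                return_sorted=False,
            )
            vals = np.full(N_BINS, np.nan)
            vals[sub["bin"].to_numpy()[ok]] = fit
            smoothed[mask] = vals
    table["smoothed"] = smoothed
    return MetageneProfile(table=table)


# ---------------------------------------------------------------------------
# HM enrichment


def hm_feature_enrichment(annotated: pd.DataFrame) -> dict:
    """Chi-squared goodness of fit of HM CpG counts across feature classes.

    ``annotated`` needs columns ``feature`` and ``hm_class``.  Expected HM
    counts are proportional to the all-CpG count of each feature class
    (df = k - 1).  Returns the statistic, p-value and per-feature HM
    fractions.
    """
    total = annotated["feature"].value_counts()
    hm = annotated.loc[annotated["hm_class"] == "HM", "feature"].value_counts()
    cats = total.index
    if len(cats) < 2:
        raise ValueError("need at least two feature categories")
    observed = hm.reindex(cats).fillna(0).to_numpy(dtype=float)
    n_hm = observed.sum()
    expected = n_hm * (total / total.sum()).to_numpy(dtype=float)
    if np.any(expected < 5):
        import warnings

        warnings.warn("expected HM count below 5 in some category")
    chi2, p = stats.chisquare(observed, expected)
    return {
        "chi2": float(chi2),
        "p_value": float(p),
        "df": len(cats) - 1,
        "hm_fraction_by_feature": dict(
            zip(cats, (observed / n_hm) if n_hm else observed)
        ),
        "observed": dict(zip(cats, observed.astype(int))),
        "expected": dict(zip(cats, expected)),
    }
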