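"""Cross-species conservation of methylation and expression.

Orthogroups are assigned to conservation categories from the clades of
their member species; orthogroup-level methylation and expression profiles
are built from feature-selected gene means (exons 2-4 in arthropods, exon 1
in vertebrates, whose scale is reversed because exon-1 methylation
anticorrelates with expression there), min-max scaled per species, and
jointly clustered.  Homologous gene pairs are also compared directly by
ranked methylation with tree cutting, and the conservation signal is
summarised by the rank-sum of methylation and expression per category.
A generic hypergeometric over-representation test rounds the module off.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CATEGORIES",
    "assign_category",
    "orthogroup_meth_expr",
    "joint_cluster",
    "ranked_methylation_clustering",
    "ranked_sum_conservation",
    "top_n_by_methylation",
    "hypergeometric_ora",
]

CATEGORIES = (
    "species_specific",
    "daphnia_specific",
    "hymenoptera_specific",
    "arthropod_specific",
    "mammal_specific",
    "common",
)

ARTHROPOD_CLADES = {"daphnia", "hymenoptera"}


def assign_category(
    species: Sequence[str], clade_map: Mapping[str, str]
) -> str:
    """Conservation category of an orthogroup from its member species.

    One species only: species_specific.  All members within one arthropod
    clade: daphnia_specific / hymenoptera_specific.  Spanning both arthropod
    clades but no mammal: arthropod_specific.  Mammals only: mammal_specific.
    At least one arthropod and one mammal: common.
    """
    sp = set(species)
    if not sp:
        raise ValueError("orthogroup without member species")
    missing = sp - set(clade_map)
    if missing:
        raise KeyError(f"species missing from clade map: {sorted(missing)}")
    clades = {clade_map[s] for s in sp}
    bad = clades - (ARTHROPOD_CLADES | {"mammal"})
    if bad:
        raise ValueError(f"unknown clade(s) {sorted(bad)}")
    if len(sp) == 1:
        return "species_specific"
    has_mammal = "mammal" in clades
    has_arthropod = bool(clades & ARTHROPOD_CLADES)
    if has_mammal and has_arthropod:
        return "common"
    if has_mammal:
        return "mammal_specific"
    if clades == {"daphnia"}:
        return "daphnia_specific"
    if clades == {"hymenoptera"}:
        return "hymenoptera_specific"
    return "arthropod_specific"


def _minmax(x: pd.Series) -> pd.Series:
    lo, hi = x.min(), x.max()
    if not np.isfinite(lo) or hi == lo:
        return pd.Series(np.where(x.notna(), 0.5, np.nan), index=x.index)
    return (x - lo) / (hi - lo)


def orthogroup_meth_expr(
    gene_summaries: pd.DataFrame,
    expression: pd.DataFrame,
    orthogroups: pd.DataFrame,
    clade_map: Mapping[str, str],
) -> pd.DataFrame:
    """Orthogroup-level scaled methylation and expression per species.

    ``gene_summaries`` is the per-gene feature methylation table with a
    ``species`` column; ``expression`` has columns gene_id, species, expr.
    The feature is selected by clade (arthropods: exons 2-4, mammals:
    exon 1).  Gene values are averaged within orthogroup and species,
    min-max scaled across orthogroups per species, and the methylation
    scale is reversed (1 - scaled) for mammals.
    """
    gm = gene_summaries.set_index(["species", "gene_id"])
    ex = expression.set_index(["species", "gene_id"])["expr"]
    rows = []
    for (og, species), grp in orthogroups.groupby(["orthogroup_id", "species"]):
        clade = clade_map.get(species)
        if clade is None:
            raise KeyError(f"species {species!r} missing from clade map")
        feat_col = "mean_meth_exon1" if clade == "mammal" else "mean_meth_exons2_4"
        meths, exprs = [], []
        for gene in grp["gene_id"]:
            key = (species, gene)
            if key in gm.index:
                v = gm.loc[key, feat_col]
                if pd.notna(v):
                    meths.append(float(v))
            if key in ex.index:
                exprs.append(float(ex.loc[key]))
        rows.append(
            {
                "orthogroup_id": og,
                "species": species,
                "clade": clade,
                "mean_meth": np.mean(meths) if meths else np.nan,
                "mean_expr": np.mean(exprs) if exprs else np.nan,
                "n_genes": len(grp),
            }
        )
    prof = pd.DataFrame(rows)
    prof["scaled_meth"] = prof.groupby("species")["mean_meth"].transform(_minmax)
    prof["scaled_expr"] = prof.groupby("species")["mean_expr"].transform(_minmax)
    mammal = prof["clade"] == "mammal"
    prof.loc[mammal, "scaled_meth"] = 1.0 - prof.loc[mammal, "scaled_meth"]
    return prof


def joint_cluster(
    profiles: pd.DataFrame,
    k: int = 2,
    method: str = "average",
    metric: str = "euclidean",
) -> pd.Series:
    """Cluster orthogroups on scaled methylation and expression.

    ``profiles`` is the long frame from :func:`orthogroup_meth_expr`; it is
    pivoted to one row per orthogroup (scaled methylation and expression per
    species) and clustered agglomeratively.  With ``k = 2`` the cluster with
    the higher mean scaled expression is labelled 'High', the other 'Low'.
    """
    wide = profiles.pivot_table(
        index="orthogroup_id",
        columns="species",
        values=["scaled_meth", "scaled_expr"],
    ).dropna()
    if wide.shape[0] < k:
        raise ValueError("fewer complete orthogroups than clusters")
    X = wide.to_numpy()
    if np.allclose(pdist(X), 0):
        warnings.warn("all orthogroup profiles identical; single effective cluster")
        return pd.Series("High", index=wide.index, name="cluster_label")
    Z = linkage(X, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    expr_cols = [c for c in wide.columns if c[0] == "scaled_expr"]
    mean_expr_by_cluster = (
        wide[expr_cols].groupby(labels).mean().mean(axis=1).sort_values()
    )
    name_map = {c: "Low" for c in mean_expr_by_cluster.index}
    name_map[mean_expr_by_cluster.index[-1]] = "High"
    return pd.Series(
        [name_map[l] for l in labels], index=wide.index, name="cluster_label"
    )


def ranked_methylation_clustering(
    gene_meth: pd.DataFrame,
    homolog_pairs: pd.DataFrame | None = None,
    k: int = 5,
    method: str = "average",
) -> pd.DataFrame:
    """Cluster homologous genes by per-sample methylation ranks.

    ``gene_meth`` is genes x samples of maximum exonic CpG methylation
    (rows indexed by gene or homolog-pair id).  When ``homolog_pairs`` is
    given (columns gene_a, gene_b), the row id is gene_a and the two
    species' sample columns must already be aligned by the caller.  Genes
    are ranked per sample (competition ranking, mean ranks on ties), the
    rank matrix is clustered hierarchically and cut into ``k`` sub-clusters;
    a per-sample high/low (>50% / <=50%) annotation of the raw levels is
    attached.
    """
    if homolog_pairs is not None:
        gene_meth = gene_meth.loc[homolog_pairs["gene_a"]]
    mat = gene_meth.dropna()
    if k > len(mat):
        raise ValueError("more sub-clusters requested than genes available")
    ranks = mat.rank(axis=0, method="average")
    Z = linkage(ranks.to_numpy(), method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    out = ranks.add_prefix("rank_")
    out["sub_cluster"] = labels
    for col in mat.columns:
        out[f"class_{col}"] = np.where(mat[col] > 0.5, "high", "low")
    return out


def ranked_sum_conservation(
    meth: pd.Series,
    expr: pd.Series,
    categories: pd.Series,
    n_permutations: int = 0,
    seed: int | None = None,
) -> dict:
    """Rank-sum of methylation and expression compared across categories.

    Per gene, the sum of the methylation rank and the expression rank
    (competition ranking, mean ranks on ties; invariant to monotone
    transforms of either input).  Categories are compared with a
    Kruskal-Wallis test; optionally a permutation p-value over shuffled
    category labels is added.
    """
    df = pd.DataFrame({"meth": meth, "expr": expr, "cat": categories}).dropna()
    df["rank_sum"] = df["meth"].rank(method="average") + df["expr"].rank(
        method="average"
    )
    groups = [g["rank_sum"].to_numpy() for _, g in df.groupby("cat")]
    if len(groups) < 2:
        raise ValueError("need at least two categories")
    H, p = stats.kruskal(*groups)
    out = {
        "H": float(H),
        "p_value": float(p),
        "medians_by_category": df.groupby("cat")["rank_sum"].median().to_dict(),
        "rank_sums": df["rank_sum"],
    }
    if n_permutations:
        rng = np.random.default_rng(seed)
        cats = df["cat"].to_numpy()
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(cats)
            Hp, _ = stats.kruskal(
                *[df["rank_sum"].to_numpy()[perm == c] for c in np.unique(cats)]
            )
            if Hp >= H:
                count += 1
        out["perm_p_value"] = (count + 1) / (n_permutations + 1)
    return out


def top_n_by_methylation(
    summaries: pd.DataFrame, n: int = 1000, feature: str = "exons2_4"
) -> list[str]:
    """Highest-methylated genes by feature mean, stable id tie-break."""
    col = f"mean_meth_{feature}"
    df = summaries.dropna(subset=[col])
    if n > len(df):
        warnings.warn(
            f"requested top {n} but only {len(df)} genes have methylation data"
        )
    df = df.sort_values([col, "gene_id"], ascending=[False, True], kind="stable")
    return df["gene_id"].head(n).tolist()


def hypergeometric_ora(
    selected: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a selection.

    For each set: p = P(X >= overlap) with population N = |universe|,
    K = |set n universe| successes, n = |selected| draws; fold enrichment is
    the observed/expected overlap ratio.  BH-adjusted q-values are added
    across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    rows = []
    for name, genes in gene_sets.items():
        K = len(set(genes) & universe)
        k = len(set(genes) & selected)
        N, n = len(universe), len(selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        expected = K * n / N
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": K,
                "expected": expected,
                "fold_enrichment": (k / expected) if expected > 0 else np.nan,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        from .diffmeth import adjust_q

        out["q_value"] = adjust_q(out["p_value"].to_numpy(), method="bh")
    return out.sort_values("p_value").reset_index(drop=True)
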