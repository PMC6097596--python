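"""Synthetic whole-genome bisulfite datasets with controlled architecture.

Two methylome architectures are modelled.  The mosaic invertebrate
architecture has sparse gene-body methylation: a small fraction of genes is
methylated, methylation within them peaks at exons 2-4, CpGs are enriched
in exons, and global methylation sits in the low single-digit percent
range.  The global vertebrate architecture methylates most of the genome
heavily with a dip at the promoter and first exon, placing global
methylation around three quarters.  Latent per-CpG levels come from a
two-mode beta mixture (the HM/LM dichotomy); observed counts are binomial
draws at Poisson coverage (11x by default).  Expression is coupled to
feature methylation with an architecture-dependent sign: positive on
exons 2-4 in the mosaic architecture, negative on exon 1 in the vertebrate
one.  Every generator is a pure function of its parameters and seed, and
each returns the latent truth needed for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    SiteMatrix,
    write_gff3,
    write_methylation_calls,
    write_snp_table,
)

__all__ = [
    "MethylomeArchitecture",
    "MOSAIC_INVERTEBRATE",
    "GLOBAL_VERTEBRATE",
    "simulate_annotation",
    "simulate_methylome",
    "simulate_expression",
    "inject_snps",
    "simulate_dmc_experiment",
    "simulate_orthogroups",
    "write_dataset",
]


@dataclass(frozen=True)
class MethylomeArchitecture:
    """Parameters describing one methylome architecture.

    ``hm_prob_by_feature`` gives, per feature class, the probability that a
    CpG of a methylated gene carries high (HM-mode) methylation;
    ``background_hm_prob`` applies to CpGs of unmethylated genes and
    intergenic CpGs.  Latent levels are Beta(*hm_beta*) in the high mode and
    Beta(*lm_beta*) in the low mode.  ``expression_coupling`` is the signed
    strength (log-scale units per unit methylation) linking the coupling
    feature's methylation to expression.
    """

    name: str
    frac_methylated_genes: float
    hm_beta: tuple[float, float]
    lm_beta: tuple[float, float]
    hm_prob_by_feature: Mapping[str, float]
    background_hm_prob: float
    target_global_pct: tuple[float, float]
    coverage_mean: float = 11.0
    expression_coupling: float = 0.0
    coupling_feature: str = "exons2_4"
    cpg_rate_exon: float = 0.04
    cpg_rate_background: float = 0.012
    #: when set, the promoter region (upstream flank + exon 1) of each gene
    #: gets a per-gene HM probability drawn from this beta law, emulating
    #: the island/non-island promoter dichotomy of vertebrate genomes
    promoter_gene_beta: tuple[float, float] | None = None


MOSAIC_INVERTEBRATE = MethylomeArchitecture(
    name="mosaic_invertebrate",
    frac_methylated_genes=0.045,
    hm_beta=(8.0, 1.3),
    lm_beta=(0.2, 60.0),
    hm_prob_by_feature={
        "upstream": 0.03,
        "exon_1": 0.22,
        "exons_2_4": 0.60,
        "exon_other": 0.28,
        "intron": 0.08,
        "downstream": 0.03,
        "intergenic": 0.0,
    },
    background_hm_prob=0.001,
    target_global_pct=(0.4, 1.5),
    coverage_mean=11.0,
    expression_coupling=3.0,
    coupling_feature="exons2_4",
    cpg_rate_exon=0.045,
    cpg_rate_background=0.012,
)

GLOBAL_VERTEBRATE = MethylomeArchitecture(
    name="global_vertebrate",
    frac_methylated_genes=1.0,
    hm_beta=(14.0, 1.1),
    lm_beta=(0.3, 30.0),
    hm_prob_by_feature={
        "upstream": 0.50,
        "exon_1": 0.18,
        "exons_2_4": 0.93,
        "exon_other": 0.93,
        "intron": 0.88,
        "downstream": 0.85,
        "intergenic": 0.86,
    },
    background_hm_prob=0.86,
    target_global_pct=(72.0, 76.0),
    coverage_mean=11.0,
    expression_coupling=-3.0,
    coupling_feature="exon1",
    cpg_rate_exon=0.02,
    cpg_rate_background=0.02,
    promoter_gene_beta=(0.9, 1.2),
)


def _architecture(arch) -> MethylomeArchitecture:
    if isinstance(arch, MethylomeArchitecture):
        return arch
    table = {
        "mosaic_invertebrate": MOSAIC_INVERTEBRATE,
        "global_vertebrate": GLOBAL_VERTEBRATE,
    }
    if arch not in table:
        raise ValueError(f"unknown architecture {arch!r}")
    return table[arch]


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    n_genes: int = 200,
    n_chroms: int = 4,
    exon_count_range: tuple[int, int] = (2, 7),
    exon_len_range: tuple[int, int] = (120, 400),
    intron_len_range: tuple[int, int] = (80, 400),
    intergenic_len_range: tuple[int, int] = (3000, 8000),
    architecture=MOSAIC_INVERTEBRATE,
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, int], pd.DataFrame]:
    """Simulate non-overlapping gene models and CpG dyad positions.

    Genes are laid down chromosome by chromosome with intergenic gaps large
    enough that 1 kb flanks never overlap a neighbouring gene.  CpG dyads
    are placed by a Bernoulli process whose per-base rate is higher in exons
    when the architecture calls for exonic CpG enrichment.  Returns the gene
    models, contig sizes and a (chrom, pos) CpG table.
    """
    arch = _architecture(architecture)
    rng = np.random.default_rng(seed)
    lo_gap = max(intergenic_len_range[0], 2001)  # keep flanks gene-exclusive
    gap_range = (lo_gap, max(intergenic_len_range[1], lo_gap + 1))
    genes: list[GeneModel] = []
    contig_sizes: dict[str, int] = {}
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1
    gene_no = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(*gap_range))
        for _ in range(per_chrom[ci]):
            n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
            exons_genomic = []
            pos = cursor
            for k in range(n_ex):
                length = int(rng.integers(*exon_len_range))
                exons_genomic.append((pos, pos + length))
                pos += length
                if k < n_ex - 1:
                    pos += int(rng.integers(*intron_len_range))
            strand = "+" if rng.random() < 0.5 else "-"
            ordered = exons_genomic if strand == "+" else exons_genomic[::-1]
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(ordered),
                )
            )
            cursor = pos + int(rng.integers(*gap_range))
        contig_sizes[chrom] = cursor + int(rng.integers(*gap_range))
    # CpG placement: higher rate inside exons, background elsewhere
    cpg_rows = []
    for chrom, size in contig_sizes.items():
        rate = np.full(size, arch.cpg_rate_background)
        for g in genes:
            if g.chrom != chrom:
                continue
            for a, b in g.exons:
                rate[a:b] = arch.cpg_rate_exon
        draws = rng.random(size - 1) < rate[:-1]
        pos = np.flatnonzero(draws)
        keep = np.ones(len(pos), dtype=bool)  # dyads need 2 bp: min spacing 2
        last = -10
        for i, p in enumerate(pos):
            if p - last < 2:
                keep[i] = False
            else:
                last = p
        for p in pos[keep]:
            cpg_rows.append((chrom, int(p)))
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos"])
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand=g.strand,
            exons=g.exons,
            contig_length=contig_sizes[g.chrom],
        )
        for g in genes
    ]
    return genes, contig_sizes, cpgs


# ---------------------------------------------------------------------------
# methylome


def _feature_class(feature: str) -> str:
    if feature == "upstream_1kb":
        return "upstream"
    if feature == "downstream_1kb":
        return "downstream"
    if feature == "exon_1":
        return "exon_1"
    if feature.startswith("exon_"):
        k = int(feature.split("_")[1])
        return "exons_2_4" if k <= 4 else "exon_other"
    if feature.startswith("intron_"):
        return "intron"
    return "intergenic"


def simulate_methylome(
    genes: list[GeneModel],
    cpgs: pd.DataFrame,
    architecture=MOSAIC_INVERTEBRATE,
    n_samples: int = 3,
    seed: int = 0,
    sample_prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample methylation calls plus the latent truth table.

    Each CpG gets a latent level from the architecture's two-mode beta
    mixture (mode choice driven by its gene's methylation status and its
    feature class); per sample, coverage is Poisson(coverage mean) truncated
    at 1 and methylated counts are binomial.  Returns the long call frame
    (destranded convention, strand '+') and the truth table with the latent
    level, feature class and HM mode of every CpG.
    """
    from .landscape import assign_feature

    arch = _architecture(architecture)
    rng = np.random.default_rng(seed)
    ann = assign_feature(cpgs[["chrom", "pos"]], genes)
    feat_class = ann["feature"].map(_feature_class)
    gene_ids = sorted(g.gene_id for g in genes)
    # fixed count of methylated genes (stratified draw) so the achieved
    # global level varies little between seeds
    n_meth_genes = int(round(arch.frac_methylated_genes * len(gene_ids)))
    methylated_genes = set(
        rng.choice(gene_ids, size=n_meth_genes, replace=False)
    )
    in_meth_gene = ann["gene_id"].isin(methylated_genes)
    hm_prob = np.where(
        in_meth_gene,
        feat_class.map(lambda f: arch.hm_prob_by_feature.get(f, 0.0)),
        arch.background_hm_prob,
    )
    if arch.promoter_gene_beta is not None:
        promoter_prob = pd.Series(
            rng.beta(*arch.promoter_gene_beta, size=len(gene_ids)),
            index=gene_ids,
        )
        at_promoter = (
            feat_class.isin(["upstream", "exon_1"]) & in_meth_gene
        ).to_numpy()
        hm_prob = np.where(
            at_promoter,
            ann["gene_id"].map(promoter_prob).to_numpy(),
            hm_prob,
        )
    is_hm = rng.random(len(cpgs)) < hm_prob
    level = np.where(
        is_hm,
        rng.beta(*arch.hm_beta, size=len(cpgs)),
        rng.beta(*arch.lm_beta, size=len(cpgs)),
    )
    truth = pd.DataFrame(
        {
            "chrom": cpgs["chrom"].to_numpy(),
            "pos": cpgs["pos"].to_numpy(),
            "feature": ann["feature"].to_numpy(),
            "feature_class": feat_class.to_numpy(),
            "gene_id": ann["gene_id"].to_numpy(),
            "gene_methylated": in_meth_gene.to_numpy(),
            "is_hm": is_hm,
            "latent_level": level,
        }
    )
    achieved = 100.0 * level.mean()
    lo, hi = arch.target_global_pct
    if not lo <= achieved <= hi:
        import warnings

        warnings.warn(
            f"architecture {arch.name}: latent global methylation "
            f"{achieved:.2f}% outside target [{lo}, {hi}]%"
        )
    prefix = sample_prefix or arch.name[:3]
    frames = []
    for s in range(n_samples):
        # per-strand Poisson coverage; the destranded record sums both strands
        cov = np.maximum(
            rng.poisson(arch.coverage_mean, size=len(cpgs))
            + rng.poisson(arch.coverage_mean, size=len(cpgs)),
            1,
        )
        n_meth = rng.binomial(cov, level)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": truth["chrom"],
                    "pos": truth["pos"],
                    "strand": "+",
                    "n_meth": n_meth,
                    "n_unmeth": cov - n_meth,
                    "sample_id": f"{prefix}_s{s + 1}",
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return calls, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    architecture=MOSAIC_INVERTEBRATE,
    n_samples: int = 3,
    dispersion: float = 0.2,
    mean_library_size: float = 2_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate gene-level RNA counts coupled to feature methylation.

    Gene baselines are log-normal; the log-mean is shifted by
    ``expression_coupling x (feature methylation - its mean)`` where the
    feature is exons 2-4 (mosaic) or exon 1 (vertebrate, negative
    coupling).  Counts are negative binomial with the given dispersion and
    scale with exonic gene length, so FPKM values are comparable.
    """
    arch = _architecture(architecture)
    rng = np.random.default_rng(seed)
    if arch.coupling_feature == "exons2_4":
        feats = {"exon_2", "exon_3", "exon_4"}
    else:
        feats = {"exon_1"}
    per_gene = (
        truth[truth["feature"].isin(feats)]
        .groupby("gene_id")["latent_level"]
        .mean()
    )
    rows = []
    gene_order = [g.gene_id for g in genes]
    meth = np.array([per_gene.get(g, 0.0) for g in gene_order])
    meth_centered = meth - meth.mean()
    log_mu = rng.normal(loc=4.0, scale=1.0, size=len(genes))
    log_mu += arch.expression_coupling * meth_centered
    lengths = np.array(
        [sum(b - a for a, b in g.exons) for g in genes], dtype=float
    )
    mu = np.exp(log_mu) * lengths / lengths.mean()
    mu *= mean_library_size / mu.sum()
    r = 1.0 / dispersion  # NB size parameter
    counts = {}
    for s in range(n_samples):
        lam = rng.gamma(shape=r, scale=mu / r)
        counts[f"rna_s{s + 1}"] = rng.poisson(lam)
    out = pd.DataFrame(counts, index=pd.Index(gene_order, name="gene_id"))
    return out


# ---------------------------------------------------------------------------
# SNPs


def inject_snps(
    cpgs: pd.DataFrame,
    contig_sizes: Mapping[str, int],
    n_snps: int = 600,
    frac_at_cpg: float = 0.1,
    n_samples: int = 3,
    mean_depth: float = 17.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Place SNPs, a stated fraction of them on CpG dyad positions.

    Qualities are exponential around the masking threshold so that both
    maskable (> 50) and ignorable SNPs occur; confidences straddle the
    900 filter; per-sample depths are Poisson so some fall below the
    depth-8 rule.
    """
    rng = np.random.default_rng(seed)
    n_at_cpg = int(round(n_snps * frac_at_cpg))
    cpg_pool = cpgs.sample(
        n=min(n_at_cpg, len(cpgs)), random_state=int(rng.integers(2**31))
    )
    rows = []
    bases = np.array(list("ACGT"))
    occupied = {(c, p) for c, p in zip(cpgs["chrom"], cpgs["pos"])}
    occupied |= {(c, p + 1) for c, p in zip(cpgs["chrom"], cpgs["pos"])}
    for _, row in cpg_pool.iterrows():
        offset = int(rng.integers(0, 2))  # C or G side of the dyad
        rows.append((row["chrom"], int(row["pos"]) + offset))
    chroms = list(contig_sizes)
    while len(rows) < n_snps:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, contig_sizes[chrom]))
        if (chrom, pos) in occupied:
            continue
        rows.append((chrom, pos))
    snps = pd.DataFrame(rows, columns=["chrom", "pos"])
    ref = bases[rng.integers(0, 4, size=len(snps))]
    shift = rng.integers(1, 4, size=len(snps))
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    snps["ref"] = ref
    snps["alt"] = alt
    snps["quality"] = np.round(rng.exponential(scale=45.0, size=len(snps)) + 5, 1)
    snps["confidence"] = np.round(
        rng.exponential(scale=400.0, size=len(snps)) + 700, 1
    )
    for s in range(n_samples):
        snps[f"dp_s{s + 1}"] = rng.poisson(mean_depth, size=len(snps))
    return snps.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# two-group DMC experiment


def simulate_dmc_experiment(
    n_sites: int = 2000,
    n_true_dmcs: int = 200,
    effect_size_pct: float = 40.0,
    n_treat: int = 4,
    n_ctrl: int = 3,
    coverage_mean: float = 11.0,
    strands: int = 2,
    base_levels: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[SiteMatrix, dict[str, str], pd.DataFrame]:
    """Two-group methylome with planted differential CpGs.

    A random subset of sites is shifted by ``effect_size_pct`` points in the
    treatment group (direction chosen so levels stay inside [0, 1]); all
    other sites share one latent level in both groups.  ``coverage_mean``
    is the per-strand sequencing coverage; destranded CpG records sum
    ``strands`` strands (set ``strands=1`` for single-strand sites).
    Returns the wide site matrix, the sample-to-group map and the truth
    table.
    """
    rng = np.random.default_rng(seed)
    if base_levels is None:
        base_levels = rng.uniform(0.1, 0.9, size=n_sites)
    base_levels = np.asarray(base_levels, dtype=float)
    n_sites = base_levels.size
    if n_true_dmcs > n_sites:
        raise ValueError("more true DMCs than sites")
    true_idx = rng.choice(n_sites, size=n_true_dmcs, replace=False)
    effect = effect_size_pct / 100.0
    direction = np.where(base_levels[true_idx] + effect <= 0.98, 1.0, -1.0)
    treat_levels = base_levels.copy()
    treat_levels[true_idx] = base_levels[true_idx] + direction * effect
    treat_levels = np.clip(treat_levels, 0.0, 1.0)
    index = pd.MultiIndex.from_arrays(
        [np.repeat("sim", n_sites), np.arange(n_sites) * 10],
        names=["chrom", "pos"],
    )
    meth, unmeth, groups = {}, {}, {}

    def _coverage():
        tot = np.zeros(n_sites, dtype=int)
        for _ in range(strands):
            tot = tot + rng.poisson(coverage_mean, size=n_sites)
        return np.maximum(tot, 1)

    for s in range(n_treat):
        sid = f"treat_{s + 1}"
        cov = _coverage()
        m = rng.binomial(cov, treat_levels)
        meth[sid], unmeth[sid], groups[sid] = m, cov - m, "treat"
    for s in range(n_ctrl):
        sid = f"ctrl_{s + 1}"
        cov = _coverage()
        m = rng.binomial(cov, base_levels)
        meth[sid], unmeth[sid], groups[sid] = m, cov - m, "ctrl"
    sites = SiteMatrix(
        pd.DataFrame(meth, index=index, dtype=float),
        pd.DataFrame(unmeth, index=index, dtype=float),
    )
    is_true = np.zeros(n_sites, dtype=bool)
    is_true[true_idx] = True
    truth = pd.DataFrame(
        {
            "base_level": base_levels,
            "treat_level": treat_levels,
            "is_dmc": is_true,
        },
        index=index,
    )
    return sites, groups, truth


# ---------------------------------------------------------------------------
# orthogroups


DEFAULT_SPECIES_CLADES = {
    "dmagna": "daphnia",
    "dpulex": "daphnia",
    "amellifera": "hymenoptera",
    "nvitripennis": "hymenoptera",
    "hsapiens": "mammal",
    "mmusculus": "mammal",
}

DEFAULT_CATEGORY_MIX = {
    "species_specific": 0.25,
    "daphnia_specific": 0.15,
    "hymenoptera_specific": 0.10,
    "arthropod_specific": 0.15,
    "mammal_specific": 0.10,
    "common": 0.25,
}

_CATEGORY_CONSERVATION_RANK = {
    "species_specific": 0.0,
    "daphnia_specific": 0.4,
    "hymenoptera_specific": 0.4,
    "arthropod_specific": 0.7,
    "mammal_specific": 0.7,
    "common": 1.0,
}


def simulate_orthogroups(
    species_clades: Mapping[str, str] | None = None,
    n_orthogroups: int = 414,
    category_mix: Mapping[str, float] | None = None,
    conservation_methylation_link: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an orthogroup table with a conservation-methylation link.

    Orthogroup categories are drawn from ``category_mix``; member species
    are chosen to realise each category.  When the link is positive, more
    conserved categories receive higher latent methylation and expression
    (on top of noise), mirroring the enrichment of methylated, highly
    expressed genes among evolutionarily conserved orthogroups.
    Returns the long orthogroup table and a per-gene truth table with
    latent methylation, expression and the category.
    """
    clades = dict(species_clades or DEFAULT_SPECIES_CLADES)
    mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    rng = np.random.default_rng(seed)
    by_clade: dict[str, list[str]] = {}
    for s, c in clades.items():
        by_clade.setdefault(c, []).append(s)
    for c in by_clade:
        by_clade[c].sort()
    cats = list(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs /= probs.sum()
    og_rows, truth_rows = [], []
    for i in range(n_orthogroups):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        if cat == "species_specific":
            members = [sorted(clades)[int(rng.integers(len(clades)))]]
        elif cat == "daphnia_specific":
            members = by_clade["daphnia"]
        elif cat == "hymenoptera_specific":
            members = by_clade["hymenoptera"]
        elif cat == "arthropod_specific":
            members = by_clade["daphnia"] + by_clade["hymenoptera"]
        elif cat == "mammal_specific":
            members = by_clade["mammal"]
        else:
            members = sorted(clades)
        og_id = f"OG{i + 1:05d}"
        rank = _CATEGORY_CONSERVATION_RANK[cat]
        base_meth = rng.beta(2.0, 2.0)
        base_expr = rng.normal(0.0, 1.0)
        meth_latent = np.clip(
            base_meth * (1 - conservation_methylation_link)
            + conservation_methylation_link * rank
            + rng.normal(0, 0.05),
            0.0,
            1.0,
        )
        expr_latent = base_expr + 2.0 * conservation_methylation_link * rank
        for sp in members:
            gene = f"{og_id}_{sp}"
            og_rows.append((og_id, sp, gene))
            truth_rows.append(
                (
                    og_id,
                    sp,
                    gene,
                    cat,
                    float(np.clip(meth_latent + rng.normal(0, 0.03), 0, 1)),
                    float(np.exp(expr_latent + rng.normal(0, 0.2))),
                )
            )
    orthogroups = pd.DataFrame(
        og_rows, columns=["orthogroup_id", "species", "gene_id"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "orthogroup_id",
            "species",
            "gene_id",
            "category",
            "latent_meth",
            "latent_expr",
        ],
    )
    return orthogroups, truth


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(
    outdir,
    architecture=MOSAIC_INVERTEBRATE,
    n_genes: int = 200,
    n_samples: int = 3,
    seed: int = 0,
) -> dict:
    """Write a complete synthetic dataset in the pipeline's input dialects.

    Produces a GFF3 annotation, one CpG-report call table per sample, a SNP
    TSV, an expression count TSV and the latent truth tables (JSON/TSV).
    Returns a manifest of the written paths.
    """
    arch = _architecture(architecture)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    s_ann, s_met, s_expr, s_snp = rng.integers(0, 2**31, size=4)
    genes, contigs, cpgs = simulate_annotation(
        n_genes=n_genes, architecture=arch, seed=int(s_ann)
    )
    calls, truth = simulate_methylome(
        genes, cpgs, architecture=arch, n_samples=n_samples, seed=int(s_met)
    )
    expr = simulate_expression(
        genes, truth, architecture=arch, n_samples=n_samples, seed=int(s_expr)
    )
    snps = inject_snps(cpgs, contigs, n_samples=n_samples, seed=int(s_snp))
    paths: dict[str, str] = {}
    gff = outdir / "annotation.gff3"
    write_gff3(genes, gff)
    paths["annotation"] = str(gff)
    for sid, sub in calls.groupby("sample_id"):
        p = outdir / f"{sid}.cpg_report.tsv"
        write_methylation_calls(sub, p, dialect="cpg_report")
        paths[f"calls:{sid}"] = str(p)
    snp_path = outdir / "snps.tsv"
    write_snp_table(snps, snp_path)
    paths["snps"] = str(snp_path)
    expr_path = outdir / "expression_counts.tsv"
    expr.to_csv(expr_path, sep="\t")
    paths["expression"] = str(expr_path)
    truth_path = outdir / "truth_sites.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth_sites"] = str(truth_path)
    meta = {
        "architecture": arch.name,
        "seed": seed,
        "n_genes": n_genes,
        "n_samples": n_samples,
        "contig_sizes": contigs,
        "n_cpgs": int(len(cpgs)),
    }
    meta_path = outdir / "dataset.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["meta"] = str(meta_path)
    return paths
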