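"""Readers, writers and core containers for methylome analysis tables.

Every coordinate inside the package is 0-based, half-open.  All external
dialects (GFF3/GTF 1-based closed intervals, Bismark-style CpG reports with
1-based positions) are converted at the boundary, so no other module ever
reasons about coordinate conventions.

The central bulk container for methylation calls is a "long" pandas
DataFrame with columns ``chrom, pos, strand, n_meth, n_unmeth, sample_id``
(one row per CpG per sample); :class:`SiteMatrix` is the wide site-by-sample
view used by the multi-sample filters and tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "MethylationCall",
    "GeneModel",
    "SiteMatrix",
    "CALL_COLUMNS",
    "read_methylation_calls",
    "write_methylation_calls",
    "destrand_cpgs",
    "read_gene_models",
    "write_gff3",
    "read_snp_table",
    "write_snp_table",
    "read_expression_counts",
    "read_orthogroups",
    "read_orthofinder_table",
    "read_gmt",
    "pivot_site_matrix",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "sample_id"]

FLANK_BP = 1000


class ParseError(ValueError):
    """Malformed input row; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


@dataclass(frozen=True)
class MethylationCall:
    """One CpG dyad in one sample.

    ``pos`` is the 0-based position of the C on the plus strand of the dyad
    (for un-destranded minus-strand calls it is the position of the minus
    strand C itself).
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    sample_id: str = ""

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        if self.coverage == 0:
            raise ValueError("methylation level undefined at zero coverage")
        return self.n_meth / self.coverage


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon structure plus derived introns and 1 kb flanks.

    ``exons`` are half-open ``(start, end)`` intervals in *transcription*
    order: ``exons[0]`` is the 5'-most exon, which on the minus strand is the
    one with the largest genomic coordinates.  Interval bounds themselves are
    always ``start < end`` in genomic orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    contig_length: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        genomic = sorted(self.exons)
        for (a, b), (c, d) in zip(genomic[:-1], genomic[1:]):
            if b > c:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        expected = tuple(genomic if self.strand == "+" else genomic[::-1])
        if tuple(self.exons) != expected:
            raise ValueError(
                f"exons of {self.gene_id} not in transcription order"
            )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        genomic = sorted(self.exons)
        gaps = tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(genomic[:-1], genomic[1:])
        )
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def start(self) -> int:
        return min(a for a, _ in self.exons)

    @property
    def end(self) -> int:
        return max(b for _, b in self.exons)

    @property
    def upstream_flank(self) -> tuple[int, int]:
        """1 kb upstream of the first exon, clipped at contig edges."""
        if self.strand == "+":
            return (max(0, self.start - FLANK_BP), self.start)
        hi = self.end + FLANK_BP
        if self.contig_length is not None:
            hi = min(hi, self.contig_length)
        return (self.end, hi)

    @property
    def downstream_flank(self) -> tuple[int, int]:
        if self.strand == "+":
            hi = self.end + FLANK_BP
            if self.contig_length is not None:
                hi = min(hi, self.contig_length)
            return (self.end, hi)
        return (max(0, self.start - FLANK_BP), self.start)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self, with_flanks: bool = False) -> tuple[int, int]:
        if not with_flanks:
            return (self.start, self.end)
        lo = min(self.upstream_flank[0], self.downstream_flank[0], self.start)
        hi = max(self.upstream_flank[1], self.downstream_flank[1], self.end)
        return (lo, hi)


# ---------------------------------------------------------------------------
# methylation call tables


def _validate_calls(df: pd.DataFrame, path) -> pd.DataFrame:
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        bad = df.index[(df["n_meth"] < 0) | (df["n_unmeth"] < 0)][0]
        raise ParseError(f"negative count in {path}", line=int(bad) + 1)
    if (df["pos"] < 0).any():
        raise ParseError(f"negative position in {path}")
    return df


def read_methylation_calls(
    path,
    sample_id: str,
    dialect: Literal["bedgraph_counts", "cpg_report"] = "cpg_report",
) -> pd.DataFrame:
    """Read one sample's per-CpG methylation calls into the long call frame.

    ``bedgraph_counts``: chrom, start, end, pct, n_meth, n_unmeth
    (MethylDackel-style bedGraph, already 0-based; strand taken as '+').
    ``cpg_report``: chrom, 1-based pos, strand, n_meth, n_unmeth, context
    (Bismark CpG report; non-CpG-context rows are dropped).
    Gzipped files are handled transparently.
    """
    names = {
        "bedgraph_counts": ["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        "cpg_report": ["chrom", "pos1", "strand", "n_meth", "n_unmeth", "context"],
    }
    if dialect not in names:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(
            path,
            sep=r"\s+",
            names=names[dialect],
            header=None,
            comment="#",
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=names[dialect])
    for col in ("n_meth", "n_unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any() and len(raw):
            line = int(np.flatnonzero(vals.isna())[0]) + 1
            raise ParseError(f"malformed count field in {path}", line=line)
        raw[col] = vals.astype(int)
    if dialect == "bedgraph_counts":
        out = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": pd.to_numeric(raw["start"]).astype(int),
                "strand": "+",
                "n_meth": raw["n_meth"],
                "n_unmeth": raw["n_unmeth"],
            }
        )
    else:
        pos1 = pd.to_numeric(raw["pos1"], errors="coerce")
        if pos1.isna().any() and len(raw):
            line = int(np.flatnonzero(pos1.isna())[0]) + 1
            raise ParseError(f"malformed position in {path}", line=line)
        keep = raw["context"].astype(str).str.upper().str.startswith("CG")
        raw = raw[keep]
        out = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": pos1[keep].astype(int) - 1,
                "strand": raw["strand"],
                "n_meth": raw["n_meth"],
                "n_unmeth": raw["n_unmeth"],
            }
        )
    out["sample_id"] = sample_id
    out = out.reset_index(drop=True)
    return _validate_calls(out, path)[CALL_COLUMNS]


def write_methylation_calls(
    calls: pd.DataFrame,
    path,
    dialect: Literal["bedgraph_counts", "cpg_report"] = "cpg_report",
) -> None:
    """Write a single sample's calls back out in the given dialect."""
    if calls["sample_id"].nunique() > 1:
        raise ValueError("write one sample at a time")
    if dialect == "cpg_report":
        out = pd.DataFrame(
            {
                "chrom": calls["chrom"],
                "pos1": calls["pos"] + 1,
                "strand": calls["strand"],
                "n_meth": calls["n_meth"],
                "n_unmeth": calls["n_unmeth"],
                "context": "CG",
            }
        )
    elif dialect == "bedgraph_counts":
        cov = calls["n_meth"] + calls["n_unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * calls["n_meth"] / cov, 0.0)
        out = pd.DataFrame(
            {
                "chrom": calls["chrom"],
                "start": calls["pos"],
                "end": calls["pos"] + 1,
                "pct": np.round(pct, 6),
                "n_meth": calls["n_meth"],
                "n_unmeth": calls["n_unmeth"],
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


def destrand_cpgs(calls: pd.DataFrame, genome=None) -> pd.DataFrame:
    """Merge the two strands of each CpG dyad into one plus-strand record.

    A plus-strand call at position ``p`` and a minus-strand call at ``p + 1``
    (the C on the reverse complement) are summed into a single record at
    ``p``.  Unpaired calls pass through unchanged.  Total methylated and
    unmethylated read counts are conserved exactly.

    ``genome``, when given, must be a mapping ``chrom -> sequence`` and is
    used only to warn when a merged position is not a CG dinucleotide.
    """
    required = set(CALL_COLUMNS) - {"sample_id"}
    if not required.issubset(calls.columns):
        raise ValueError(f"call frame must have columns {sorted(required)}")
    if "sample_id" not in calls.columns:
        calls = calls.assign(sample_id="")
    out = []
    for sample, sub in calls.groupby("sample_id", sort=False):
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    "calls must be sorted by (chrom, pos); sort before destranding"
                )
            plus = grp[grp["strand"] == "+"]
            minus = grp[grp["strand"] == "-"]
            pair = minus["pos"].isin(set(plus["pos"] + 1))
            paired_minus = minus[pair].set_index(minus["pos"][pair] - 1)
            merged = plus.set_index("pos", drop=False).copy()
            add = paired_minus.reindex(merged.index)
            merged["n_meth"] += add["n_meth"].fillna(0).astype(int)
            merged["n_unmeth"] += add["n_unmeth"].fillna(0).astype(int)
            rest = minus[~pair]
            res = pd.concat([merged.reset_index(drop=True), rest])
            res = res.sort_values("pos", kind="stable")
            if genome is not None and chrom in genome:
                seq = str(genome[chrom])
                for p in res.loc[res["strand"] == "+", "pos"]:
                    if seq[p : p + 2].upper() != "CG":
                        warnings.warn(
                            f"{chrom}:{p} is not a CG dinucleotide in the "
                            "supplied genome"
                        )
            out.append(res)
    if not out:
        return calls.iloc[0:0]
    return pd.concat(out, ignore_index=True)[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path, contig_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Parse gene models from GFF3/GTF into transcription-ordered exon lists.

    Exons of all transcripts of a gene are collapsed; overlapping exons are
    merged with a warning; genes without exons are skipped with a warning.
    GFF 1-based closed intervals become 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(gene, featuretype="exon")
        ]
        if not exons:
            warnings.warn(f"gene {gene.id} has no exons; skipped")
            continue
        exons = sorted(set(exons))
        merged: list[list[int]] = []
        overlapped = False
        for a, b in exons:
            if merged and a < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
                overlapped = True
            else:
                merged.append([a, b])
        if overlapped:
            warnings.warn(f"overlapping exons in gene {gene.id}; merged")
        ordered = [tuple(e) for e in merged]
        if gene.strand == "-":
            ordered = ordered[::-1]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(ordered),
                contig_length=(contig_lengths or {}).get(gene.seqid),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmethylomap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{g.chrom}\tmethylomap\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# SNP, expression, orthogroup and gene-set tables

SNP_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "quality", "confidence"]


def read_snp_table(path) -> pd.DataFrame:
    """Read a VCF-subset SNP TSV.

    Expected header: ``chrom pos ref alt quality confidence`` followed by one
    read-depth column per sample (any names).  ``pos`` is 1-based in the file
    (VCF convention) and converted to 0-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"SNP table {path} lacks columns {missing}")
    df["pos"] = df["pos"].astype(int) - 1
    depth_cols = [c for c in df.columns if c not in SNP_FIXED_COLUMNS]
    if not depth_cols:
        raise ParseError(f"SNP table {path} has no per-sample depth columns")
    return df


def write_snp_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def snp_depth_columns(snps: pd.DataFrame) -> list[str]:
    return [c for c in snps.columns if c not in SNP_FIXED_COLUMNS]


def read_expression_counts(path) -> pd.DataFrame:
    """Gene-by-sample integer count matrix; first column is gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_orthogroups(path) -> pd.DataFrame:
    """Long orthogroup table: columns orthogroup_id, species, gene_id."""
    df = pd.read_csv(path, sep="\t")
    need = {"orthogroup_id", "species", "gene_id"}
    if not need.issubset(df.columns):
        raise ParseError(f"orthogroup table {path} lacks columns {sorted(need)}")
    dup = df.duplicated(["species", "gene_id"], keep=False)
    if dup.any():
        raise ParseError(
            f"gene(s) in more than one orthogroup within a species: "
            f"{sorted(df.loc[dup, 'gene_id'].unique()[:5])}"
        )
    return df


def read_orthofinder_table(path) -> pd.DataFrame:
    """Read the wide OrthoFinder ``Orthogroups.tsv`` dialect into long form.

    First column is the orthogroup id; each further column is a species whose
    cells hold comma-separated gene lists.
    """
    wide = pd.read_csv(path, sep="\t", dtype=str)
    og_col = wide.columns[0]
    rows = []
    for _, row in wide.iterrows():
        for species in wide.columns[1:]:
            cell = row[species]
            if pd.isna(cell) or not str(cell).strip():
                continue
            for gene in str(cell).split(","):
                gene = gene.strip()
                if gene:
                    rows.append((row[og_col], species, gene))
    return pd.DataFrame(rows, columns=["orthogroup_id", "species", "gene_id"])


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if not line.strip():
                    continue
                raise ParseError(f"GMT line with fewer than 3 fields", line=i)
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# wide site-by-sample view


@dataclass
class SiteMatrix:
    """Site-by-sample methylated / unmethylated count matrices.

    Rows are indexed by ``(chrom, pos)``; columns are sample ids.  Missing
    (uncovered) entries are NaN.  ``meth`` and ``unmeth`` always share index
    and columns.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self):
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth matrices must be aligned")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_sites(self) -> int:
        return len(self.meth)

    @property
    def coverage(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    @property
    def levels(self) -> pd.DataFrame:
        cov = self.coverage
        return self.meth / cov.where(cov > 0)

    def pooled_levels(self) -> pd.Series:
        """Per-site level from counts summed over samples."""
        m = self.meth.sum(axis=1, min_count=1)
        cov = m + self.unmeth.sum(axis=1, min_count=1)
        return m / cov.where(cov > 0)

    def select(self, keep: pd.Index | np.ndarray) -> "SiteMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            return SiteMatrix(self.meth.loc[keep], self.unmeth.loc[keep])
        return SiteMatrix(self.meth.loc[keep], self.unmeth.loc[keep])

    def to_long(self) -> pd.DataFrame:
        frames = []
        for s in self.samples:
            cov = self.meth[s] + self.unmeth[s]
            mask = cov.notna()
            sub = pd.DataFrame(
                {
                    "chrom": [c for c, _ in self.meth.index[mask]],
                    "pos": [p for _, p in self.meth.index[mask]],
                    "strand": "+",
                    "n_meth": self.meth.loc[mask, s].astype(int).to_numpy(),
                    "n_unmeth": self.unmeth.loc[mask, s].astype(int).to_numpy(),
                    "sample_id": s,
                }
            )
            frames.append(sub)
        return pd.concat(frames, ignore_index=True)


def pivot_site_matrix(calls: pd.DataFrame) -> SiteMatrix:
    """Pivot the long call frame to the wide site-by-sample matrices."""
    meth = calls.pivot_table(
        index=["chrom", "pos"], columns="sample_id", values="n_meth", aggfunc="sum"
    )
    unmeth = calls.pivot_table(
        index=["chrom", "pos"], columns="sample_id", values="n_unmeth", aggfunc="sum"
    )
    unmeth = unmeth.reindex(index=meth.index, columns=meth.columns)
    meth.columns.name = None
    unmeth.columns.name = None
    return SiteMatrix(meth, unmeth)
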