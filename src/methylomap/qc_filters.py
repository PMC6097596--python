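"""Quality-control filters applied to SNP calls and CpG methylation calls.

The multi-sample site filters run in a fixed order (SNP masking, coverage
outliers, low coverage, uninformative sites) and each stage produces a
:class:`FilterReport` so the per-rule removal counts reconcile exactly with
the input and output site totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SiteMatrix, snp_depth_columns

__all__ = [
    "FilterReport",
    "ConversionRateResult",
    "filter_snp_calls",
    "mask_snp_cpgs",
    "filter_coverage_outliers",
    "filter_low_coverage",
    "filter_uninformative",
    "run_site_filters",
    "bisulfite_conversion_rate",
]

VALID_BASES = {"A", "C", "G", "T"}


@dataclass
class FilterReport:
    """Book-keeping for one filtering stage."""

    name: str
    n_input: int
    n_removed_per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.n_removed_per_rule.values())

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed:{k}", v) for k, v in self.n_removed_per_rule.items()]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["item", "count"]).assign(stage=self.name)


@dataclass(frozen=True)
class ConversionRateResult:
    """Bisulfite conversion efficiency measured on CHH-context cytosines."""

    n_converted: int
    n_total: int

    @property
    def rate_pct(self) -> float:
        return 100.0 * self.n_converted / self.n_total


def filter_snp_calls(
    snps: pd.DataFrame,
    min_depth: int = 8,
    min_confidence: float = 900.0,
) -> pd.DataFrame:
    """Keep only well-supported single-nucleotide variants.

    Removes SNPs with indel alleles or non-ACGT reference/alternate bases,
    SNPs with read depth below ``min_depth`` in any sample, and SNPs whose
    Phred-scaled confidence that not all samples are homozygous reference is
    below ``min_confidence``.
    """
    depth_cols = snp_depth_columns(snps)
    ref_ok = snps["ref"].astype(str).str.upper().isin(VALID_BASES)
    alt_ok = snps["alt"].astype(str).str.upper().isin(VALID_BASES)
    depth_ok = (snps[depth_cols] >= min_depth).all(axis=1)
    conf_ok = snps["confidence"] >= min_confidence
    return snps[ref_ok & alt_ok & depth_ok & conf_ok].reset_index(drop=True)


def _dyad_positions(index: pd.MultiIndex) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": index.get_level_values(0), "pos": index.get_level_values(1)}
    )


def mask_snp_cpgs(
    sites: SiteMatrix,
    snps: pd.DataFrame,
    min_quality: float = 50.0,
) -> tuple[SiteMatrix, FilterReport]:
    """Remove CpG dyads that overlap a potential SNP with quality > threshold.

    A destranded CpG record at position ``p`` covers the dyad ``{p, p + 1}``;
    a SNP at either position removes the site from every sample.  The quality
    cut is strict (``> min_quality``), so a SNP at exactly the threshold does
    not mask.
    """
    hot = snps[snps["quality"] > min_quality]
    hot_set = set(zip(hot["chrom"], hot["pos"]))
    dyads = _dyad_positions(sites.meth.index)
    bad = np.fromiter(
        (
            (c, p) in hot_set or (c, p + 1) in hot_set
            for c, p in zip(dyads["chrom"], dyads["pos"])
        ),
        dtype=bool,
        count=len(dyads),
    )
    report = FilterReport(
        "mask_snp_cpgs", sites.n_sites, {"snp_overlap": int(bad.sum())}
    )
    return sites.select(~bad), report


def filter_coverage_outliers(
    sites: SiteMatrix,
    sd_fold: float = 2.0,
    min_fraction_samples: float = 0.5,
) -> tuple[SiteMatrix, FilterReport]:
    """Drop sites with excessive coverage in enough samples.

    Excessive coverage flags likely collapsed duplications.  The per-sample
    threshold is ``mean + sd_fold * SD`` of that sample's coverage over its
    covered CpGs; a site is removed when it exceeds the threshold in at least
    ``ceil(min_fraction_samples * n_samples)`` samples.  The trim is
    iterated to a fixed point (removing the tail lowers the threshold, so a
    single pass is not a projection); on typical data the first pass
    removes nearly everything.
    """
    n_samples = sites.coverage.shape[1]
    if n_samples == 1:
        needed = 1
    else:
        needed = math.ceil(min_fraction_samples * n_samples)
    n_input = sites.n_sites
    removed = 0
    while True:
        cov = sites.coverage
        thresh = cov.mean(axis=0) + sd_fold * cov.std(axis=0, ddof=1)
        exceeds = cov.gt(thresh, axis=1).sum(axis=1)
        bad = (exceeds >= needed).to_numpy()
        if not bad.any():
            break
        removed += int(bad.sum())
        sites = sites.select(~bad)
    report = FilterReport(
        "coverage_outliers", n_input, {"high_coverage": removed}
    )
    return sites, report


def filter_low_coverage(
    sites: SiteMatrix, min_reads: int = 3
) -> tuple[SiteMatrix, FilterReport]:
    """Keep sites covered by at least ``min_reads`` reads in every sample."""
    cov = sites.coverage
    ok = cov.notna().all(axis=1) & (cov.fillna(0) >= min_reads).all(axis=1)
    bad = (~ok).to_numpy()
    report = FilterReport(
        "low_coverage", sites.n_sites, {"below_min_reads": int(bad.sum())}
    )
    return sites.select(~bad), report


def filter_uninformative(
    sites: SiteMatrix, min_meth_reads: int = 2
) -> tuple[SiteMatrix, FilterReport]:
    """Drop saturated, incompletely covered, or near-zero-methylation sites.

    Removes, attributing each site to the first matching rule:
    (a) sites where every sample is at 100% methylation;
    (b) sites not covered in every sample;
    (c) sites where more than half of the samples have fewer than
    ``min_meth_reads`` methylated reads (strictly more than half).
    """
    cov = sites.coverage
    n_samples = cov.shape[1]
    covered_all = cov.notna().all(axis=1) & (cov.fillna(0) > 0).all(axis=1)
    levels = sites.levels
    saturated = covered_all & (levels == 1.0).all(axis=1)
    low_meth_n = (sites.meth.fillna(0) < min_meth_reads).sum(axis=1)
    mostly_unmeth = low_meth_n > n_samples / 2
    rule = np.where(
        saturated,
        "saturated",
        np.where(
            ~covered_all,
            "not_covered_in_all",
            np.where(mostly_unmeth, "low_methylated_reads", ""),
        ),
    )
    counts = {
        "saturated": int((rule == "saturated").sum()),
        "not_covered_in_all": int((rule == "not_covered_in_all").sum()),
        "low_methylated_reads": int((rule == "low_methylated_reads").sum()),
    }
    report = FilterReport("uninformative", sites.n_sites, counts)
    return sites.select(rule == ""), report


def run_site_filters(
    sites: SiteMatrix,
    snps: pd.DataFrame | None = None,
    snp_quality: float = 50.0,
    sd_fold: float = 2.0,
    min_fraction_samples: float = 0.5,
    min_reads: int = 3,
    min_meth_reads: int = 2,
) -> tuple[SiteMatrix, list[FilterReport]]:
    """Run the full site-filter chain in the fixed order.

    Order: SNP masking, coverage-outlier removal, low-coverage removal,
    uninformative-site removal.  Masking runs first so that a variant on
    either strand of a dyad removes the merged site.
    """
    reports: list[FilterReport] = []
    if snps is not None:
        sites, rep = mask_snp_cpgs(sites, snps, min_quality=snp_quality)
        reports.append(rep)
    sites, rep = filter_coverage_outliers(
        sites, sd_fold=sd_fold, min_fraction_samples=min_fraction_samples
    )
    reports.append(rep)
    sites, rep = filter_low_coverage(sites, min_reads=min_reads)
    reports.append(rep)
    sites, rep = filter_uninformative(sites, min_meth_reads=min_meth_reads)
    reports.append(rep)
    return sites, reports


def bisulfite_conversion_rate(
    chh_calls: pd.DataFrame,
    variant_positions: set[tuple[str, int]] | None = None,
) -> ConversionRateResult:
    """Conversion efficiency from CHH-context cytosines.

    ``chh_calls`` is a long call frame where ``n_unmeth`` counts reads in
    which the CHH cytosine was read as thymine (converted) and ``n_meth``
    counts unconverted reads.  CHH sites overlapping known variants are
    excluded; the rate is converted reads / total reads x 100.
    """
    if variant_positions:
        keep = [
            (c, p) not in variant_positions
            for c, p in zip(chh_calls["chrom"], chh_calls["pos"])
        ]
        chh_calls = chh_calls[np.asarray(keep, dtype=bool)]
    n_converted = int(chh_calls["n_unmeth"].sum())
    n_total = n_converted + int(chh_calls["n_meth"].sum())
    if n_total == 0:
        raise ValueError("conversion rate undefined: no CHH read counts")
    return ConversionRateResult(n_converted=n_converted, n_total=n_total)
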