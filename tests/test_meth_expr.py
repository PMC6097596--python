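import numpy as np
import pandas as pd
import pytest

from methylomap.io_formats import GeneModel
from methylomap.meth_expr import (
    dmc_expression_concordance,
    exclude_overlapping_genes,
    expression_density_by_meth_class,
    fpkm,
    gene_feature_methylation,
    quantile_meth_expr_regression,
)


class TestFpkm:
    def test_closed_form(self):
        assert fpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count_is_zero(self):
        assert fpkm(0, 500, 10**6) == 0.0

    def test_global_count_rescaling_invariance(self):
        counts = np.array([3, 17, 240])
        lengths = np.array([300, 1200, 5000])
        total = counts.sum()
        a = fpkm(counts, lengths, total)
        b = fpkm(2 * counts, lengths, 2 * total)
        assert np.allclose(a, b)

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            fpkm(5, 0, 100)


class TestOverlapExclusion:
    def test_single_shared_base_removes_both(self):
        genes = [
            GeneModel("a", "c1", "+", ((100, 200),)),
            GeneModel("b", "c1", "+", ((199, 300),)),
        ]
        assert exclude_overlapping_genes(genes) == []

    def test_nested_gene_removes_both(self):
        genes = [
            GeneModel("outer", "c1", "+", ((100, 200), (800, 900))),
            GeneModel("inner", "c1", "+", ((400, 500),)),
        ]
        # inner sits in outer's intron: spans overlap but exons do not
        assert {g.gene_id for g in exclude_overlapping_genes(genes)} == {
            "outer",
            "inner",
        }
        nested = [
            GeneModel("outer", "c1", "+", ((100, 500),)),
            GeneModel("inner", "c1", "+", ((200, 300),)),
        ]
        assert exclude_overlapping_genes(nested) == []

    def test_bruteforce_agreement_on_toy_set(self):
        genes = [
            GeneModel("g1", "c1", "+", ((0, 100),)),
            GeneModel("g2", "c1", "+", ((90, 150),)),  # overlaps g1
            GeneModel("g3", "c1", "+", ((200, 250),)),
            GeneModel("g4", "c1", "-", ((300, 360),)),
            GeneModel("g5", "c2", "+", ((0, 100),)),
        ]
        kept = {g.gene_id for g in exclude_overlapping_genes(genes)}
        # brute-force pairwise exon intersection
        def inter(a, b):
            return a.chrom == b.chrom and any(
                x1 < y2 and y1 < x2
                for x1, x2 in a.exons
                for y1, y2 in b.exons
            )

        bad = {
            g.gene_id
            for g in genes
            for h in genes
            if g is not h and inter(g, h)
        }
        assert kept == {g.gene_id for g in genes} - bad == {"g3", "g4", "g5"}

    def test_flank_rule_removes_close_neighbours(self):
        genes = [
            GeneModel("a", "c1", "+", ((1000, 1200),)),
            GeneModel("b", "c1", "+", ((1900, 2100),)),  # within 1 kb of a
        ]
        assert exclude_overlapping_genes(genes) == genes
        assert exclude_overlapping_genes(genes, include_flanks=True) == []


class TestGeneFeatureMethylation:
    def test_zero_levels_excluded_from_feature_mean(self):
        gene = GeneModel("g", "c1", "+", ((0, 100), (200, 300)))
        sites = pd.DataFrame(
            {
                "chrom": "c1",
                "pos": [10, 20, 30],
                "level": [0.0, 0.4, 0.6],
            }
        )
        out = gene_feature_methylation(sites, [gene]).set_index("gene_id")
        assert out.loc["g", "mean_meth_exon1"] == pytest.approx(0.5)

    def test_feature_without_nonzero_cpgs_is_missing(self):
        gene = GeneModel("g", "c1", "+", ((0, 100), (200, 300)))
        sites = pd.DataFrame({"chrom": "c1", "pos": [10], "level": [0.0]})
        out = gene_feature_methylation(sites, [gene]).set_index("gene_id")
        assert np.isnan(out.loc["g", "mean_meth_exon1"])
        assert out.loc["g", "hm_class_exon1"] is None

    def test_exons_2_4_uses_available_exons_only(self):
        # 3-exon gene: exons 2-4 mean covers exons 2 and 3 only
        gene = GeneModel("g", "c1", "+", ((0, 100), (200, 300), (400, 500)))
        sites = pd.DataFrame(
            {
                "chrom": "c1",
                "pos": [250, 450],
                "level": [0.2, 0.8],
            }
        )
        out = gene_feature_methylation(sites, [gene]).set_index("gene_id")
        assert out.loc["g", "mean_meth_exons2_4"] == pytest.approx(0.5)
        # brute force per exon: exon2 mean 0.2, exon3 mean 0.8
        single = GeneModel("s", "c1", "+", ((0, 100),))
        out1 = gene_feature_methylation(sites, [single]).set_index("gene_id")
        assert np.isnan(out1.loc["s", "mean_meth_exons2_4"])


def _summaries(meths):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(meths))],
            "mean_meth_exons2_4": meths,
        }
    )


class TestQuantileRegression:
    def test_recovers_planted_positive_coupling(self):
        rng = np.random.default_rng(21)
        meth = rng.uniform(0, 1, size=400)
        expr = pd.Series(
            np.exp(2.5 * meth + rng.normal(0, 0.4, size=400)),
            index=[f"g{i}" for i in range(400)],
        )
        res = quantile_meth_expr_regression(
            _summaries(meth), expr, n_quantiles=25
        )
        assert res.slope > 0 and res.p_value < 0.01
        assert res.n_genes == 400
        assert res.genes_per_quantile == pytest.approx(16.0)

    def test_recovers_planted_negative_coupling(self):
        rng = np.random.default_rng(22)
        meth = rng.uniform(0, 1, size=400)
        expr = pd.Series(
            np.exp(-2.5 * meth + rng.normal(0, 0.4, size=400)),
            index=[f"g{i}" for i in range(400)],
        )
        res = quantile_meth_expr_regression(
            _summaries(meth), expr, n_quantiles=25
        )
        assert res.slope < 0 and res.p_value < 0.01

    def test_null_coupling_rarely_significant(self):
        """Expression independent of methylation: the regression p-value is
        roughly uniform, so p < 0.05 in about 5% of replicates."""
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(100):
            meth = rng.uniform(0, 1, size=120)
            expr = pd.Series(
                np.exp(rng.normal(0, 1, size=120)),
                index=[f"g{i}" for i in range(120)],
            )
            res = quantile_meth_expr_regression(
                _summaries(meth), expr, n_quantiles=12
            )
            hits += res.p_value < 0.05
        assert hits <= 10

    def test_gene_order_invariance_with_stable_ties(self):
        rng = np.random.default_rng(24)
        meth = np.round(rng.uniform(0, 1, size=60), 1)  # many ties
        expr = pd.Series(
            rng.uniform(1, 100, size=60), index=[f"g{i}" for i in range(60)]
        )
        s = _summaries(meth)
        r1 = quantile_meth_expr_regression(s, expr, n_quantiles=6)
        r2 = quantile_meth_expr_regression(
            s.sample(frac=1, random_state=9), expr, n_quantiles=6
        )
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_constant_methylation_is_degenerate(self):
        expr = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            quantile_meth_expr_regression(
                _summaries(np.full(10, 0.3)), expr, n_quantiles=5
            )


class TestExpressionDensity:
    def test_kruskal_wallis_hand_example(self):
        # groups [1,2], [3,4], [5,6] -> H = 32/7
        summaries = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "mean_meth_exons2_4": [0.9, 0.8, 0.3, 0.2, np.nan, np.nan],
            }
        )
        expr = pd.Series(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            index=[f"g{i}" for i in range(6)],
        )
        out = expression_density_by_meth_class(summaries, expr)
        assert out["H"] == pytest.approx(32 / 7)

    def test_single_class_is_an_error(self):
        summaries = pd.DataFrame(
            {"gene_id": ["a", "b"], "mean_meth_exons2_4": [0.9, 0.8]}
        )
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            expression_density_by_meth_class(summaries, expr)


class TestConcordance:
    def _tables(self, table):
        """Build DMC + DE tables realising the given 2x2 direction counts."""
        rows, de_rows = [], []
        gid = 0
        for (mu, eu), n in zip(
            [(1, 1), (1, -1), (-1, 1), (-1, -1)],
            [table[0][0], table[0][1], table[1][0], table[1][1]],
        ):
            for _ in range(n):
                g = f"g{gid}"
                gid += 1
                rows.append((g, 60.0 * mu))
                de_rows.append((g, 2.5 * eu, 0.001))
        dmcs = pd.DataFrame(rows, columns=["gene_id", "meth_diff"])
        de = pd.DataFrame(de_rows, columns=["gene_id", "log2fc", "adj_p"])
        return dmcs, de

    def test_hand_computed_two_by_two(self):
        # n(ad - bc)^2 / (r1 r2 c1 c2) = 100*(1600-100)^2 / 50^4 = 36
        dmcs, de = self._tables([[40, 10], [10, 40]])
        out = dmc_expression_concordance(dmcs, de, min_abs_meth_diff=50)
        assert out["chi2"] == pytest.approx(36.0)
        assert out["concordant_fraction"] == pytest.approx(0.8)

    def test_perfect_concordance(self):
        dmcs, de = self._tables([[50, 0], [0, 50]])
        out = dmc_expression_concordance(dmcs, de, min_abs_meth_diff=50)
        assert out["chi2"] == pytest.approx(100.0)

    def test_zero_margin_is_an_error(self):
        dmcs, de = self._tables([[10, 0], [5, 0]])
        with pytest.raises(ValueError):
            dmc_expression_concordance(dmcs, de, min_abs_meth_diff=50)

    def test_threshold_filters_small_changes(self):
        dmcs = pd.DataFrame(
            {"gene_id": ["a", "b"], "meth_diff": [40.0, 60.0]}
        )
        de = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2fc": [1.0, 1.0], "adj_p": [0.5, 0.5]}
        )
        with pytest.raises(ValueError):  # only one DMC survives -> zero margin
            dmc_expression_concordance(dmcs, de, min_abs_meth_diff=50)
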