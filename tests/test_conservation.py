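import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylomap.conservation import (
    CATEGORIES,
    assign_category,
    hypergeometric_ora,
    joint_cluster,
    orthogroup_meth_expr,
    ranked_methylation_clustering,
    ranked_sum_conservation,
    top_n_by_methylation,
)
from methylomap.synthetic_data import (
    DEFAULT_SPECIES_CLADES,
    simulate_orthogroups,
)

CLADES = DEFAULT_SPECIES_CLADES


class TestAssignCategory:
    @pytest.mark.parametrize(
        "species,expected",
        [
            (["dmagna"], "species_specific"),
            (["dmagna", "dpulex"], "daphnia_specific"),
            (["amellifera", "nvitripennis"], "hymenoptera_specific"),
            (["dmagna", "amellifera"], "arthropod_specific"),
            (["hsapiens", "mmusculus"], "mammal_specific"),
            (["amellifera", "hsapiens"], "common"),
            (["dmagna", "dpulex", "hsapiens"], "common"),
        ],
    )
    def test_clade_rules(self, species, expected):
        assert assign_category(species, CLADES) == expected

    def test_unknown_species_is_an_error(self):
        with pytest.raises(KeyError):
            assign_category(["martian"], CLADES)

    @given(
        members=st.lists(
            st.sampled_from(sorted(CLADES)), min_size=1, max_size=6
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_total_function_onto_known_categories(self, members):
        """Every orthogroup gets exactly one of the six categories."""
        assert assign_category(members, CLADES) in CATEGORIES


class TestOrthogroupProfiles:
    def _inputs(self):
        og = pd.DataFrame(
            {
                "orthogroup_id": ["OG1"] * 3 + ["OG2"] * 3 + ["OG3"] * 3,
                "species": ["dmagna", "amellifera", "hsapiens"] * 3,
                "gene_id": [f"g{i}" for i in range(9)],
            }
        )
        gm = pd.DataFrame(
            {
                "species": og["species"],
                "gene_id": og["gene_id"],
                "mean_meth_exons2_4": [0.2, 0.3, 0.9, 0.4, 0.5, 0.5, 0.6, 0.7, 0.1],
                "mean_meth_exon1": [0.8, 0.7, 0.0, 0.6, 0.5, 0.25, 0.4, 0.3, 0.5],
            }
        )
        expr = pd.DataFrame(
            {
                "species": og["species"],
                "gene_id": og["gene_id"],
                "expr": np.arange(9, dtype=float),
            }
        )
        return gm, expr, og

    def test_feature_rule_and_scaling_reversal(self):
        gm, expr, og = self._inputs()
        prof = orthogroup_meth_expr(gm, expr, og, CLADES).set_index(
            ["orthogroup_id", "species"]
        )
        # arthropods use exons 2-4, mammals exon 1
        assert prof.loc[("OG1", "dmagna"), "mean_meth"] == 0.2
        assert prof.loc[("OG1", "hsapiens"), "mean_meth"] == 0.0
        # mammal raw min (0.0) scales to 0 then reverses to 1
        assert prof.loc[("OG1", "hsapiens"), "scaled_meth"] == 1.0
        # midpoint of the species range is a fixed point of the reversal
        assert prof.loc[("OG2", "hsapiens"), "scaled_meth"] == 0.5

    def test_orthogroup_mean_of_two_genes(self):
        og = pd.DataFrame(
            {
                "orthogroup_id": ["OG1", "OG1"],
                "species": ["dmagna", "dmagna"],
                "gene_id": ["a", "b"],
            }
        )
        gm = pd.DataFrame(
            {
                "species": ["dmagna", "dmagna"],
                "gene_id": ["a", "b"],
                "mean_meth_exons2_4": [0.2, 0.4],
                "mean_meth_exon1": [0.1, 0.1],
            }
        )
        expr = pd.DataFrame(
            {"species": ["dmagna"], "gene_id": ["a"], "expr": [5.0]}
        )
        prof = orthogroup_meth_expr(gm, expr, og, CLADES)
        assert prof.iloc[0]["mean_meth"] == pytest.approx(0.3)

    @given(
        vals=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=3, max_size=20, unique=True
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_reversal_is_an_involution(self, vals):
        """reversed(x) = 1 - scaled(x), and reversing twice is the identity."""
        x = pd.Series(vals)
        scaled = (x - x.min()) / (x.max() - x.min())
        reversed_ = 1.0 - scaled
        assert np.allclose(1.0 - reversed_, scaled)
        assert ((reversed_ >= 0) & (reversed_ <= 1)).all()


class TestJointCluster:
    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(31)
        rows = []
        for i in range(60):
            high = i < 30
            for sp in ("dmagna", "hsapiens"):
                rows.append(
                    {
                        "orthogroup_id": f"OG{i:03d}",
                        "species": sp,
                        "clade": CLADES[sp],
                        "scaled_meth": (0.8 if high else 0.2) + rng.normal(0, 0.05),
                        "scaled_expr": (0.9 if high else 0.1) + rng.normal(0, 0.05),
                    }
                )
        prof = pd.DataFrame(rows)
        labels = joint_cluster(prof, k=2)
        truth = pd.Series(
            ["High" if int(i[2:]) < 30 else "Low" for i in labels.index],
            index=labels.index,
        )
        agreement = (labels == truth).mean()
        # Rand index for two balanced clusters >= 0.95 ~ label agreement
        assert agreement >= 0.95

    def test_identical_rows_warn_single_cluster(self):
        rows = []
        for i in range(8):
            rows.append(
                {
                    "orthogroup_id": f"OG{i}",
                    "species": "dmagna",
                    "clade": "daphnia",
                    "scaled_meth": 0.5,
                    "scaled_expr": 0.5,
                }
            )
        with pytest.warns(UserWarning, match="identical"):
            labels = joint_cluster(pd.DataFrame(rows), k=2)
        assert set(labels) == {"High"}


class TestRankedClustering:
    def test_identical_rank_vectors_share_a_subcluster(self):
        rng = np.random.default_rng(32)
        base = rng.uniform(0, 1, size=(10, 4))
        mat = pd.DataFrame(
            np.vstack([base, base[:1], base[:1]]),
            index=[f"g{i}" for i in range(12)],
            columns=list("abcd"),
        )
        out = ranked_methylation_clustering(mat, k=4)
        dup = out.loc[["g0", "g10", "g11"], "sub_cluster"]
        assert dup.nunique() == 1

    def test_planted_pattern_recovered(self):
        rng = np.random.default_rng(33)
        blocks = []
        for lo_a, lo_b in [(0.9, 0.9), (0.9, 0.1), (0.1, 0.9)]:
            block = np.column_stack(
                [
                    np.clip(lo_a + rng.normal(0, 0.03, 20), 0, 1),
                    np.clip(lo_a + rng.normal(0, 0.03, 20), 0, 1),
                    np.clip(lo_b + rng.normal(0, 0.03, 20), 0, 1),
                    np.clip(lo_b + rng.normal(0, 0.03, 20), 0, 1),
                ]
            )
            blocks.append(block)
        mat = pd.DataFrame(
            np.vstack(blocks),
            index=[f"g{i}" for i in range(60)],
            columns=["spA_1", "spA_2", "spB_1", "spB_2"],
        )
        out = ranked_methylation_clustering(mat, k=3)
        truth = np.repeat([0, 1, 2], 20)
        # majority label per planted block must be distinct and dominant
        agree = 0
        for b in range(3):
            sub = out["sub_cluster"].to_numpy()[truth == b]
            agree += (sub == np.bincount(sub).argmax()).sum()
        assert agree / 60 >= 0.9
        assert (out.loc["g0", ["class_spA_1", "class_spB_1"]] == "high").all()

    def test_more_clusters_than_genes_is_an_error(self):
        mat = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(3, 2)),
            index=list("abc"),
            columns=["s1", "s2"],
        )
        with pytest.raises(ValueError):
            ranked_methylation_clustering(mat, k=5)


class TestRankedSumConservation:
    def test_rank_sum_of_single_gene(self):
        # gene ranked 10th by methylation and 20th by expression -> 30
        n = 25
        meth = pd.Series(np.arange(n, dtype=float))
        expr = pd.Series(np.roll(np.arange(n, dtype=float), 10))
        cats = pd.Series(["common"] * 13 + ["species_specific"] * 12)
        out = ranked_sum_conservation(meth, expr, cats)
        gene9 = out["rank_sums"].iloc[9]  # meth rank 10
        assert gene9 == 10 + (np.argsort(np.argsort(expr))[9] + 1)

    def test_planted_conservation_link_orders_categories(self):
        og, truth = simulate_orthogroups(
            n_orthogroups=300, conservation_methylation_link=0.6, seed=5
        )
        arth = truth[truth["species"] == "dmagna"]
        out = ranked_sum_conservation(
            arth["latent_meth"].reset_index(drop=True),
            arth["latent_expr"].reset_index(drop=True),
            arth["category"].reset_index(drop=True),
        )
        med = out["medians_by_category"]
        assert med["common"] > med["daphnia_specific"] > med["species_specific"]
        assert out["p_value"] < 0.01

    def test_permutation_null_uniform(self):
        rng = np.random.default_rng(35)
        meth = pd.Series(rng.uniform(size=60))
        expr = pd.Series(rng.uniform(size=60))
        cats = pd.Series(rng.choice(["a", "b", "c"], size=60))
        out = ranked_sum_conservation(
            meth, expr, cats, n_permutations=100, seed=1
        )
        assert 0.0 < out["perm_p_value"] <= 1.0

    def test_rank_sum_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(36)
        meth = pd.Series(rng.uniform(size=40))
        expr = pd.Series(rng.uniform(size=40))
        cats = pd.Series(["a"] * 20 + ["b"] * 20)
        a = ranked_sum_conservation(meth, expr, cats)
        b = ranked_sum_conservation(np.exp(5 * meth), expr**3, cats)
        assert np.allclose(a["rank_sums"], b["rank_sums"])


class TestTopN:
    def _summaries(self):
        return pd.DataFrame(
            {
                "gene_id": ["gB", "gA", "gC", "gD", "gE"],
                "mean_meth_exons2_4": [0.9, 0.9, 0.5, 0.7, np.nan],
            }
        )

    def test_hand_checkable_order_and_tie_break(self):
        top = top_n_by_methylation(self._summaries(), n=3)
        assert top == ["gA", "gB", "gD"]  # tie at 0.9 broken by id

    def test_n_larger_than_genes_warns(self):
        with pytest.warns(UserWarning):
            top = top_n_by_methylation(self._summaries(), n=10)
        assert len(top) == 4  # NaN gene excluded


class TestHypergeometricOra:
    def test_matches_exact_summation_oracle(self):
        from math import comb

        N, K, n, k = 100, 10, 20, 2
        universe = {f"g{i}" for i in range(N)}
        gene_set = {f"g{i}" for i in range(K)}
        selected = {f"g{i}" for i in range(8, 8 + n)}  # overlap g8, g9 -> k=2
        out = hypergeometric_ora(selected, {"S": gene_set}, universe)
        p_exact = sum(
            comb(K, i) * comb(N - K, n - i) / comb(N, n) for i in range(k, min(K, n) + 1)
        )
        assert out.iloc[0]["overlap"] == k
        assert out.iloc[0]["p_value"] == pytest.approx(p_exact, rel=1e-12)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = {f"g{i}" for i in range(50)}
        out = hypergeometric_ora(
            {f"g{i}" for i in range(10)},
            {"S": {f"g{i}" for i in range(40, 45)}},
            universe,
        )
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_set_equal_to_universe(self):
        universe = {f"g{i}" for i in range(30)}
        out = hypergeometric_ora(
            {f"g{i}" for i in range(7)}, {"S": set(universe)}, universe
        )
        assert out.iloc[0]["fold_enrichment"] == pytest.approx(1.0)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            hypergeometric_ora({"g"}, {"S": {"g"}}, set())
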