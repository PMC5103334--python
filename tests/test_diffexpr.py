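import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnome.diffexpr import (
    NBDifferentialExpression,
    accumulate_go_expression,
    bh_adjust,
    call_de,
    correlation_cluster,
    filter_expressed,
    intersect_de,
    nb_de_test,
    pca,
    quantile_normalize,
    size_factors_median_ratio,
    tmm_factors,
)
from mirnome.records import CountMatrix

from _oracles import oracle_bh, oracle_complete_linkage_merges, oracle_tmm_log2


def nb_draws(rng, mu, dispersion, size=None):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mu, dtype=float)), size=size)


class TestQuantileNormalize:
    def test_hand_computed_two_by_two(self):
        m = pd.DataFrame([[1.0, 3.0], [2.0, 4.0]], columns=["a", "b"])
        out = quantile_normalize(m)
        assert out.values.tolist() == [[2.0, 2.0], [3.0, 3.0]]

    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        assert quantile_normalize(m).equals(m)

    def test_columns_share_sorted_vectors_and_idempotence(self):
        # tie-free expression values: the defining property is then exact
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.gamma(5, 10, size=(40, 5)), columns=list("abcde"))
        out = quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out.values[:, j]), ref)
        assert np.allclose(out.sum(axis=0), out.sum(axis=0).iloc[0])
        assert np.allclose(quantile_normalize(out).values, out.values)

    def test_ties_receive_the_mean_quantile_value(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 10.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_column_sums_identical_even_with_ties(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.poisson(20, size=(50, 4)).astype(float),
                         columns=list("abcd"))
        out = quantile_normalize(m)
        assert np.allclose(out.sum(axis=0), out.sum(axis=0).iloc[0])


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame(np.tile(np.arange(1, 30.0), (3, 1)).T, columns=list("abc"))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_pure_depth_difference_is_absorbed(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, 300).astype(float) + 1
        m = pd.DataFrame({"a": base, "b": 2 * base, "c": base})
        assert np.allclose(tmm_factors(m, reference_library="a"), 1.0, atol=1e-6)

    def test_matches_published_formula_oracle_with_asymmetric_features(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(80, 400).astype(float) + 1
        obs = base.copy()
        high = rng.choice(400, size=40, replace=False)
        obs[high] *= 8  # 10% high-count asymmetric features
        m = pd.DataFrame({"ref": base, "obs": obs})
        factors = tmm_factors(m, reference_library="ref")
        expected_log = oracle_tmm_log2(list(obs), list(base))
        expected = 2.0 ** np.array([0.0, expected_log])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(factors.to_numpy(), expected, rtol=0.05)

    def test_all_zero_library_is_an_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError):
            tmm_factors(m)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame(np.tile(np.arange(1, 20.0), (4, 1)).T, columns=list("abcd"))
        assert np.allclose(size_factors_median_ratio(m), 1.0)

    def test_doubled_column_has_double_factor(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(60, 100).astype(float) + 1
        m = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = size_factors_median_ratio(m)
        assert sf["c"] / sf["a"] == pytest.approx(2.0)

    def test_recovers_planted_depth_multipliers(self):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 500))
        depths = np.array([1.0, 2.0, 0.5, 1.5])
        m = pd.DataFrame(
            {f"l{j}": nb_draws(rng, mu * d, 0.05) for j, d in enumerate(depths)}
        )
        sf = size_factors_median_ratio(m).to_numpy()
        sf = sf / np.exp(np.mean(np.log(sf)))
        truth = depths / np.exp(np.mean(np.log(depths)))
        assert np.all(np.abs(sf / truth - 1) < 0.10)

    def test_no_universally_expressed_feature_is_an_error(self):
        m = pd.DataFrame({"a": [0.0, 5.0], "b": [3.0, 0.0]})
        with pytest.raises(ValueError):
            size_factors_median_ratio(m)


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_literal_definition_and_dominates_p(self, pvalues):
        adj = bh_adjust(pvalues)
        assert np.allclose(adj, oracle_bh(pvalues))
        assert np.all(adj >= np.asarray(pvalues) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallAndIntersect:
    def table(self, lfc, padj):
        return pd.DataFrame({"log2fc": [lfc], "padj": [padj]}, index=["f"])

    @pytest.mark.parametrize(
        "lfc,padj,alpha,expected",
        [
            (2.5, 0.005, 0.01, "up"),
            (2.0, 0.005, 0.01, "ns"),   # strict: |log2FC| must exceed 2
            (-3.0, 0.02, 0.01, "ns"),
            (-2.5, 0.005, 0.01, "down"),
        ],
    )
    def test_strict_thresholds(self, lfc, padj, alpha, expected):
        assert call_de(self.table(lfc, padj), 2.0, alpha).iloc[0] == expected

    def test_intersection_requires_agreement_in_every_comparison(self):
        calls = {
            "c1": {"a": "up", "b": "up", "c": "up", "d": "down"},
            "c2": {"a": "up", "b": "up", "d": "down"},
            "c3": {"a": "up", "b": "down", "d": "down"},
        }
        up, down = intersect_de(calls)
        assert up == {"a"}
        assert down == {"d"}
        assert "b" not in up and "b" not in down

    def test_intersection_bounded_by_smallest_call_set(self):
        calls = {
            "c1": {"a": "up", "b": "down"},
            "c2": {"a": "up", "b": "down", "c": "up"},
        }
        up, down = intersect_de(calls)
        assert len(up) + len(down) <= 2


class TestNBDifferentialExpression:
    def test_null_features_give_flat_fold_changes(self):
        rng = np.random.default_rng(6)
        mu = np.full(100, 500.0)
        m = pd.DataFrame(
            {f"l{j}": nb_draws(rng, mu, 0.05) for j in range(6)},
        )
        res = nb_de_test(m, ["l0", "l1", "l2"], ["l3", "l4", "l5"])
        assert res.table["log2fc"].abs().mean() < 0.3
        assert (res.table["call"] == "ns").all()

    def test_null_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(7)
        mu = np.exp(rng.uniform(np.log(20), np.log(200), 2000))
        m = pd.DataFrame({f"l{j}": nb_draws(rng, mu, 0.05) for j in range(6)})
        res = nb_de_test(m, ["l0", "l1", "l2"], ["l3", "l4", "l5"])
        fpr = float((res.table["pvalue"].dropna() < 0.05).mean())
        assert 0.03 <= fpr <= 0.07

    def test_sixteen_fold_effects_detected_with_high_power(self):
        hits = reps = 0
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            mu = np.exp(rng.uniform(np.log(20), np.log(200), 150))
            block = {f"l{j}": nb_draws(rng, mu, 0.05) for j in range(6)}
            planted = np.concatenate(
                [nb_draws(rng, np.full(3, 200.0), 0.05),
                 nb_draws(rng, np.full(3, 3200.0), 0.05)]
            )
            m = pd.DataFrame(block, index=[f"f{i}" for i in range(150)])
            m.loc["planted"] = planted
            res = nb_de_test(m, ["l0", "l1", "l2"], ["l3", "l4", "l5"], alpha=0.01)
            row = res.table.loc["planted"]
            reps += 1
            hits += row["call"] == "up" and row["padj"] < 0.01
        assert hits / reps >= 0.9

    def test_all_zero_features_are_excluded_as_na(self):
        m = pd.DataFrame(
            {"a": [10, 0, 8], "b": [12, 0, 9], "c": [9, 0, 30], "d": [11, 0, 40]},
            index=["x", "zero", "y"],
        )
        res = nb_de_test(m, ["a", "b"], ["c", "d"])
        assert np.isnan(res.table.loc["zero", "pvalue"])
        assert res.table.loc["zero", "call"] == "ns"

    def test_model_results_summary_reports_calls(self):
        rng = np.random.default_rng(8)
        mu = np.full(50, 100.0)
        m = pd.DataFrame({f"l{j}": nb_draws(rng, mu, 0.05) for j in range(6)})
        res = NBDifferentialExpression(m, ["l0", "l1", "l2"], ["l3", "l4", "l5"]).fit()
        text = res.summary()
        assert "features tested   : 50 / 50" in text
        assert res.size_factors.shape == (6,)


class TestExpressionPatternAnalyses:
    def test_identical_vectors_merge_first(self):
        rng = np.random.default_rng(9)
        base = rng.normal(10, 3, 12)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(10, 3, 12),
             "d": -base + 20}
        )
        out = correlation_cluster(m, axis="columns")
        first = sorted(out.linkage[0, :2].astype(int))
        assert [out.labels[i] for i in first] == ["a", "b"]
        assert out.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_at_distance_two(self):
        x = np.arange(10, dtype=float)
        m = pd.DataFrame({"a": x, "b": -x, "c": x * 2})
        out = correlation_cluster(m, axis="columns")
        from scipy.spatial.distance import squareform

        d = squareform(out.distance)
        ia, ib = out.labels.index("a"), out.labels.index("b")
        assert d[ia, ib] == pytest.approx(2.0)

    def test_merge_order_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(50, 10, size=(12, 10)),
                         columns=[f"v{i}" for i in range(10)])
        out = correlation_cluster(m, axis="columns")
        from scipy.spatial.distance import squareform

        dist = squareform(out.distance).tolist()
        expected = oracle_complete_linkage_merges(dist)
        observed = []
        n = len(out.labels)
        members = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, _, _) in enumerate(out.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            observed.append(merged)
        assert observed == expected

    def test_pca_variance_proportions_sum_to_one(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.poisson(40, (30, 6)).astype(float),
                         columns=[f"l{i}" for i in range(6)])
        res = pca(m)
        assert res.variance_ratio.sum() == pytest.approx(1.0)
        assert list(res.scores.index) == list(m.columns)

    def test_rank_one_matrix_loads_entirely_on_pc1(self):
        u = np.arange(1, 9, dtype=float)
        v = np.array([1.0, 2.0, 3.0])
        m = pd.DataFrame(np.outer(u, v), columns=["a", "b", "c"])
        res = pca(m)
        assert res.variance_ratio[0] == pytest.approx(1.0)

    def test_species_separate_in_pc_space(self, mrna_bundle):
        from mirnome.diffexpr import quantile_normalize

        m = quantile_normalize(mrna_bundle.counts)
        res = pca(m)
        scores = res.scores[["PC1", "PC2"]]
        species = mrna_bundle.counts.species
        focal = sorted(set(species.values()))[0]
        focal_libs = [l for l in scores.index if species[l] == focal]
        other_libs = [l for l in scores.index if species[l] != focal]
        within = max(
            np.linalg.norm(scores.loc[a] - scores.loc[b])
            for a in focal_libs for b in focal_libs
        )
        between = min(
            np.linalg.norm(scores.loc[a] - scores.loc[b])
            for a in focal_libs for b in other_libs
        )
        assert between > within


class TestGOAccumulation:
    def matrix(self):
        counts = pd.DataFrame(
            {"s1_l1": [2.0, 5.0], "s1_l2": [4.0, 5.0], "s2_l1": [8.0, 7.0]},
            index=["g1", "g2"],
        )
        species = {"s1_l1": "s1", "s1_l2": "s1", "s2_l1": "s2"}
        return CountMatrix(counts=counts, species=species)

    def test_mean_within_species_then_sum_over_genes(self):
        out = accumulate_go_expression(
            self.matrix(), {"g1": ["T1"], "g2": ["T1"]}, ["T1"]
        )
        assert out.loc["T1", "s1"] == pytest.approx(3.0 + 5.0)
        assert out.loc["T1", "s2"] == pytest.approx(8.0 + 7.0)

    def test_gene_in_two_terms_contributes_to_both(self):
        out = accumulate_go_expression(
            self.matrix(), {"g1": ["T1", "T2"]}, ["T1", "T2"]
        )
        assert out.loc["T1", "s1"] == out.loc["T2", "s1"] == pytest.approx(3.0)

    def test_term_without_genes_warns_and_reports_zero(self):
        with pytest.warns(UserWarning):
            out = accumulate_go_expression(self.matrix(), {"g1": ["T1"]}, ["T9"])
        assert (out.loc["T9"] == 0).all()

    def test_linearity_in_the_expression_matrix(self):
        m = self.matrix()
        doubled = m.with_counts(m.counts * 2)
        go = {"g1": ["T1"], "g2": ["T1"]}
        a = accumulate_go_expression(m, go, ["T1"])
        b = accumulate_go_expression(doubled, go, ["T1"])
        assert np.allclose(b.values, 2 * a.values)


class TestFilterExpressed:
    def test_all_zero_rows_removed_and_single_count_retained(self):
        m = pd.DataFrame(
            {"a": [0, 1, 0], "b": [0, 0, 0]}, index=["z1", "keep", "z2"]
        )
        out = filter_expressed(m)
        assert list(out.index) == ["keep"]

    def test_matrix_without_zero_rows_unchanged(self):
        m = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        assert filter_expressed(m).equals(m)
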