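"""Offset-anchored similarity, family coherence, bootstrap null, diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import family, make_expression, make_layout
from oracles import naive_pearson, naive_singleton_score

from coregulon.coherence import (
    bin_for_histogram,
    bootstrap_null,
    family_scores,
    pairwise_similarity_matrix,
    selection_uniformity,
    similarity,
)
from coregulon.genome import partition_family

finite_vectors = st.lists(
    st.floats(min_value=-50, max_value=50), min_size=4, max_size=12
)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        x = np.array([0.0, 1.0, -2.0, 3.0])
        assert similarity(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_proportional_through_origin(self):
        assert similarity(np.array([1.0, 2.0]), np.array([2.0, 4.0])) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert similarity(np.array([1.0, -1.0]), np.array([-1.0, 1.0])) == pytest.approx(-1.0)

    def test_mean_offsets_reduce_to_pearson(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            s = similarity(x, y, x_offset=x.mean(), y_offset=y.mean())
            assert s == pytest.approx(naive_pearson(x, y), abs=1e-10)

    def test_constant_at_offset_is_undefined_not_zero(self):
        x = np.zeros(5)
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert np.isnan(similarity(x, y))
        assert np.isnan(similarity(y, x))

    def test_missing_positions_excluded(self):
        x = np.array([0.0, 1.0, np.nan, 2.0])
        y = np.array([0.0, 2.0, 5.0, 4.0])
        assert similarity(x, y) == pytest.approx(
            similarity(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 4.0]))
        )

    @given(finite_vectors, finite_vectors)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        s = similarity(x, y)
        if not np.isnan(s):
            assert -1.0 <= s <= 1.0
            assert s == pytest.approx(similarity(y, x), abs=1e-12)
            # invariant to positive rescaling of a centred vector
            assert similarity(3.5 * x, y) == pytest.approx(s, abs=1e-12)


class TestFamilyScores:
    def layout_and_expr(self, vectors):
        genes = sorted(vectors)
        layout = make_layout({"chr1": genes})
        expr = make_expression({"c1": vectors})
        return layout, expr

    def test_identical_singletons_score_one(self):
        v = [0.0, 1.0, 2.0, 1.0]
        layout = make_layout({"chr1": ["a", "mid", "b"]})
        expr = make_expression({"c1": {"a": v, "b": v}})
        part = partition_family(layout, family("a", "b"))
        res = family_scores(part, expr)
        assert res.singleton_score == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(res.cluster_score)

    def test_anticorrelated_pair_scores_minus_one(self):
        layout = make_layout({"chr1": ["a", "b", "far1", "far2", "s1", "far3", "s2"]})
        expr = make_expression(
            {"c1": {"a": [0, 1, -2], "b": [0, -1, 2], "s1": [0, 1, 1], "s2": [0, 1, 0]}}
        )
        part = partition_family(layout, family("a", "b", "s1", "s2"))
        res = family_scores(part, expr)
        assert res.cluster_score == pytest.approx(-1.0, abs=1e-12)
        assert res.n_clustered == 2 and res.n_singletons == 2

    def test_four_singletons_match_brute_force(self):
        rng = np.random.default_rng(3)
        vectors = {f"s{i}": rng.normal(size=6).tolist() for i in range(4)}
        order = ["s0", "gap1", "s1", "gap2", "s2", "gap3", "s3"]
        layout = make_layout({"chr1": order})
        expr = make_expression({"c1": vectors})
        part = partition_family(layout, family("s0", "s1", "s2", "s3"))
        res = family_scores(part, expr)
        assert res.singleton_score == pytest.approx(
            naive_singleton_score(vectors, ["s0", "s1", "s2", "s3"]), abs=1e-12
        )

    def test_cluster_score_averages_over_clusters(self):
        # two 2-gene clusters with known pair scores 1 and -1 average to 0
        layout = make_layout({"chr1": ["a", "b", "gap", "c", "d"]})
        expr = make_expression(
            {"c1": {"a": [0, 1, 2], "b": [0, 2, 4], "c": [0, 1, -1], "d": [0, -1, 1]}}
        )
        part = partition_family(layout, family("a", "b", "c", "d"))
        res = family_scores(part, expr)
        assert res.cluster_score == pytest.approx(0.0, abs=1e-12)

    def test_three_gene_cluster_all_pairs_vs_adjacent_only(self):
        rng = np.random.default_rng(9)
        vecs = {g: rng.normal(size=8).tolist() for g in ("a", "b", "c")}
        layout = make_layout({"chr1": ["a", "b", "c"]})
        expr = make_expression({"c1": vecs})
        part = partition_family(layout, family("a", "b", "c"))
        v = {g: np.asarray(vecs[g]) for g in vecs}
        all_pairs = np.mean(
            [similarity(v[a], v[b]) for a, b in itertools.combinations("abc", 2)]
        )
        adj_pairs = np.mean([similarity(v["a"], v["b"]), similarity(v["b"], v["c"])])
        assert family_scores(part, expr).cluster_score == pytest.approx(all_pairs)
        assert family_scores(part, expr, cluster_pairing="adjacent").cluster_score == (
            pytest.approx(adj_pairs)
        )

    def test_per_condition_mode_reports_each_condition(self):
        layout = make_layout({"chr1": ["a", "b", "gap", "s1", "gap2", "s2"]})
        expr = make_expression(
            {"c1": {"a": [0, 1, 2], "b": [0, 1, 2], "s1": [0, 1, 0], "s2": [0, 0, 1]},
             "c2": {"a": [0, 1, -1], "b": [0, -1, 1], "s1": [0, 2, 1], "s2": [0, 2, 1]}}
        )
        part = partition_family(layout, family("a", "b", "s1", "s2"))
        res = family_scores(part, expr, mode="per_condition")
        assert set(res.per_condition) == {"c1", "c2"}
        assert res.per_condition["c1"][1] == pytest.approx(1.0)
        assert res.per_condition["c2"][1] == pytest.approx(-1.0)

    def test_undefined_pairs_excluded_and_counted(self, caplog):
        layout = make_layout({"chr1": ["a", "b", "gap", "s1", "g2", "s2", "g3", "s3"]})
        expr = make_expression(
            {"c1": {"a": [0, 1, 2], "b": [0, 1, 1], "s1": [0, 0, 0],  # zero phi
                    "s2": [0, 1, 3], "s3": [0, 2, 1]}}
        )
        part = partition_family(layout, family("a", "b", "s1", "s2", "s3"))
        with caplog.at_level("WARNING"):
            res = family_scores(part, expr)
        assert res.n_excluded_pairs == 2  # s1 paired with s2 and with s3
        assert not np.isnan(res.singleton_score)


class TestBootstrapNull:
    def setup_family(self, n_genes=12, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        if identical:
            base = rng.normal(size=10)
            vecs = {f"g{i}": base.tolist() for i in range(n_genes)}
        else:
            vecs = {f"g{i}": rng.normal(size=10).tolist() for i in range(n_genes)}
        layout = make_layout({"chr1": sorted(vecs)})
        expr = make_expression({"c1": vecs})
        fam = family(*vecs, fid="bf")
        return fam, expr

    def test_degenerate_identical_profiles(self):
        fam, expr = self.setup_family(identical=True)
        null = bootstrap_null(fam, expr, group_size=6, n_iterations=300, seed=1)
        np.testing.assert_allclose(null.null_scores, 1.0)

    def test_same_seed_reproducible(self):
        fam, expr = self.setup_family()
        a = bootstrap_null(fam, expr, group_size=6, n_iterations=400, seed=9)
        b = bootstrap_null(fam, expr, group_size=6, n_iterations=400, seed=9)
        np.testing.assert_array_equal(a.null_scores, b.null_scores)
        assert a.selection_counts == b.selection_counts

    def test_selection_counts_sum(self):
        fam, expr = self.setup_family()
        null = bootstrap_null(fam, expr, group_size=8, n_iterations=250, seed=2)
        assert sum(null.selection_counts.values()) == 250 * 8

    def test_self_pairs_redrawn(self):
        fam, expr = self.setup_family(n_genes=2)
        null = bootstrap_null(fam, expr, group_size=2, n_iterations=500, seed=3)
        # only one distinct pair exists, so every score equals its S
        assert np.unique(null.null_scores).size == 1
        assert null.n_self_pair_redraws > 0

    def test_percentile_uses_plus_one_correction(self):
        fam, expr = self.setup_family()
        null = bootstrap_null(
            fam, expr, group_size=6, n_iterations=100, seed=4, observed_score=2.0
        )
        assert null.empirical_percentile == pytest.approx(101 / 101)
        assert null.upper_percentile == pytest.approx(1 / 101)

    def test_validation(self):
        fam, expr = self.setup_family()
        with pytest.raises(ValueError):
            bootstrap_null(fam, expr, group_size=5, n_iterations=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_null(fam, expr, group_size=4, n_iterations=0, seed=0)

    def test_percentile_calibration_under_own_null(self):
        # an observed score drawn from the null itself has a uniform percentile
        fam, expr = self.setup_family(n_genes=8, seed=6)
        S = pairwise_similarity_matrix(expr, sorted(fam.members))
        rng = np.random.default_rng(123)
        pct = []
        for rep in range(200):
            null = bootstrap_null(fam, expr, group_size=4, n_iterations=150, seed=1000 + rep)
            idx = rng.integers(0, 8, size=(2, 2))
            while (idx[0] == idx[1]).any():
                idx = rng.integers(0, 8, size=(2, 2))
            obs = S[idx[0], idx[1]].mean()
            r = np.sum(null.null_scores <= obs)
            pct.append((r + 1) / (null.n_iterations + 1))
        assert stats.kstest(pct, "uniform").pvalue > 1e-3


class TestHistogramAndDiagnostics:
    def test_floor_clamping(self):
        edges, counts = bin_for_histogram(np.array([-0.5, -0.2, 0.3]), floor=-0.1, bin_width=0.2)
        assert counts.sum() == 3
        assert counts[0] == 2  # both sub-floor values land in the floor bin
        assert edges[0] == pytest.approx(-0.1)

    def test_no_clamp_when_all_above_floor(self):
        scores = np.array([0.05, 0.4, 0.9])
        edges, counts = bin_for_histogram(scores, bin_width=0.5)
        raw, _ = np.histogram(scores, bins=edges)
        np.testing.assert_array_equal(counts, raw)

    def test_empty_input(self):
        edges, counts = bin_for_histogram(np.array([]))
        assert counts.size == 0

    def test_counts_sum_property(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(-1, 1, size=500)
        _, counts = bin_for_histogram(scores, bin_width=0.07)
        assert counts.sum() == 500

    def test_uniform_counts_zero_cv(self):
        diag = selection_uniformity({f"g{i}": 50 for i in range(10)})
        assert diag.cv == 0.0 and not diag.bias_warning

    def test_never_selected_gene_flags_bias(self):
        counts = {f"g{i}": 100 for i in range(10)}
        counts["g9"] = 0
        assert selection_uniformity(counts).bias_warning

    def test_fair_sampling_passes_chi_square(self):
        rng = np.random.default_rng(8)
        draws = rng.integers(0, 40, size=10_000 * 4)
        counts = {f"g{i}": int((draws == i).sum()) for i in range(40)}
        diag = selection_uniformity(counts)
        assert diag.chisq_p > 1e-3 and not diag.bias_warning
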