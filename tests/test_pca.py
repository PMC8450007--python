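import numpy as np
import pandas as pd
import pytest

from phylostab import (
    DataError,
    ValidationError,
    build_support_matrix,
    group_dispersion,
    parse_newick,
    run_pca,
    summarize_tree_stats,
    total_tree_length,
    variable_contributions,
)


def svd_route(x, standardize):
    """Independent PCA via numpy SVD (the cross-check route)."""
    x = np.asarray(x, dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        x = x[:, sd > 0]
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    else:
        x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (x.shape[0] - 1)
    return eig, u * s, vt.T


class TestRunPCA:
    def test_identical_rows_zero_eigenvalues(self):
        x = np.tile([3.0, 1.0, 4.0], (5, 1))
        p = run_pca(x, standardize=False)
        assert np.allclose(p.eigenvalues, 0.0)
        assert np.allclose(p.scores, 0.0)
        assert np.allclose(p.explained, 0.0)

    def test_two_by_two_worked_example(self):
        p = run_pca(np.array([[0.0, 0.0], [2.0, 2.0]]), standardize=False)
        assert np.allclose(p.eigenvalues, [4.0, 0.0])
        # covariance [[2,2],[2,2]] -> leading eigenvector (1,1)/sqrt(2)
        assert np.allclose(np.abs(p.loadings[:, 0]), 1 / np.sqrt(2))

    @pytest.mark.parametrize("standardize", [True, False])
    @pytest.mark.parametrize("shape", [(5, 3), (10, 8), (20, 40)])
    def test_reconstruction_identity(self, shape, standardize):
        rng = np.random.default_rng(hash(shape) % 2**32)
        x = rng.normal(size=shape)
        p = run_pca(x, standardize=standardize)
        centered = (
            (x - x.mean(0)) / x.std(0, ddof=1) if standardize else x - x.mean(0)
        )
        assert np.allclose(p.scores @ p.loadings.T, centered, atol=1e-8)

    @pytest.mark.parametrize("standardize", [True, False])
    @pytest.mark.parametrize("seed", range(5))
    def test_svd_cross_check(self, seed, standardize):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 30)), int(rng.integers(2, 60))
        x = rng.normal(size=(n, m)) * rng.uniform(0.5, 3, size=m)
        p = run_pca(x, standardize=standardize)
        eig, scores, loadings = svd_route(x, standardize)
        k = min(len(eig), len(p.eigenvalues))
        assert np.allclose(p.eigenvalues[:k], eig[:k], atol=1e-8)
        for j in range(k):
            if eig[j] < 1e-10:
                continue
            a, b = p.scores[:, j], scores[:, j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_sklearn_cross_check(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(99)
        x = rng.normal(size=(15, 6))
        p = run_pca(x, standardize=False)
        sk = SkPCA().fit(x)
        assert np.allclose(p.eigenvalues[:6], sk.explained_variance_, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        p = run_pca(rng.normal(size=(12, 7)))
        gram = p.loadings.T @ p.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_zero_variance_columns_dropped(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        p = run_pca(x, standardize=True)
        assert p.dropped == ["var1"]
        assert p.column_ids == ["var0"]

    def test_all_zero_variance_errors(self):
        with pytest.raises(DataError, match="zero variance"):
            run_pca(np.ones((4, 3)), standardize=True)

    def test_missing_entries_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(DataError, match="missing"):
            run_pca(x, standardize=False)

    def test_single_row_rejected(self):
        with pytest.raises(DataError, match=">=2 rows"):
            run_pca(np.ones((1, 3)))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(9, 5))
        perm = rng.permutation(9)
        p1 = run_pca(x)
        p2 = run_pca(x[perm])
        assert np.allclose(p1.eigenvalues, p2.eigenvalues, atol=1e-10)
        assert np.allclose(p1.scores[perm], p2.scores, atol=1e-8)
        assert np.allclose(p1.contributions, p2.contributions, atol=1e-10)

    def test_explained_sums_to_one(self):
        rng = np.random.default_rng(11)
        p = run_pca(rng.normal(size=(10, 4)))
        assert abs(p.explained.sum() - 1.0) < 1e-9

    def test_matrix_input(self, small_treeset):
        ts, _ = small_treeset
        m = build_support_matrix(ts)
        p = run_pca(m)
        assert p.scores.shape[0] == len(ts)
        assert p.column_ids  # split encodings, not varN
        assert all("|" in c for c in p.column_ids)


class TestContributions:
    def test_sum_to_100_per_component(self):
        rng = np.random.default_rng(5)
        p = run_pca(rng.normal(size=(8, 5)))
        assert np.allclose(p.contributions.sum(axis=0), 100.0, atol=1e-9)

    def test_even_eigenvector_fifty_fifty(self):
        # rows along the diagonal -> leading eigenvector (1,1)/sqrt(2)
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        p = run_pca(x, standardize=False)
        ranked = variable_contributions(p, 0)
        assert [round(v, 9) for _, v in ranked] == [50.0, 50.0]
        # stable tie-break: original column order
        assert [name for name, _ in ranked] == ["var0", "var1"]

    def test_single_retained_variable(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]])
        p = run_pca(x, standardize=True)
        assert variable_contributions(p, 0) == [("var0", 100.0)]

    def test_squares_of_loadings(self):
        rng = np.random.default_rng(21)
        p = run_pca(rng.normal(size=(10, 5)))
        for k in range(p.n_components):
            vals = dict(variable_contributions(p, k))
            for j, name in enumerate(p.column_ids):
                assert vals[name] == pytest.approx(
                    100 * p.loadings[j, k] ** 2, abs=1e-12
                )

    def test_invalid_component(self):
        p = run_pca(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValidationError):
            variable_contributions(p, 99)


class TestDispersion:
    def test_single_tree_strategy_zero(self):
        rng = np.random.default_rng(1)
        p = run_pca(rng.normal(size=(5, 4)))
        rep = group_dispersion(p, ["solo", "x", "x", "x", "x"], n_components=2)
        assert rep.dispersion["solo"] == 0.0

    def test_two_points_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 1.0], [0.0, 2.0]])
        p = run_pca(x, standardize=False)
        rep = group_dispersion(p, ["a", "a", "b", "b"], n_components=2)
        d = np.linalg.norm(p.scores[0, :2] - p.scores[1, :2])
        assert rep.dispersion["a"] == pytest.approx(d)

    def test_ranks_ascending_dense_first(self):
        scores = np.array(
            [[0, 0], [0.1, 0], [5, 5], [9, 9], [1, 1], [1.2, 1.1]], dtype=float
        )
        p = run_pca(scores, standardize=False)
        rep = group_dispersion(
            p, ["tight", "tight", "loose", "loose", "mid", "mid"], n_components=2
        )
        order = sorted(rep.rank, key=rep.rank.get)
        assert order == ["tight", "mid", "loose"]

    def test_duplication_keeps_centroid_does_not_increase_dispersion(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(6, 4))
        p1 = run_pca(x, standardize=False)
        rep1 = group_dispersion(p1, ["a"] * 3 + ["b"] * 3, n_components=2)
        x2 = np.vstack([x, x[:3]])  # duplicate every tree of strategy a
        p2 = run_pca(x2, standardize=False)
        rep2 = group_dispersion(p2, ["a"] * 3 + ["b"] * 3 + ["a"] * 3, 2)
        # mean pairwise distance among duplicated points never increases
        assert rep2.dispersion["a"] <= rep1.dispersion["a"] + 1e-9

    def test_k_exceeds_components(self):
        p = run_pca(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValidationError, match="exceeds"):
            group_dispersion(p, ["a"] * 4, n_components=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_noise_ordering(self, seed):
        rng = np.random.default_rng(seed)
        sigmas = {"a": 0.05, "b": 0.5, "c": 2.0}
        rows, labels = [], []
        center = rng.normal(size=6)
        for lab, sig in sigmas.items():
            for _ in range(8):
                rows.append(center + rng.normal(scale=sig, size=6))
                labels.append(lab)
        p = run_pca(np.array(rows), standardize=False)
        rep = group_dispersion(p, labels, n_components=2)
        assert sorted(rep.rank, key=rep.rank.get) == ["a", "b", "c"]

    def test_planted_backbone_separation(self, small_treeset):
        from sklearn.metrics import silhouette_score

        from phylostab import reduce_matrix

        ts, truth = small_treeset
        m = build_support_matrix(ts)
        reduced, _ = reduce_matrix(m, truth.scheme, min_support=0, min_presence=0.0)
        p = run_pca(reduced)
        labels = [s for s in ts.strategies]
        assert silhouette_score(p.scores[:, :2], labels) > 0


class TestTreeStats:
    def test_total_length_example(self):
        t = parse_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        assert total_tree_length(t) == pytest.approx(6.0)

    def test_all_zero(self):
        t = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        assert total_tree_length(t) == 0.0

    def test_missing_length_strict(self):
        t = parse_newick("((A:1,B),(C:1,D:1):0.5);")
        with pytest.raises(DataError, match="without a branch length"):
            total_tree_length(t)
        assert total_tree_length(t, strict=False) == pytest.approx(3.5)

    def test_additivity_random_tree(self, random_tree):
        tree = random_tree(12, 5)
        rng = np.random.default_rng(5)
        lengths = []
        for node in tree.postorder():
            if node is not tree.root:
                node.length = float(rng.exponential(0.1))
                lengths.append(node.length)
        assert total_tree_length(tree) == pytest.approx(sum(lengths))

    def test_summary_simple(self):
        df = pd.DataFrame({"strategy": ["s"] * 3, "total_length": [1.0, 2.0, 3.0]})
        out = summarize_tree_stats(df)
        row = out.iloc[0]
        assert row["median"] == 2.0 and row["mean"] == 2.0 and row["n"] == 3

    def test_quartiles_linear_interpolation(self):
        df = pd.DataFrame({"strategy": ["s"] * 4, "x": [1.0, 2.0, 3.0, 4.0]})
        row = summarize_tree_stats(df).iloc[0]
        assert row["q1"] == pytest.approx(1.75)
        assert row["q3"] == pytest.approx(3.25)

    def test_two_strategies_two_rows_per_metric(self):
        df = pd.DataFrame(
            {
                "strategy": ["a", "a", "b"],
                "total_length": [1.0, 2.0, 3.0],
                "log_likelihood": [-10.0, -11.0, -12.0],
            }
        )
        out = summarize_tree_stats(df)
        assert len(out) == 4
        assert set(out["strategy"]) == {"a", "b"}
        assert set(out["metric"]) == {"total_length", "log_likelihood"}
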