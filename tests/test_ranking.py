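"""Importance measures, meta feature table, clustering and feature sets."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from conftest import brute_silhouette
from stillstack.preprocess import DesignMatrix
from stillstack.ranking import (
    FeatureClustering,
    ImportanceVector,
    UnsupportedMeasureError,
    build_feature_set,
    build_mft,
    cluster_features,
    coef_importance,
    full_feature_set,
    gini_importance,
    mda_importance,
    mean_silhouette,
    normalize_mft,
    rank_clusters,
    select_k_candidates,
)
from stillstack.schema import ConfigurationError


def _dm(X, columns=None, y=None, sources=None):
    columns = columns or [f"f{i}" for i in range(X.shape[1])]
    sources = sources or {c: c for c in columns}
    return DesignMatrix(np.asarray(X, float), columns, sources, y)


def _clustering(index, labels, X):
    labels = np.asarray(labels)
    X = np.asarray(X, float)
    k = labels.max() + 1
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return FeatureClustering(
        k=int(k),
        assignment=pd.Series(labels, index=index),
        centroids=centroids,
        seed=0,
        wcss=0.0,
    )


# ---------------------------------------------------------------------------
# importance measures

class TestMDA:
    def test_constant_column_scores_exactly_zero(self):
        """Permuting a constant column is the identity, so MDA is 0."""
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=100), np.full(100, 3.0)])
        y = (X[:, 0] > 0).astype(int)
        model = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
        iv = mda_importance(model, _dm(X, y=y), n_repeats=5, seed=1)
        assert iv.scores["f1"] == 0.0

    def test_separable_stump_loses_half_accuracy(self):
        """A stump with training accuracy 1.0 on a perfectly separating
        feature drops to chance (~0.5) under permutation, so MDA ~ 0.5;
        oracle = explicit permutation loop."""
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(-3, 0.5, 200), rng.normal(3, 0.5, 200)])[:, None]
        y = np.repeat([0, 1], 200)
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        assert model.score(X, y) == 1.0
        iv = mda_importance(model, _dm(X, y=y), n_repeats=20, seed=3)
        # independent brute-force loop
        oracle_rng = np.random.default_rng(99)
        drops = []
        for _ in range(20):
            Xp = X[oracle_rng.permutation(len(X))]
            drops.append(1.0 - (model.predict(Xp) == y).mean())
        assert iv.scores["f0"] == pytest.approx(0.5, abs=0.1)
        assert iv.scores["f0"] == pytest.approx(np.mean(drops), abs=0.1)

    def test_one_hot_block_permuted_jointly(self):
        """All one-hot columns of a nominal feature move together: with a
        3-level one-hot carrying the signal, grouped MDA is large even
        though each single column alone is partially redundant."""
        rng = np.random.default_rng(4)
        levels = rng.integers(0, 3, 600)
        y = (levels == 2).astype(int)
        X = np.column_stack([(levels == v).astype(float) for v in range(3)])
        cols = [f"c={v}" for v in range(3)]
        dm = DesignMatrix(X, cols, {c: "c" for c in cols}, y)
        model = DecisionTreeClassifier(random_state=0).fit(X, y)
        iv = mda_importance(model, dm, n_repeats=10, seed=5)
        assert list(iv.scores.index) == ["c"]
        assert iv.scores["c"] > 0.2

    def test_matches_sklearn_permutation_importance_single_columns(self):
        """For single-column features, grouped MDA agrees with
        sklearn.inspection.permutation_importance (independent route)."""
        from sklearn.inspection import permutation_importance

        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 3))
        y = ((X[:, 0] + 0.3 * X[:, 1]) > 0).astype(int)
        model = LogisticRegression().fit(X, y)
        iv = mda_importance(model, _dm(X, y=y), n_repeats=30, seed=7)
        ref = permutation_importance(
            model, X, y, scoring="accuracy", n_repeats=30, random_state=7
        )
        np.testing.assert_allclose(
            iv.scores.to_numpy(), ref.importances_mean, atol=0.05
        )

    def test_repeats_validation(self):
        with pytest.raises(ConfigurationError):
            mda_importance(None, _dm(np.zeros((2, 1)), y=np.array([0, 1])), n_repeats=0)


class TestGini:
    def test_unused_feature_scores_zero_and_pure_split_scores_one(self):
        X = np.column_stack([np.repeat([0.0, 1.0], 10), np.zeros(20)])
        y = np.repeat([0, 1], 10)
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        iv = gini_importance(model, _dm(X))
        assert iv.scores["f1"] == 0.0
        assert iv.scores["f0"] == pytest.approx(1.0)

    def test_two_split_tree_matches_hand_computation(self):
        """12-row table, root split on A (decrease 1/9 of samples-weighted
        Gini), then a pure split on B inside A=1 (decrease 1/6): manual
        impurity arithmetic gives normalized importances 2/5 and 3/5."""
        A = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1], float)
        B = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 0, 1, 1], float)
        y = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1])
        model = DecisionTreeClassifier(max_depth=2, random_state=0).fit(
            np.column_stack([A, B]), y
        )
        iv = gini_importance(model, _dm(np.column_stack([A, B]), columns=["A", "B"]))
        assert iv.scores["A"] == pytest.approx(2 / 5, abs=1e-12)
        assert iv.scores["B"] == pytest.approx(3 / 5, abs=1e-12)

    def test_non_tree_model_rejected(self):
        model = LogisticRegression().fit(np.eye(4), [0, 1, 0, 1])
        with pytest.raises(UnsupportedMeasureError):
            gini_importance(model, _dm(np.eye(4)))


class TestCoef:
    def test_absolute_value_of_coefficients(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        model = LogisticRegression().fit(X, y)
        iv = coef_importance(model, _dm(X))
        np.testing.assert_allclose(
            iv.scores.to_numpy(), np.abs(model.coef_).ravel()
        )
        assert (iv.scores >= 0).all()

    def test_signal_feature_dominates(self):
        """Only feature 0 carries signal, so |coef0| > |coef1|; oracle =
        refit on fixed toy data."""
        rng = np.random.default_rng(9)
        X = np.column_stack([np.repeat([-1.0, 1.0], 100), rng.normal(size=200)])
        y = np.repeat([0, 1], 100)
        model = SVC(kernel="linear").fit(X, y)
        iv = coef_importance(model, _dm(X), classifier="SVM")
        assert iv.scores["f0"] > iv.scores["f1"]

    def test_nonlinear_kernel_rejected(self):
        model = SVC(kernel="rbf").fit(np.eye(4), [0, 1, 0, 1])
        with pytest.raises(UnsupportedMeasureError):
            coef_importance(model, _dm(np.eye(4)), classifier="SVM")


# ---------------------------------------------------------------------------
# meta feature table

class TestMFT:
    def _vec(self, cid, measure, d):
        return ImportanceVector(cid, measure, pd.Series(d))

    def test_columnwise_concatenation_preserves_values(self):
        v1 = self._vec("DT", "GI", {"a": 1.0, "b": 2.0, "c": 3.0})
        v2 = self._vec("LR", "MC", {"a": 4.0, "b": 5.0, "c": 6.0})
        mft = build_mft([v1, v2])
        assert mft.shape == (3, 2)
        assert mft.loc["b", "DT:GI"] == 2.0 and mft.loc["c", "LR:MC"] == 6.0

    def test_single_vector_identity(self):
        v = self._vec("RF", "MDA", {"a": 0.1, "b": 0.7})
        mft = build_mft([v])
        pd.testing.assert_series_equal(mft["RF:MDA"], v.scores, check_names=False)

    def test_rows_aligned_by_code_not_position(self):
        v1 = self._vec("DT", "GI", {"a": 1.0, "b": 2.0})
        v2 = ImportanceVector("LR", "MC", pd.Series({"b": 9.0, "a": 8.0}))
        mft = build_mft([v1, v2])
        assert mft.loc["a", "LR:MC"] == 8.0 and mft.loc["b", "LR:MC"] == 9.0

    def test_mismatched_feature_lists_named_in_error(self):
        v1 = self._vec("DT", "GI", {"a": 1.0, "b": 2.0})
        v2 = self._vec("LR", "MC", {"a": 1.0, "z": 2.0})
        with pytest.raises(ValueError, match="z"):
            build_mft([v1, v2])

    def test_normalization_examples(self):
        mft = pd.DataFrame({"u": [2.0, 4.0, 6.0], "v": [3.0, 3.0, 3.0]})
        out = normalize_mft(mft)
        assert out["u"].tolist() == [0.0, 0.5, 1.0]
        assert out["v"].tolist() == [0.0, 0.0, 0.0]

    def test_nonconstant_columns_hit_exact_bounds(self):
        rng = np.random.default_rng(10)
        mft = pd.DataFrame(rng.normal(size=(9, 4)), columns=list("wxyz"))
        out = normalize_mft(mft)
        for c in out.columns:
            assert out[c].min() == 0.0 and out[c].max() == 1.0

    def test_scale_robustness(self):
        """Multiplying a raw column by a positive constant leaves the
        normalized MFT (hence clustering and ranks) unchanged."""
        rng = np.random.default_rng(11)
        mft = pd.DataFrame(rng.random((8, 3)), columns=list("abc"))
        scaled = mft.copy()
        scaled["b"] = scaled["b"] * 137.5
        pd.testing.assert_frame_equal(normalize_mft(mft), normalize_mft(scaled))


# ---------------------------------------------------------------------------
# clustering + silhouette

class TestClustering:
    def test_k_equals_n_gives_zero_wcss(self):
        mft = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.0, 1.0, 2.0]})
        c = cluster_features(mft, k=3, seed=0)
        assert c.wcss == pytest.approx(0.0)
        assert c.assignment.nunique() == 3

    def test_two_high_scorers_form_top_cluster(self):
        """Two features scoring ~1 everywhere split from the ~0 rest at
        K=2 (the dominant-predictor cluster structure)."""
        rng = np.random.default_rng(12)
        rows = {f"n{i}": rng.normal(0.05, 0.02, 4) for i in range(8)}
        rows["ga"] = rng.normal(0.97, 0.02, 4)
        rows["fh"] = rng.normal(0.95, 0.02, 4)
        mft = pd.DataFrame(rows).T
        c = rank_clusters(cluster_features(mft, 2, seed=1))
        top = c.members(c.cluster_by_rank(1))
        assert sorted(top) == ["fh", "ga"]

    def test_six_planted_groups_recovered(self):
        """K=6 recovers six well-separated planted score groups up to
        label permutation; oracle = pairwise co-membership comparison."""
        rng = np.random.default_rng(13)
        truth = np.repeat(np.arange(6), 2)
        X = truth[:, None] * 2.0 + rng.normal(0, 0.05, (12, 3))
        mft = pd.DataFrame(X, index=[f"g{i}" for i in range(12)])
        c = cluster_features(mft, 6, seed=2)
        got = c.assignment.to_numpy()
        co_true = truth[:, None] == truth[None, :]
        co_got = got[:, None] == got[None, :]
        np.testing.assert_array_equal(co_true, co_got)

    def test_k_above_n_rejected(self):
        mft = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ConfigurationError):
            cluster_features(mft, 3)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(14)
        truth = np.repeat([0, 1, 2], 4)
        X = truth[:, None] * 3.0 + rng.normal(0, 0.05, (12, 2))
        mft = pd.DataFrame(X, index=[f"r{i}" for i in range(12)])
        shuffled = mft.sample(frac=1.0, random_state=5)

        def ranks_by_feature(m):
            c = rank_clusters(cluster_features(m, 3, seed=3))
            return {f: c.ranks[c.assignment[f]] for f in m.index}

        assert ranks_by_feature(mft) == ranks_by_feature(shuffled)


class TestSilhouette:
    def test_hand_worked_two_cluster_example(self):
        """Points {0, 0.1} vs {10, 10.1}: hand evaluation of a(i), b(i)
        gives mean silhouette 0.9900."""
        mft = pd.DataFrame({"x": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
        c = _clustering(mft.index, [0, 0, 1, 1], mft.to_numpy())
        assert mean_silhouette(mft, c) == pytest.approx(0.99, abs=1e-4)

    def test_identical_point_sets_not_positive(self):
        mft = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]}, index=list("abcd"))
        c = _clustering(mft.index, [0, 0, 1, 1], mft.to_numpy())
        assert mean_silhouette(mft, c) <= 0.0

    def test_k1_undefined(self):
        mft = pd.DataFrame({"x": [0.0, 1.0]})
        c = _clustering(mft.index, [0, 0], mft.to_numpy())
        with pytest.raises(ConfigurationError):
            mean_silhouette(mft, c)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_definition(self, seed):
        """Mean silhouette equals the brute-force definition to 1e-9 on
        random partitions of up to 12 features (singletons included)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(2, n))
        X = rng.normal(size=(n, 3))
        labels = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
        rng.shuffle(labels)
        mft = pd.DataFrame(X, index=[f"f{i}" for i in range(n)])
        c = _clustering(mft.index, labels, X)
        assert mean_silhouette(mft, c) == pytest.approx(
            brute_silhouette(X, labels), abs=1e-9
        )

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(10, 2))
        c = _clustering(range(10), rng.integers(0, 2, 10), X)
        mft = pd.DataFrame(X, index=range(10))
        assert -1.0 <= mean_silhouette(mft, c) <= 1.0


class TestSelectK:
    def test_three_planted_groups_among_top_candidates(self):
        rng = np.random.default_rng(16)
        truth = np.repeat([0, 1, 2], 5)
        X = truth[:, None] * 5.0 + rng.normal(0, 0.05, (15, 3))
        mft = pd.DataFrame(X, index=[f"f{i}" for i in range(15)])
        cands = select_k_candidates(mft, 2, 8, n_candidates=3, seed=4)
        assert 3 in [k for k, _ in cands]
        assert cands[0][0] == 3  # sharply separated: K=3 wins outright

    def test_descending_silhouette_order(self):
        rng = np.random.default_rng(17)
        mft = pd.DataFrame(rng.random((10, 3)))
        cands = select_k_candidates(mft, 2, 6, n_candidates=5, seed=5)
        sils = [s for _, s in cands]
        assert sils == sorted(sils, reverse=True)

    def test_empty_range_rejected(self):
        mft = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            select_k_candidates(mft, 4, 3)


class TestRankClusters:
    def test_centroid_mean_ordering(self):
        c = FeatureClustering(
            k=3,
            assignment=pd.Series([0, 1, 2], index=list("abc")),
            centroids=np.array([[0.9], [0.1], [0.5]]),
            seed=0,
            wcss=0.0,
        )
        ranked = rank_clusters(c)
        assert ranked.ranks == {0: 1, 1: 3, 2: 2}

    def test_singleton_clustering(self):
        c = FeatureClustering(
            k=1,
            assignment=pd.Series([0, 0], index=list("ab")),
            centroids=np.array([[0.5]]),
            seed=0,
            wcss=0.0,
        )
        assert rank_clusters(c).ranks == {0: 1}

    def test_tie_broken_by_size_then_id(self):
        c = FeatureClustering(
            k=2,
            assignment=pd.Series([0, 1, 1], index=list("abc")),
            centroids=np.array([[0.5], [0.5]]),
            seed=0,
            wcss=0.0,
        )
        assert rank_clusters(c).ranks == {1: 1, 0: 2}  # larger cluster first


class TestFeatureSets:
    def _ranked(self, members_by_cluster):
        index, labels = [], []
        for cid, members in enumerate(members_by_cluster):
            index.extend(members)
            labels.extend([cid] * len(members))
        X = np.array(labels, float)[:, None] * -1.0  # cluster 0 highest score
        return rank_clusters(_clustering(index, np.array(labels), X))

    def test_union_across_tasks(self):
        t1 = self._ranked([["ga", "fh"], ["x1", "x2"]])
        t2 = self._ranked([["ga", "ma"], ["x1", "x3"]])
        fs = build_feature_set([(t1, [1]), (t2, [1])], name="FSC22")
        assert sorted(fs.members) == ["fh", "ga", "ma"]

    def test_keep_all_equals_full_set(self):
        t1 = self._ranked([["a", "b"], ["c"]])
        fs = build_feature_set([(t1, [1, 2])], name="all")
        assert sorted(fs.members) == ["a", "b", "c"]
        assert set(fs.members) == set(full_feature_set(["a", "b", "c"]).members)

    def test_single_task_singleton_cluster(self):
        t1 = self._ranked([["only"], ["x", "y"]])
        fs = build_feature_set([(t1, [1])], name="s")
        assert fs.members == ("only",)

    def test_missing_rank_rejected(self):
        t1 = self._ranked([["a"], ["b"]])
        with pytest.raises(ConfigurationError):
            build_feature_set([(t1, [5])], name="bad")
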