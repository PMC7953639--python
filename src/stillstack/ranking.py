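"""Consensus feature ranking.

Per-classifier importance scores (mean decrease accuracy, Gini impurity
decrease, absolute linear-model coefficients) are concatenated column-wise
into a meta feature table (MFT: features x (classifier, measure) scores),
min-max normalized per column, clustered with K-means over a silhouette
sweep of K, and the clusters ranked by their centroid scores; feature sets
are unions of the top-ranked clusters across the two classification tasks.

A fourth measure ("CN") is mentioned once in the source methodology but
never defined; it is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import accuracy_score, silhouette_samples

from .preprocess import DesignMatrix
from .schema import ConfigurationError

__all__ = [
    "ImportanceVector",
    "FeatureClustering",
    "FeatureSet",
    "mda_importance",
    "gini_importance",
    "coef_importance",
    "build_mft",
    "normalize_mft",
    "cluster_features",
    "mean_silhouette",
    "select_k_candidates",
    "rank_clusters",
    "build_feature_set",
    "full_feature_set",
]

CLASSIFIER_IDS = ("DT", "GBC", "LR", "RF", "SVM")
MEASURES = ("MDA", "GI", "MC")


class UnsupportedMeasureError(TypeError):
    """The importance measure is not defined for this model family."""


@dataclass(frozen=True)
class ImportanceVector:
    """One column of the meta feature table: per-feature scores produced by
    one (classifier, measure) pair."""

    classifier: str
    measure: str
    scores: pd.Series  # index: source feature codes

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_IDS:
            raise ConfigurationError(f"unknown classifier id {self.classifier!r}")
        if self.measure not in MEASURES:
            raise ConfigurationError(f"unknown measure {self.measure!r}")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("importance scores must be finite")

    @property
    def label(self) -> str:
        return f"{self.classifier}:{self.measure}"


def mda_importance(
    model,
    matrix: DesignMatrix,
    n_repeats: int = 10,
    seed: int = 0,
    classifier: str = "DT",
) -> ImportanceVector:
    """Mean decrease accuracy by grouped column permutation.

    For each source feature, all of its encoded columns (e.g. the one-hot
    block of a nominal feature) are permuted *jointly* with the same row
    permutation, and the drop from baseline accuracy is averaged over
    ``n_repeats`` seeded permutations.  ``matrix`` should hold rows held
    out from the model fit.  Scores may be negative.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    if matrix.y is None:
        raise ValueError("mda_importance needs labels")
    rng = np.random.default_rng(seed)
    baseline = accuracy_score(matrix.y, model.predict(matrix.X))
    scores = {}
    for code in matrix.features:
        cols = matrix.feature_columns(code)
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(matrix.X))
            Xp = matrix.X.copy()
            Xp[:, cols] = Xp[perm][:, cols]
            drops.append(baseline - accuracy_score(matrix.y, model.predict(Xp)))
        scores[code] = float(np.mean(drops))
    return ImportanceVector(classifier, "MDA", pd.Series(scores))


def gini_importance(model, matrix: DesignMatrix, classifier: str = "DT") -> ImportanceVector:
    """Total impurity decrease per source feature, aggregated over trees
    and over one-hot columns, normalized to sum to 1."""
    if not hasattr(model, "feature_importances_"):
        raise UnsupportedMeasureError(
            "Gini importance requires a fitted tree-based model"
        )
    imp = np.asarray(model.feature_importances_, dtype=float)
    scores = {}
    for code in matrix.features:
        scores[code] = float(imp[matrix.feature_columns(code)].sum())
    s = pd.Series(scores)
    total = s.sum()
    if total > 0:
        s = s / total
    return ImportanceVector(classifier, "GI", s)


def coef_importance(model, matrix: DesignMatrix, classifier: str = "LR") -> ImportanceVector:
    """Absolute hyperplane coefficients of a linear model; one-hot columns
    aggregate to their source feature by maximum absolute value.  Inputs
    are assumed normalized so magnitudes are comparable."""
    kernel = getattr(model, "kernel", None)
    if kernel is not None and kernel != "linear":
        raise UnsupportedMeasureError("model coefficients need a linear kernel")
    if not hasattr(model, "coef_"):
        raise UnsupportedMeasureError("model has no linear coefficients")
    coef = np.abs(np.asarray(model.coef_)).ravel()
    scores = {
        code: float(coef[matrix.feature_columns(code)].max())
        for code in matrix.features
    }
    return ImportanceVector(classifier, "MC", pd.Series(scores))


def build_mft(vectors: Sequence[ImportanceVector]) -> pd.DataFrame:
    """Concatenate importance vectors column-wise into the meta feature
    table.  Rows are aligned by feature code (not position); vectors must
    cover identical feature lists."""
    if not vectors:
        raise ConfigurationError("at least one importance vector required")
    index = list(vectors[0].scores.index)
    ref = set(index)
    for v in vectors[1:]:
        got = set(v.scores.index)
        if got != ref:
            missing = sorted(ref - got)
            extra = sorted(got - ref)
            raise ValueError(
                f"{v.label}: feature list mismatch (missing={missing}, extra={extra})"
            )
    return pd.DataFrame({v.label: v.scores.reindex(index) for v in vectors}, index=index)


def normalize_mft(mft: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each MFT column to [0, 1]; constant columns map
    to all zeros so no column dominates another."""
    out = {}
    for col in mft.columns:
        x = mft[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        out[col] = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=mft.index)


@dataclass(frozen=True)
class FeatureClustering:
    """K-means partition of MFT rows with optional silhouette and ranks."""

    k: int
    assignment: pd.Series  # feature code -> cluster id (0..k-1)
    centroids: np.ndarray  # k x n_columns
    seed: int
    wcss: float
    mean_silhouette: float | None = None
    ranks: dict[int, int] | None = None  # cluster id -> rank (1 = best)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])

    def cluster_by_rank(self, rank: int) -> int:
        if self.ranks is None:
            raise ValueError("clusters not ranked yet")
        for cid, r in self.ranks.items():
            if r == rank:
                return cid
        raise KeyError(f"no cluster with rank {rank}")


def cluster_features(
    mft: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> FeatureClustering:
    """Cluster MFT rows with Lloyd's K-means (Euclidean distance, random
    data-point initialization, ``n_restarts`` seeded restarts keeping the
    lowest within-cluster sum of squares)."""
    n = len(mft)
    if not 1 <= k <= n:
        raise ConfigurationError(f"K={k} outside [1, {n}]")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(mft.to_numpy(dtype=float))
    assignment = pd.Series(km.labels_.astype(int), index=mft.index)
    return FeatureClustering(
        k=k,
        assignment=assignment,
        centroids=km.cluster_centers_,
        seed=seed,
        wcss=float(km.inertia_),
    )


def mean_silhouette(mft: pd.DataFrame, clustering: FeatureClustering) -> float:
    """Mean silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)) over features
    (Euclidean); singleton clusters contribute 0.  Undefined for K = 1."""
    if clustering.k < 2:
        raise ConfigurationError("silhouette is undefined for K = 1")
    labels = clustering.assignment.reindex(mft.index).to_numpy()
    counts = np.bincount(labels, minlength=clustering.k)
    if (counts == 0).any():
        raise ConfigurationError("every cluster must be non-empty")
    if clustering.k == len(mft):
        return 0.0  # all singletons: each contributes 0 by convention
    s = silhouette_samples(mft.to_numpy(dtype=float), labels, metric="euclidean")
    return float(s.mean())


def select_k_candidates(
    mft: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    n_candidates: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[tuple[int, float]]:
    """Sweep K over ``[k_min, k_max]``, computing the mean silhouette of
    each K-means clustering, and return the ``n_candidates`` values of K
    with the highest silhouette, descending (ties favour smaller K)."""
    n = len(mft)
    if k_min < 2 or k_max > n or k_min > k_max:
        raise ConfigurationError(f"invalid K range [{k_min}, {k_max}] for {n} features")
    results = []
    for k in range(k_min, k_max + 1):
        clustering = cluster_features(mft, k, seed=seed, n_restarts=n_restarts)
        results.append((k, mean_silhouette(mft, clustering)))
    results.sort(key=lambda kv: (-kv[1], kv[0]))
    return results[:n_candidates]


def rank_clusters(clustering: FeatureClustering) -> FeatureClustering:
    """Rank clusters by descending mean of their centroid coordinates
    (rank 1 = best); ties broken by cluster size (larger first), then by
    cluster id."""
    scores = clustering.centroids.mean(axis=1)
    sizes = np.bincount(clustering.assignment.to_numpy(), minlength=clustering.k)
    order = sorted(
        range(clustering.k), key=lambda c: (-scores[c], -sizes[c], c)
    )
    ranks = {cid: r + 1 for r, cid in enumerate(order)}
    return replace(clustering, ranks=ranks)


@dataclass(frozen=True)
class FeatureSet:
    """Named union of features from kept clusters across tasks."""

    name: str
    members: tuple[str, ...]
    provenance: tuple[str, ...] = ()

    def __contains__(self, code: str) -> bool:
        return code in self.members


def build_feature_set(
    selections: Sequence[tuple[FeatureClustering, Sequence[int]]],
    name: str,
) -> FeatureSet:
    """Union of the member features of the kept clusters (identified by
    rank) across the per-task clusterings."""
    members: set[str] = set()
    provenance: list[str] = []
    for i, (clustering, keep_ranks) in enumerate(selections):
        if clustering.ranks is None:
            raise ValueError("rank clusters before building feature sets")
        for rank in keep_ranks:
            if rank not in clustering.ranks.values():
                raise ConfigurationError(
                    f"selection {i}: no cluster holds rank {rank} (K={clustering.k})"
                )
            cid = clustering.cluster_by_rank(rank)
            members.update(clustering.members(cid))
            provenance.append(f"task{i + 1}:K={clustering.k}:rank{rank}")
    return FeatureSet(name, tuple(sorted(members)), tuple(provenance))


def full_feature_set(codes: Sequence[str], name: str = "FFS") -> FeatureSet:
    """The full feature set: all surviving features."""
    return FeatureSet(name, tuple(codes), ("all",))
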