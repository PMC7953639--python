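"""Two-layer stacked ensemble with vote-boosting aggregation.

Architecture ("normal stacking mode"): five base classifiers — decision
tree (DT), gradient boosting (GBC), logistic regression (LR), random
forest (RF) and linear-kernel SVM — are trained independently on the
design matrix.  Their predicted class labels form the first meta feature
set (instances x 5), which feeds an identical second layer; the second
layer's label outputs form the second meta feature set, which a
vote-boosting aggregator combines into the final decision.  Raw features
never reach layer 2 or the aggregator.

Vote-boosting weights training instances by the degree of agreement among
the last layer's votes, via a symmetric-Beta emphasis function (uniform at
its default hyperparameter), then fits boosted decision stumps over the
five meta-columns.  Stumps are restricted to direct column predictors with
non-negative round weights, which guarantees the unanimity invariant: if
all five votes agree on an instance, the aggregate equals that vote.

By default the meta features used to *train* each next stage are produced
out-of-fold (cross-validated predictions), which avoids stacking leakage;
the literal direct mode (training-set predictions) is available via
``SEConfig(stacking="direct")``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .schema import ConfigurationError

__all__ = [
    "CLASSIFIER_IDS",
    "SEConfig",
    "BaseClassifierBank",
    "VoteBoostAggregator",
    "TrainedStackedEnsemble",
    "make_classifier",
    "default_hyperparams",
    "fit_layer",
    "layer_outputs",
    "fit_vote_boost",
    "fit_se",
    "predict_se",
    "grid_search_tune",
]

CLASSIFIER_IDS = ("DT", "GBC", "LR", "RF", "SVM")


def default_hyperparams() -> dict[str, dict]:
    return {
        "DT": {"max_depth": 8},
        "GBC": {"n_estimators": 60, "max_depth": 3, "learning_rate": 0.1},
        "LR": {"C": 1.0, "max_iter": 2000},
        "RF": {"n_estimators": 100, "max_depth": None},
        "SVM": {"C": 1.0, "kernel": "linear"},
    }


def default_grids() -> dict[str, list[dict]]:
    """Small per-classifier hyperparameter grids for 9:1 grid search."""
    return {
        "DT": [{"max_depth": d} for d in (4, 8, None)],
        "GBC": [{"n_estimators": n, "max_depth": 3} for n in (30, 60, 120)],
        "LR": [{"C": c, "max_iter": 2000} for c in (0.1, 1.0, 10.0)],
        "RF": [{"n_estimators": n} for n in (50, 100, 200)],
        "SVM": [{"C": c, "kernel": "linear"} for c in (0.1, 1.0, 10.0)],
    }


def make_classifier(cid: str, params: dict | None = None, seed: int = 0):
    params = dict(params or default_hyperparams()[cid])
    if cid == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if cid == "GBC":
        return GradientBoostingClassifier(random_state=seed, **params)
    if cid == "LR":
        return LogisticRegression(**params)
    if cid == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if cid == "SVM":
        return SVC(random_state=seed, **params)
    raise ConfigurationError(f"unknown classifier id {cid!r}")


@dataclass
class SEConfig:
    """Stacked-ensemble configuration.

    stacking: "oof" (out-of-fold meta features, default) or "direct"
    (paper-literal training-set predictions).  ``use_proba`` switches the
    meta features from hard labels (default, as specified) to soft scores.
    """

    hyperparams: dict[str, dict] = field(default_factory=default_hyperparams)
    stacking: str = "oof"
    cv_folds: int = 5
    n_rounds: int = 10
    emphasis_alpha: float = 1.0
    use_proba: bool = False

    def __post_init__(self) -> None:
        if self.stacking not in ("oof", "direct"):
            raise ConfigurationError("stacking must be 'oof' or 'direct'")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")


@dataclass
class BaseClassifierBank:
    """Five fitted base classifiers, one per id, fitted on the same rows."""

    models: dict[str, object]
    n_features: int
    seed: int

    def __post_init__(self) -> None:
        if tuple(self.models) != CLASSIFIER_IDS:
            raise ConfigurationError("bank must hold exactly DT, GBC, LR, RF, SVM")


def _spawn(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint32)]


def fit_layer(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict[str, dict] | None = None,
    seed: int = 0,
) -> BaseClassifierBank:
    """Fit the five base classifiers independently on identical rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit a layer")
    hyperparams = hyperparams or default_hyperparams()
    seeds = _spawn(seed, len(CLASSIFIER_IDS))
    models = {}
    for cid, s in zip(CLASSIFIER_IDS, seeds):
        models[cid] = make_classifier(cid, hyperparams.get(cid), seed=s).fit(X, y)
    return BaseClassifierBank(models, X.shape[1], seed)


def _soft_output(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    z = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-z))


def layer_outputs(
    bank: BaseClassifierBank, X: np.ndarray, use_proba: bool = False
) -> np.ndarray:
    """Predictions of the bank, column-wise in (DT, GBC, LR, RF, SVM)
    order: the meta feature set fed to the next stage."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != bank.n_features:
        raise ValueError(
            f"expected {bank.n_features} feature columns, got {X.shape[1] if X.ndim == 2 else 'non-matrix'}"
        )
    if len(X) == 0:
        return np.empty((0, len(CLASSIFIER_IDS)))
    cols = []
    for cid in CLASSIFIER_IDS:
        model = bank.models[cid]
        if use_proba:
            cols.append(_soft_output(model, X))
        else:
            cols.append(model.predict(X).astype(float))
    return np.column_stack(cols)


def _oof_outputs(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: dict[str, dict],
    seed: int,
    cv_folds: int,
    use_proba: bool,
) -> np.ndarray:
    """Out-of-fold meta features: each instance's meta row comes from
    models that never saw it during training."""
    seeds = _spawn(seed, len(CLASSIFIER_IDS) + 1)
    n_splits = min(cv_folds, int(np.bincount(pd_factorize(y)).min()))
    if n_splits < 2:
        raise ValueError("too few per-class rows for out-of-fold stacking")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seeds[-1])
    cols = []
    for cid, s in zip(CLASSIFIER_IDS, seeds):
        est = make_classifier(cid, hyperparams.get(cid), seed=s)
        method = "predict"
        if use_proba:
            method = "predict_proba" if hasattr(est, "predict_proba") else "decision_function"
        pred = cross_val_predict(est, X, y, cv=cv, method=method)
        if use_proba:
            if pred.ndim == 2:
                pred = pred[:, 1]
            else:
                pred = 1.0 / (1.0 + np.exp(-pred))
        cols.append(np.asarray(pred, dtype=float))
    return np.column_stack(cols)


def pd_factorize(y: np.ndarray) -> np.ndarray:
    _, inv = np.unique(y, return_inverse=True)
    return inv


class VoteBoostAggregator:
    """Agreement-weighted boosted-stump combiner over the 5 meta-columns.

    Per-instance agreement a_i = (plurality vote count) / 5; initial
    training weights are proportional to a symmetric Beta(alpha, alpha)
    emphasis evaluated at a_i (alpha = 1 gives uniform weights, reducing
    the aggregator to a weighted majority vote over the columns picked by
    boosting).  Each boosting round selects the meta-column whose direct
    vote minimizes weighted error; rounds with error >= 0.5 are rejected,
    so all round weights are non-negative and unanimity is preserved.
    """

    def __init__(self, n_rounds: int = 10, emphasis_alpha: float = 1.0):
        if n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")
        if emphasis_alpha <= 0:
            raise ConfigurationError("emphasis_alpha must be positive")
        self.n_rounds = n_rounds
        self.emphasis_alpha = emphasis_alpha
        self.stumps_: list[tuple[int, float]] = []
        self.initial_weights_: np.ndarray | None = None

    @staticmethod
    def agreement(meta: np.ndarray) -> np.ndarray:
        votes = (np.asarray(meta) >= 0.5).astype(int)
        pos = votes.sum(axis=1)
        k = votes.shape[1]
        return np.maximum(pos, k - pos) / k

    def _emphasis(self, a: np.ndarray) -> np.ndarray:
        a = np.clip(a, 0.01, 0.99)
        e = self.emphasis_alpha
        return a ** (e - 1.0) * (1.0 - a) ** (e - 1.0)

    def fit(self, meta: np.ndarray, y: np.ndarray) -> "VoteBoostAggregator":
        meta = (np.asarray(meta, dtype=float) >= 0.5).astype(float)
        y = np.asarray(y, dtype=float)
        if meta.ndim != 2:
            raise ValueError("meta feature set must be 2-D")
        w = self._emphasis(self.agreement(meta))
        w = w / w.sum()
        self.initial_weights_ = w.copy()
        self.stumps_ = []
        eps = 1e-12
        for _ in range(self.n_rounds):
            errors = np.array([(w * (meta[:, j] != y)).sum() for j in range(meta.shape[1])])
            j = int(errors.argmin())
            e = float(errors[j])
            if e >= 0.5 - 1e-9:
                break  # no column beats chance under current weights
            e = max(e, eps)
            alpha = 0.5 * np.log((1.0 - e) / e)
            self.stumps_.append((j, float(alpha)))
            if e <= eps:
                break  # perfect stump; further rounds are redundant
            miss = meta[:, j] != y
            w = w * np.exp(np.where(miss, alpha, -alpha))
            w = w / w.sum()
        if not self.stumps_:
            # degenerate: fall back to an unweighted majority vote
            self.stumps_ = [(j, 1.0) for j in range(meta.shape[1])]
        return self

    def predict_score(self, meta: np.ndarray) -> np.ndarray:
        """Weighted-vote margin mapped to [0, 1]."""
        if not self.stumps_:
            raise RuntimeError("aggregator not fitted")
        meta = (np.asarray(meta, dtype=float) >= 0.5).astype(float)
        total = sum(a for _, a in self.stumps_)
        score = np.zeros(len(meta))
        for j, a in self.stumps_:
            score += a * meta[:, j]
        return score / total

    def predict(self, meta: np.ndarray) -> np.ndarray:
        # ties (score exactly 0.5) resolve to the positive class
        return (self.predict_score(meta) >= 0.5).astype(int)


def fit_vote_boost(
    meta2: np.ndarray,
    y: np.ndarray,
    n_rounds: int = 10,
    seed: int = 0,
    emphasis_alpha: float = 1.0,
) -> VoteBoostAggregator:
    if len(meta2) != len(y):
        raise ValueError("meta features and labels must be aligned")
    return VoteBoostAggregator(n_rounds, emphasis_alpha).fit(meta2, y)


@dataclass
class TrainedStackedEnsemble:
    """Fitted two-layer stack: layer1 -> meta1 -> layer2 -> meta2 ->
    vote-boost aggregator."""

    layer1: BaseClassifierBank
    layer2: BaseClassifierBank
    aggregator: VoteBoostAggregator
    config: SEConfig
    seed: int

    def serialize(self) -> bytes:
        return pickle.dumps(self)


def fit_se(
    X: np.ndarray, y: np.ndarray, config: SEConfig | None = None, seed: int = 0
) -> TrainedStackedEnsemble:
    """Fit the full stacked ensemble; all stage seeds derive from ``seed``."""
    config = config or SEConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    s1, s2, s3 = _spawn(seed, 3)
    layer1 = fit_layer(X, y, config.hyperparams, seed=s1)
    if config.stacking == "oof":
        meta1 = _oof_outputs(X, y, config.hyperparams, s1, config.cv_folds, config.use_proba)
    else:
        meta1 = layer_outputs(layer1, X, config.use_proba)
    layer2 = fit_layer(meta1, y, config.hyperparams, seed=s2)
    if config.stacking == "oof":
        meta2 = _oof_outputs(meta1, y, config.hyperparams, s2, config.cv_folds, config.use_proba)
    else:
        meta2 = layer_outputs(layer2, meta1, config.use_proba)
    aggregator = VoteBoostAggregator(config.n_rounds, config.emphasis_alpha).fit(meta2, y)
    return TrainedStackedEnsemble(layer1, layer2, aggregator, config, seed)


def predict_se(
    model: TrainedStackedEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels plus continuous scores in [0, 1] (aggregator margin)."""
    meta1 = layer_outputs(model.layer1, X, model.config.use_proba)
    meta2 = layer_outputs(model.layer2, meta1, model.config.use_proba)
    if len(X) == 0:
        return np.empty(0, dtype=int), np.empty(0)
    scores = model.aggregator.predict_score(meta2)
    return (scores >= 0.5).astype(int), scores


def grid_search_tune(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[dict],
    make_model,
    seed: int = 0,
) -> tuple[dict, float]:
    """Grid search on a stratified 9:1 train/validation split.

    Each grid point is fitted on the 90% split and scored by accuracy on
    the 10% split; ties keep the first grid point in declared order.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=0.1, stratify=y, random_state=seed
    )
    best_params, best_score = None, -np.inf
    for params in grid:
        model = make_model(params)
        if hasattr(model, "fit"):
            model.fit(X_tr, y_tr)
            score = accuracy_score(y_val, model.predict(X_val))
        else:
            raise TypeError("make_model must return an estimator with fit/predict")
        if score > best_score:
            best_params, best_score = params, score
    return best_params, float(best_score)
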