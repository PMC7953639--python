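"""Evaluation battery: confusion metrics, ROC/PR curves with AUC,
stratified k-fold cross-validation of the full two-step pipeline, isotonic
probability calibration, and a permutation-null significance test for AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .hierarchy import (
    LABEL_LIVEBIRTH,
    TwoStepConfig,
    fit_two_step,
    predict_two_step,
)
from .schema import (
    BEFORE,
    DURING,
    OUTCOME1,
    OUTCOME2,
    STILLBIRTH,
    ConfigurationError,
)

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "confusion_from_labels",
    "roc_pr_auc",
    "kfold_cv",
    "CalibrationResult",
    "isotonic_calibrate",
    "SignificanceResult",
    "permutation_p_value",
    "permutation_significance",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f_score", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall (sensitivity), specificity and F-score
    from a confusion table; zero-denominator ratios report 0 with a
    warning."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    return {
        "accuracy": (tp + tn) / counts.total,
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "f_score": _ratio(2 * precision * recall, precision + recall, "f_score"),
    }


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def roc_pr_auc(scores, labels) -> dict:
    """ROC and precision-recall curves by threshold sweep over the unique
    scores, with trapezoidal AUC.

    The PR curve is left as the raw zigzag (no interpolation smoothing).
    AUC equals the normalized Mann-Whitney concordance exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores, drop_intermediate=False)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    return {
        "roc_points": np.column_stack([fpr, tpr]),
        "roc_thresholds": roc_thr,
        "pr_points": np.column_stack([recall, precision]),
        "pr_thresholds": pr_thr,
        "auc": float(_trapezoid_auc(fpr, tpr)),
    }


def _binary_report(y_true, y_pred, scores) -> dict[str, float]:
    rep = confusion_metrics(confusion_from_labels(y_true, y_pred))
    rep["auc"] = roc_pr_auc(scores, y_true)["auc"] if len(np.unique(y_true)) > 1 else float("nan")
    return rep


def _stratify_labels(table: pd.DataFrame) -> np.ndarray:
    """4-way stratification label so every fold carries livebirths,
    before/during stillbirths and unknown-time rows."""
    lab = np.where(
        table[OUTCOME1].to_numpy() == STILLBIRTH,
        table[OUTCOME2].astype(str).to_numpy(),
        "livebirth",
    )
    return lab


def kfold_cv(
    table: pd.DataFrame,
    schema,
    config: TwoStepConfig | None = None,
    k: int = 5,
    seed: int = 0,
    step2_on_routed: bool = False,
) -> dict:
    """Stratified k-fold cross-validation of the full two-step pipeline.

    The whole pipeline (imputation, encoding, balancing, both ensembles)
    is refitted on each fold's training rows.  Per fold, step-1 metrics
    are computed over all test rows (stillbirth positive) and step-2
    metrics over the known-time stillbirth test rows — scored directly by
    the step-2 model by default (``step2_on_routed=True`` restricts to
    rows step 1 actually routed).  The two steps' metrics are averaged
    into the reported ``average`` block, and folds are averaged in
    ``mean``.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    config = config or TwoStepConfig()
    strat = _stratify_labels(table)
    counts = pd.Series(strat).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"stratification infeasible: class {counts.idxmin()!r} has "
            f"{counts.min()} rows < k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    fold_indices = []
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(table)), strat)):
        fold_indices.append(te)
        train, test = table.iloc[tr], table.iloc[te]
        model = fit_two_step(train, schema, config, seed=seed + f)
        pred = predict_two_step(model, test)

        y1 = (test[OUTCOME1] == STILLBIRTH).to_numpy().astype(int)
        p1 = (pred["label"] != LABEL_LIVEBIRTH).to_numpy().astype(int)
        step1 = _binary_report(y1, p1, pred["step1_score"].to_numpy())

        known = test[OUTCOME2].isin([BEFORE, DURING]).to_numpy()
        if step2_on_routed:
            known = known & p1.astype(bool)
        y2 = (test.loc[known, OUTCOME2] == DURING).to_numpy().astype(int)
        s2 = model.step2.score(test.loc[known])
        step2 = _binary_report(y2, (s2 >= 0.5).astype(int), s2)

        avg = {m: (step1[m] + step2[m]) / 2 for m in METRIC_NAMES}
        folds.append({"step1": step1, "step2": step2, "average": avg})

    mean = {
        block: {
            m: float(np.nanmean([f[block][m] for f in folds])) for m in METRIC_NAMES
        }
        for block in ("step1", "step2", "average")
    }
    return {"folds": folds, "mean": mean, "fold_indices": fold_indices}


@dataclass
class CalibrationResult:
    """Monotone score -> probability map with its Brier score."""

    model: IsotonicRegression
    brier: float

    def predict(self, scores) -> np.ndarray:
        return self.model.predict(np.asarray(scores, dtype=float))


def isotonic_calibrate(scores, labels) -> CalibrationResult:
    """Isotonic (pool-adjacent-violators) calibration of scores against
    binary labels; the calibration score is the Brier score (mean squared
    error) of the calibrated probabilities."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for calibration")
    if len(np.unique(scores)) == 1:
        warnings.warn(
            "all scores identical: calibration collapses to the prevalence",
            stacklevel=2,
        )
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, labels)
    prob = iso.predict(scores)
    return CalibrationResult(iso, float(np.mean((prob - labels) ** 2)))


def permutation_p_value(observed: float, null: Sequence[float]) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= observed}) / (1 + N)``.
    Never zero; monotone non-increasing in the observed statistic."""
    null = np.asarray(null, dtype=float)
    if len(null) < 1:
        raise ConfigurationError("need at least one null draw")
    return float((1 + int((null >= observed).sum())) / (1 + len(null)))


@dataclass(frozen=True)
class SignificanceResult:
    observed_auc: float
    null_aucs: tuple[float, ...]
    p_value: float


def permutation_significance(
    fit_score: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_repeats: int = 200,
    seed: int = 0,
) -> SignificanceResult:
    """Permutation-null significance of held-out AUC.

    ``fit_score(X_train, y_train, X_test) -> scores`` fits a model and
    scores the test rows.  The null distribution refits on randomly
    permuted training labels (breaking the feature-outcome link) and
    records held-out AUC against the true test labels.  The add-one
    estimator ``p = (1 + #{null >= observed}) / (1 + n_repeats)`` is never
    zero and decreases as the observed AUC grows for a fixed null sample.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    observed = roc_pr_auc(fit_score(X_train, y_train, X_test), y_test)["auc"]
    null = []
    for _ in range(n_repeats):
        y_perm = y_train[rng.permutation(len(y_train))]
        if len(np.unique(y_perm)) < 2:  # pragma: no cover - requires tiny n
            null.append(0.5)
            continue
        null.append(roc_pr_auc(fit_score(X_train, y_perm, X_test), y_test)["auc"])
    p = permutation_p_value(observed, null)
    return SignificanceResult(float(observed), tuple(float(v) for v in null), p)
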