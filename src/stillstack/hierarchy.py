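"""Two-step hierarchical classifier.

Step 1 separates livebirth from stillbirth (stillbirth = positive class);
step 2 separates stillbirth before delivery from stillbirth during
delivery (during = positive class), trained only on stillbirth rows whose
timing is known.  Unknown-time stillbirths are excluded from step-2
*training* (and logged), but still receive a step-2 prediction at
inference whenever step 1 flags them — unknown is missing ground truth,
not a predictable label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import SEConfig, TrainedStackedEnsemble, fit_se, predict_se, _spawn
from .preprocess import (
    DesignMatrix,
    DesignTransform,
    Imputer,
    balance_sample,
    remove_high_missing,
)
from .schema import (
    BEFORE,
    DURING,
    LIVEBIRTH,
    OUTCOME1,
    OUTCOME2,
    STILLBIRTH,
    UNKNOWN,
    FeatureSpec,
)

__all__ = ["TwoStepConfig", "StepBundle", "TwoStepModel", "fit_two_step", "predict_two_step"]

LABEL_LIVEBIRTH = "livebirth"
LABEL_BEFORE = "stillbirth_before"
LABEL_DURING = "stillbirth_during"


@dataclass
class TwoStepConfig:
    """End-to-end configuration of the two-step pipeline.

    ``step1_features`` / ``step2_features``: optional feature-code subsets
    (e.g. the unions built from cluster rankings); ``None`` means all
    surviving features — per-step sets may differ, default is the same
    set for both steps.  ``balance_ratio`` triggers training-split
    majority undersampling when set.
    """

    se: SEConfig = field(default_factory=SEConfig)
    step1_features: Sequence[str] | None = None
    step2_features: Sequence[str] | None = None
    missing_threshold: float = 0.05
    balance_ratio: float | None = 1.0
    normalization: str = "minmax"


@dataclass
class StepBundle:
    """One step's fitted preprocessing + ensemble."""

    imputer: Imputer
    transform: DesignTransform
    ensemble: TrainedStackedEnsemble
    feature_codes: tuple[str, ...]
    positive_label: str

    def design(self, table: pd.DataFrame) -> DesignMatrix:
        filled, _ = self.imputer.transform(table)
        return self.transform.transform(filled)

    def score(self, table: pd.DataFrame) -> np.ndarray:
        _, scores = predict_se(self.ensemble, self.design(table).X)
        return scores


@dataclass
class TwoStepModel:
    step1: StepBundle
    step2: StepBundle
    n_excluded_unknown: int
    removed_features: tuple[str, ...]
    seed: int


def _select_schema(
    schema: Sequence[FeatureSpec],
    codes: Sequence[str] | None,
    known_codes: set[str],
) -> tuple[FeatureSpec, ...]:
    """Subset ``schema`` (post-missingness-removal) to ``codes``.

    Codes that existed in the input schema but were dropped by the
    missingness rule are skipped with a warning; codes never seen at all
    are an error.
    """
    if codes is None:
        return tuple(schema)
    codes = set(codes)
    unknown = codes - known_codes
    if unknown:
        raise ValueError(f"feature set references unknown features: {sorted(unknown)}")
    picked = tuple(f for f in schema if f.code in codes)
    dropped = codes - {f.code for f in picked}
    if dropped:
        warnings.warn(
            f"feature set members removed by the missingness rule: {sorted(dropped)}",
            stacklevel=3,
        )
    if not picked:
        raise ValueError("feature set empty after missingness removal")
    return picked


def _fit_step(
    table: pd.DataFrame,
    schema: Sequence[FeatureSpec],
    y: np.ndarray,
    config: TwoStepConfig,
    positive_label: str,
    seed: int,
) -> StepBundle:
    imputer = Imputer(schema).fit(table)
    filled, _ = imputer.transform(table)
    transform = DesignTransform(schema, normalization=config.normalization).fit(filled)
    dm = transform.transform(filled, y=y)
    if config.balance_ratio is not None:
        dm = balance_sample(dm, config.balance_ratio, seed=seed)
    ensemble = fit_se(dm.X, dm.y, config.se, seed=seed)
    return StepBundle(imputer, transform, ensemble, tuple(f.code for f in schema), positive_label)


def fit_two_step(
    table: pd.DataFrame,
    schema: Sequence[FeatureSpec],
    config: TwoStepConfig | None = None,
    seed: int = 0,
) -> TwoStepModel:
    """Fit the two-step model on a registry table.

    Step 1 trains on all rows (label: outcome1); step 2 trains only on
    stillbirth rows with outcome2 in {before, during}; unknown-time rows
    are counted and excluded from step-2 training.
    """
    config = config or TwoStepConfig()
    if OUTCOME1 not in table.columns or OUTCOME2 not in table.columns:
        raise ValueError("table must carry outcome1 and outcome2 columns")
    table, surviving, removed = remove_high_missing(table, schema, config.missing_threshold)

    still = table[OUTCOME1] == STILLBIRTH
    if not still.any():
        raise ValueError("no stillbirth rows; step 2 is degenerate")
    known = still & table[OUTCOME2].isin([BEFORE, DURING])
    n_unknown = int((still & (table[OUTCOME2] == UNKNOWN)).sum())
    step2_rows = table.loc[known]
    if (step2_rows[OUTCOME2] == DURING).sum() == 0 or (step2_rows[OUTCOME2] == BEFORE).sum() == 0:
        raise ValueError(
            "step 2 needs both known-time stillbirth classes after excluding unknowns"
        )

    s1_seed, s2_seed = _spawn(seed, 2)
    known_codes = {f.code for f in schema}
    schema1 = _select_schema(surviving, config.step1_features, known_codes)
    schema2 = _select_schema(surviving, config.step2_features, known_codes)

    y1 = (table[OUTCOME1] == STILLBIRTH).to_numpy().astype(int)
    step1 = _fit_step(table, schema1, y1, config, STILLBIRTH, s1_seed)

    y2 = (step2_rows[OUTCOME2] == DURING).to_numpy().astype(int)
    step2 = _fit_step(step2_rows, schema2, y2, config, DURING, s2_seed)

    return TwoStepModel(step1, step2, n_unknown, tuple(removed), seed)


def predict_two_step(model: TwoStepModel, table: pd.DataFrame) -> pd.DataFrame:
    """Route every row through the hierarchy.

    Step-1 negatives are labelled livebirth and never reach step 2;
    step-1 positives receive step 2's before/during label.  Returns a
    DataFrame with ``step1_score``, ``step2_score`` (NaN when not routed)
    and the final 3-way ``label``.
    """
    s1 = model.step1.score(table)
    routed = s1 >= 0.5
    s2 = np.full(len(table), np.nan)
    labels = np.full(len(table), LABEL_LIVEBIRTH, dtype=object)
    if routed.any():
        routed_scores = model.step2.score(table.loc[routed])
        s2[routed] = routed_scores
        labels[routed] = np.where(routed_scores >= 0.5, LABEL_DURING, LABEL_BEFORE)
    return pd.DataFrame(
        {"step1_score": s1, "step2_score": s2, "label": labels}, index=table.index
    )
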