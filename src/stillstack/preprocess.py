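"""Cleaning and encoding of registry tables into numeric design matrices.

The pipeline mirrors a conventional clinical-tabular workflow: features
with more than 5% missing cells are removed; remaining missing values are
imputed (median for numeric, mode for categorical, lowest level code on
ties); nominal features are one-hot encoded, ordinal features keep their
integer codes, numeric features are min-max scaled with training-split
statistics; the rare class can be rebalanced by seeded majority
undersampling on training splits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import OUTCOME1, OUTCOME2, ConfigurationError, FeatureSpec

__all__ = [
    "remove_high_missing",
    "Imputer",
    "impute",
    "DesignTransform",
    "DesignMatrix",
    "balance_sample",
]

OTHER_LEVEL = "__other__"


class DegenerateInputError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Numeric instances x encoded-columns matrix with provenance.

    ``col_source`` maps every encoded column name back to exactly one
    source feature code, so importance scores can be aggregated per
    feature.
    """

    X: np.ndarray
    columns: list[str]
    col_source: dict[str, str]
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column list")
        if set(self.col_source) != set(self.columns):
            raise ValueError("col_source must cover exactly the encoded columns")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing entries")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if len(self.y) != len(self.X):
                raise ValueError("label vector length mismatch")

    @property
    def features(self) -> list[str]:
        """Source feature codes in first-appearance column order."""
        seen: list[str] = []
        for c in self.columns:
            s = self.col_source[c]
            if s not in seen:
                seen.append(s)
        return seen

    def feature_columns(self, code: str) -> list[int]:
        return [i for i, c in enumerate(self.columns) if self.col_source[c] == code]

    def subset_rows(self, idx) -> "DesignMatrix":
        y = None if self.y is None else self.y[idx]
        return DesignMatrix(self.X[idx], list(self.columns), dict(self.col_source), y)


def remove_high_missing(
    table: pd.DataFrame, schema: Sequence[FeatureSpec], threshold: float = 0.05
) -> tuple[pd.DataFrame, tuple[FeatureSpec, ...], list[str]]:
    """Drop features whose missing fraction is strictly greater than
    ``threshold`` (the "more than 5%" rule). Outcome columns are kept.

    Returns ``(table, surviving_schema, removed_codes)``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError("threshold must be in (0, 1]")
    removed: list[str] = []
    keep: list[FeatureSpec] = []
    for spec in schema:
        frac = float(table[spec.code].isna().mean())
        if frac > threshold:
            removed.append(spec.code)
        else:
            keep.append(spec)
    if not keep:
        raise DegenerateInputError("all features exceed the missingness threshold")
    cols = [f.code for f in keep] + [c for c in (OUTCOME1, OUTCOME2) if c in table.columns]
    return table[cols].copy(), tuple(keep), removed


class Imputer:
    """Deterministic per-feature imputation: median (numeric), mode with
    lowest-code tie-break (binary/nominal/ordinal)."""

    def __init__(self, schema: Sequence[FeatureSpec]):
        self.schema = tuple(schema)
        self.fill_: dict[str, float] | None = None

    def fit(self, table: pd.DataFrame) -> "Imputer":
        fill: dict[str, float] = {}
        for spec in self.schema:
            col = table[spec.code]
            observed = col.dropna()
            if observed.empty:
                raise DegenerateInputError(
                    f"feature {spec.code} is entirely missing; remove it before imputing"
                )
            if spec.dtype == "numeric":
                fill[spec.code] = float(observed.median())
            else:
                counts = observed.value_counts()
                top = counts[counts == counts.max()]
                fill[spec.code] = int(min(top.index))
        self.fill_ = fill
        return self

    def transform(self, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Returns ``(imputed table, boolean imputed-cell mask)``."""
        if self.fill_ is None:
            raise RuntimeError("Imputer not fitted")
        out = table.copy()
        mask = pd.DataFrame(False, index=table.index, columns=[f.code for f in self.schema])
        for spec in self.schema:
            missing = out[spec.code].isna()
            mask[spec.code] = missing.to_numpy()
            if missing.any():
                out.loc[missing, spec.code] = self.fill_[spec.code]
        return out, mask


def impute(
    table: pd.DataFrame, schema: Sequence[FeatureSpec]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit-and-apply convenience wrapper around :class:`Imputer`."""
    return Imputer(schema).fit(table).transform(table)


class DesignTransform:
    """Fitted encoding + normalization: binary -> {0,1}; ordinal -> integer
    codes (order preserved); nominal -> one-hot over training levels plus an
    explicit ``__other__`` column for unseen levels; numeric -> min-max to
    [0,1] with training statistics (constant columns map to 0).

    Parameters learned in :meth:`fit` are reused verbatim at transform
    time, so test rows are encoded without leakage; the fitted state
    round-trips through JSON.
    """

    def __init__(self, schema: Sequence[FeatureSpec], normalization: str = "minmax"):
        if normalization not in ("minmax", "none"):
            raise ConfigurationError("normalization must be 'minmax' or 'none'")
        self.schema = tuple(schema)
        self.normalization = normalization
        self.numeric_range_: dict[str, tuple[float, float]] = {}
        self.nominal_levels_: dict[str, list[int]] = {}
        self.fitted = False

    def fit(self, table: pd.DataFrame) -> "DesignTransform":
        for spec in self.schema:
            col = table[spec.code]
            if col.isna().any():
                raise ValueError(f"{spec.code}: impute before encoding")
            if spec.dtype == "numeric":
                self.numeric_range_[spec.code] = (float(col.min()), float(col.max()))
            elif spec.dtype == "nominal":
                self.nominal_levels_[spec.code] = sorted(int(v) for v in col.unique())
        self.fitted = True
        return self

    def transform(self, table: pd.DataFrame, y: np.ndarray | None = None) -> DesignMatrix:
        if not self.fitted:
            raise RuntimeError("DesignTransform not fitted")
        cols: list[np.ndarray] = []
        names: list[str] = []
        source: dict[str, str] = {}
        for spec in self.schema:
            col = table[spec.code]
            if col.isna().any():
                raise ValueError(f"{spec.code}: impute before encoding")
            if spec.dtype == "numeric":
                lo, hi = self.numeric_range_[spec.code]
                x = col.to_numpy(dtype=float)
                if self.normalization == "minmax":
                    x = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
                cols.append(x)
                names.append(spec.code)
                source[spec.code] = spec.code
            elif spec.dtype in ("binary", "ordinal"):
                cols.append(col.to_numpy(dtype=float))
                names.append(spec.code)
                source[spec.code] = spec.code
            else:  # nominal -> one hot + __other__
                levels = self.nominal_levels_[spec.code]
                vals = col.to_numpy(dtype=float).astype(int)
                known = np.isin(vals, levels)
                if not known.all():
                    warnings.warn(
                        f"{spec.code}: {int((~known).sum())} unseen level(s) mapped "
                        f"to {OTHER_LEVEL}",
                        stacklevel=2,
                    )
                for lv in levels:
                    name = f"{spec.code}={lv}"
                    cols.append((vals == lv).astype(float) * known)
                    names.append(name)
                    source[name] = spec.code
                name = f"{spec.code}={OTHER_LEVEL}"
                cols.append((~known).astype(float))
                names.append(name)
                source[name] = spec.code
        X = np.column_stack(cols) if cols else np.empty((len(table), 0))
        return DesignMatrix(X, names, source, y)

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "normalization": self.normalization,
                "numeric_range": self.numeric_range_,
                "nominal_levels": self.nominal_levels_,
            }
        )

    def load_json(self, payload: str) -> "DesignTransform":
        d = json.loads(payload)
        self.normalization = d["normalization"]
        self.numeric_range_ = {k: tuple(v) for k, v in d["numeric_range"].items()}
        self.nominal_levels_ = {k: list(v) for k, v in d["nominal_levels"].items()}
        self.fitted = True
        return self


def balance_sample(matrix: DesignMatrix, ratio: float, seed: int) -> DesignMatrix:
    """Undersample the majority class (without replacement, seeded) to at
    most ``ratio`` times the minority count.  Minority rows are untouched;
    surviving rows keep their original order.  Intended for training
    splits only.
    """
    if matrix.y is None:
        raise ValueError("balance_sample needs labels")
    if ratio <= 0:
        raise ConfigurationError("sampling ratio must be positive")
    values, counts = np.unique(matrix.y, return_counts=True)
    if len(values) < 2:
        raise DegenerateInputError("both classes must be present")
    minority = values[np.argmin(counts)]
    n_min = counts.min()
    target = int(round(ratio * n_min))
    if target < 1:
        raise ConfigurationError("ratio makes the majority target < 1 row")
    keep = np.zeros(len(matrix.y), dtype=bool)
    keep[matrix.y == minority] = True
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(matrix.y != minority)
    if len(maj_idx) > target:
        maj_idx = rng.choice(maj_idx, size=target, replace=False)
    keep[maj_idx] = True
    return matrix.subset_rows(np.flatnonzero(keep))
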