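"""Synthetic perinatal registry generator.

Emulates the statistical skeleton of a national birth registry: a rare
stillbirth class (0.396% by default), an outcome2 timing split with a tiny
"during delivery" minority and an "unknown" stratum, class-conditionally
shifted informative features, and MCAR missingness with per-feature rates
in the registry's observed range.

Determinism: every random stream is derived from ``(config.seed, stream
index)``, so identical configurations produce bit-identical tables,
including mask positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import (
    BEFORE,
    DURING,
    LIVEBIRTH,
    OUTCOME1,
    OUTCOME2,
    STILLBIRTH,
    UNKNOWN,
    ConfigurationError,
    FeatureSpec,
    GeneratorConfig,
)

__all__ = [
    "generate_registry",
    "inject_missing",
    "missingness_report",
    "write_registry",
    "read_registry",
]

_CAT_DTYPES = ("binary", "nominal", "ordinal")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _base_probs(spec: FeatureSpec) -> np.ndarray:
    if spec.base_probs is not None:
        p = np.asarray(spec.base_probs, dtype=float)
        if len(p) != spec.levels:
            raise ConfigurationError(f"{spec.code}: base_probs length != n_levels")
    else:
        # gently decreasing level frequencies
        p = 1.0 / (1.0 + np.arange(spec.levels))
    return p / p.sum()


def _categorical_probs(spec: FeatureSpec, shift: float) -> np.ndarray:
    """Tilt the base level probabilities by ``exp(shift * z_l)`` with
    level scores z spread over [-1, 1]."""
    base = _base_probs(spec)
    if shift == 0.0:
        return base
    z = np.linspace(-1.0, 1.0, spec.levels)
    p = base * np.exp(shift * z)
    return p / p.sum()


def _draw_numeric(spec: FeatureSpec, group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """group: 0 = livebirth, 1 = stillbirth before, 2 = stillbirth during."""
    n = len(group)
    out = rng.normal(spec.loc, spec.scale, size=n)
    still = group >= 1
    if spec.stillbirth_mixture is not None:
        idx = np.flatnonzero(still)
        if idx.size:
            w = np.array([c[0] for c in spec.stillbirth_mixture])
            comp = rng.choice(len(w), size=idx.size, p=w / w.sum())
            locs = np.array([c[1] for c in spec.stillbirth_mixture])[comp]
            scales = np.array([c[2] for c in spec.stillbirth_mixture])[comp]
            out[idx] = rng.normal(locs, scales)
    elif spec.effect != 0.0:
        out[still] += spec.effect * spec.scale
    if spec.effect_timing != 0.0:
        out[group == 2] += spec.effect_timing * spec.scale
    return out


def _draw_binary(spec: FeatureSpec, group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p1 = _base_probs(spec)[1]
    logit = np.log(p1 / (1.0 - p1))
    shift = spec.effect * (group >= 1) + spec.effect_timing * (group == 2)
    return (rng.random(len(group)) < _sigmoid(logit + shift)).astype(np.int64)


def _draw_categorical(spec: FeatureSpec, group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(len(group), dtype=np.int64)
    shifts = {0: 0.0, 1: spec.effect, 2: spec.effect + spec.effect_timing}
    for g, shift in shifts.items():
        idx = np.flatnonzero(group == g)
        if idx.size:
            p = _categorical_probs(spec, shift)
            out[idx] = rng.choice(spec.levels, size=idx.size, p=p)
    return out


def generate_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a registry table from ``config``.

    The stillbirth count is fixed at ``round(n_total * stillbirth_rate)``
    (deterministic count, random row placement), and the outcome2 split is
    likewise fixed by rounding so that ``#before + #during + #unknown``
    equals the stillbirth count exactly.  Rows whose timing is reported
    ``unknown`` are drawn from a latent before/during mixture at the
    known-time odds, then relabelled — the timing exists but was not
    recorded.

    Returns a DataFrame with one column per feature (numeric: float64,
    categorical: nullable Int64 level codes), plus ``outcome1`` and
    ``outcome2``; the generator config seed is stored in ``.attrs``.
    """
    n = config.n_total
    n_still = int(round(n * config.stillbirth_rate))
    n_during = int(round(n_still * config.during_fraction))
    n_unknown = int(round(n_still * config.unknown_fraction))
    if n_during + n_unknown > n_still:
        n_unknown = n_still - n_during
    n_before = n_still - n_during - n_unknown

    rng = _rng(config.seed, 0)
    still_idx = rng.choice(n, size=n_still, replace=False)
    order = rng.permutation(n_still)
    during_idx = still_idx[order[:n_during]]
    unknown_idx = still_idx[order[n_during : n_during + n_unknown]]

    outcome1 = np.full(n, LIVEBIRTH, dtype=object)
    outcome1[still_idx] = STILLBIRTH
    outcome2 = np.full(n, None, dtype=object)
    outcome2[still_idx] = BEFORE
    outcome2[during_idx] = DURING
    outcome2[unknown_idx] = UNKNOWN

    # latent generation group: unknown-time rows get a latent timing drawn
    # at the known-time before:during odds
    group = np.zeros(n, dtype=np.int64)
    group[still_idx] = 1
    group[during_idx] = 2
    if n_unknown:
        denom = n_before + n_during
        p_during = (n_during / denom) if denom else 0.0
        latent = rng.random(n_unknown) < p_during
        group[unknown_idx] = np.where(latent, 2, 1)

    data: dict[str, object] = {}
    for j, spec in enumerate(config.schema):
        frng = _rng(config.seed, j + 1)
        if spec.dtype == "numeric":
            data[spec.code] = _draw_numeric(spec, group, frng)
        elif spec.dtype == "binary":
            data[spec.code] = pd.array(_draw_binary(spec, group, frng), dtype="Int64")
        else:
            data[spec.code] = pd.array(_draw_categorical(spec, group, frng), dtype="Int64")

    table = pd.DataFrame(data)
    table[OUTCOME1] = outcome1
    table[OUTCOME2] = outcome2
    table.attrs["generator"] = {
        "n_total": n,
        "stillbirth_rate": config.stillbirth_rate,
        "during_fraction": config.during_fraction,
        "unknown_fraction": config.unknown_fraction,
        "seed": config.seed,
    }
    return table


def inject_missing(
    table: pd.DataFrame, schema, seed: int, stream_offset: int = 10_000
) -> pd.DataFrame:
    """Mask feature cells completely at random at each feature's
    ``missing_rate``.  Outcome columns are never masked.

    Returns a new table; the realized per-column and row-level missingness
    is available via :func:`missingness_report`.
    """
    out = table.copy()
    for j, spec in enumerate(schema):
        if spec.code in (OUTCOME1, OUTCOME2):
            raise ConfigurationError("outcome columns may not be masked")
        if spec.missing_rate == 0.0 or spec.code not in out.columns:
            continue
        mrng = _rng(seed, stream_offset + j)
        mask = mrng.random(len(out)) < spec.missing_rate
        col = out[spec.code]
        if col.dtype == object:
            raise ConfigurationError(f"cannot mask non-feature column {spec.code}")
        out[spec.code] = col.mask(mask)
    return out


def missingness_report(table: pd.DataFrame) -> dict:
    """Per-feature missing fractions plus the any-missing row fraction."""
    feats = [c for c in table.columns if c not in (OUTCOME1, OUTCOME2)]
    per_col = {c: float(table[c].isna().mean()) for c in feats}
    any_row = float(table[feats].isna().any(axis=1).mean())
    return {"per_feature": per_col, "row_any_missing": any_row}


# ---------------------------------------------------------------------------
# CSV round trip (empty string encodes a missing cell)

def write_registry(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_registry(path, schema) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype="object")
    for spec in schema:
        if spec.code not in table.columns:
            continue
        if spec.dtype == "numeric":
            table[spec.code] = pd.to_numeric(table[spec.code], errors="raise")
        else:
            table[spec.code] = pd.array(
                pd.to_numeric(table[spec.code], errors="raise"), dtype="Int64"
            )
    if OUTCOME2 in table.columns:
        table[OUTCOME2] = table[OUTCOME2].where(table[OUTCOME2].notna(), None)
    return table
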