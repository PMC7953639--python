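"""Feature schema for registry-like perinatal tables.

A registry table has one row per birth, a column per feature, and two
outcome columns: ``outcome1`` (livebirth / stillbirth) and ``outcome2``
(stillbirth before delivery / during delivery / unknown, defined only for
stillbirth rows).  Features fall into four categories — maternal (M),
perinatal (P), environmental (E) and health-system (H) — and four dtypes:
binary, nominal, ordinal, numeric.  Categorical features are stored as
integer level codes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: observed per-feature missing-rate ceiling in the source registry
DEFAULT_MISSING_MAX = 0.0463
#: fraction of rows carrying at least one missing value in the source registry
TARGET_ROW_MISSING = 0.1974

OUTCOME1 = "outcome1"
OUTCOME2 = "outcome2"
LIVEBIRTH = "livebirth"
STILLBIRTH = "stillbirth"
BEFORE = "before"
DURING = "during"
UNKNOWN = "unknown"

CATEGORIES = ("M", "P", "E", "H")
DTYPES = ("binary", "nominal", "ordinal", "numeric")


class ConfigurationError(ValueError):
    """Raised when a schema or generator configuration is invalid."""


@dataclass(frozen=True)
class FeatureSpec:
    """Description of a single registry feature.

    Parameters
    ----------
    code:
        Short identifier, e.g. ``"f31"``.
    category:
        One of ``M`` (maternal), ``P`` (perinatal), ``E`` (environmental),
        ``H`` (health system).
    dtype:
        ``binary``, ``nominal``, ``ordinal`` or ``numeric``.
    n_levels:
        Number of levels; required (>= 2) for nominal/ordinal, forbidden
        otherwise.
    missing_rate:
        Missing-completely-at-random cell rate in ``[0, 1]``.
    effect:
        Class-conditional effect size separating stillbirth from livebirth.
        Numeric features: location shift in units of ``scale``.  Binary:
        additive logit shift.  Nominal/ordinal: strength of an exponential
        probability tilt across levels.
    effect_timing:
        Additional effect separating stillbirth *during* delivery from
        stillbirth *before* delivery (same semantics as ``effect``).
    loc, scale:
        Base (livebirth) distribution for numeric features.
    stillbirth_mixture:
        Optional Gaussian mixture ``((weight, loc, scale), ...)`` replacing
        the shifted-Gaussian stillbirth distribution of a numeric feature
        (used for the non-linear gestational-age-like shape).
    base_probs:
        Optional base level probabilities for categorical features
        (binary: ``(p0, p1)``).
    """

    code: str
    name: str = ""
    category: str = "M"
    dtype: str = "numeric"
    n_levels: int | None = None
    missing_rate: float = 0.0
    effect: float = 0.0
    effect_timing: float = 0.0
    loc: float = 0.0
    scale: float = 1.0
    stillbirth_mixture: tuple[tuple[float, float, float], ...] | None = None
    base_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"{self.code}: bad category {self.category!r}")
        if self.dtype not in DTYPES:
            raise ConfigurationError(f"{self.code}: bad dtype {self.dtype!r}")
        if self.dtype in ("nominal", "ordinal"):
            if self.n_levels is None or self.n_levels < 2:
                raise ConfigurationError(
                    f"{self.code}: nominal/ordinal features need n_levels >= 2"
                )
        elif self.n_levels is not None:
            raise ConfigurationError(
                f"{self.code}: n_levels is only valid for nominal/ordinal features"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError(
                f"{self.code}: missing_rate {self.missing_rate} outside [0, 1]"
            )
        if self.scale <= 0:
            raise ConfigurationError(f"{self.code}: scale must be positive")
        if self.stillbirth_mixture is not None:
            w = sum(c[0] for c in self.stillbirth_mixture)
            if abs(w - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{self.code}: mixture weights sum to {w}, expected 1"
                )

    @property
    def informative(self) -> bool:
        """True if the feature carries any class-conditional signal."""
        return (
            self.effect != 0.0
            or self.effect_timing != 0.0
            or self.stillbirth_mixture is not None
        )

    @property
    def levels(self) -> int:
        if self.dtype == "binary":
            return 2
        if self.n_levels is None:
            raise ValueError(f"{self.code} is numeric; no levels")
        return self.n_levels


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic registry generator.

    Defaults emulate the source registry: 0.396% stillbirth prevalence and
    an outcome2 split of 4557 before / 144 during / 801 unknown out of 5502
    stillbirths (the counts that are internally consistent in the source;
    an alternative 5602/901 accounting is also reported there and can be
    configured via the fractions).
    """

    n_total: int
    schema: tuple[FeatureSpec, ...]
    stillbirth_rate: float = 0.00396
    during_fraction: float = 144 / 5502
    unknown_fraction: float = 801 / 5502
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ConfigurationError("n_total must be >= 1")
        if not self.schema:
            raise ConfigurationError("schema must be non-empty")
        if not 0.0 < self.stillbirth_rate < 1.0:
            raise ConfigurationError("stillbirth_rate must be in (0, 1)")
        for f in (self.during_fraction, self.unknown_fraction):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("outcome2 fractions must be in [0, 1]")
        if self.during_fraction + self.unknown_fraction > 1.0 + 1e-12:
            raise ConfigurationError(
                "during_fraction + unknown_fraction must not exceed 1"
            )
        codes = [f.code for f in self.schema]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("duplicate feature codes in schema")
        if OUTCOME1 in codes or OUTCOME2 in codes:
            raise ConfigurationError("outcome columns may not appear in schema")


def assign_missing_rates(
    schema: Sequence[FeatureSpec],
    target_row_missing: float = TARGET_ROW_MISSING,
    cap: float = DEFAULT_MISSING_MAX,
) -> tuple[FeatureSpec, ...]:
    """Assign per-feature MCAR rates so the expected fraction of rows with
    at least one missing cell equals ``target_row_missing``.

    Rates are spread over features with a deterministic weight pattern,
    capped at ``cap``, and solved by bisection on a common scale factor.
    """
    import math

    n = len(schema)
    # heavy-tailed pattern: a few features near the cap, many near zero
    weights = [(((7 * i + 3) % 23) / 23.0) ** 12 for i in range(n)]
    if all(w == 0 for w in weights):
        raise ConfigurationError("degenerate weight pattern")

    def row_missing(s: float) -> float:
        log_keep = sum(math.log(1.0 - min(s * w, cap)) for w in weights)
        return 1.0 - math.exp(log_keep)

    hi = cap * 2
    while row_missing(hi) < target_row_missing:
        hi *= 2
        if hi > 1e6:
            raise ConfigurationError("target row missingness unattainable under cap")
    lo = 0.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if row_missing(mid) < target_row_missing:
            lo = mid
        else:
            hi = mid
    s = (lo + hi) / 2
    return tuple(
        dataclasses.replace(f, missing_rate=min(s * w, cap))
        for f, w in zip(schema, weights)
    )


# (code, name, category, dtype, n_levels, extra-kwargs)
_DEFAULT_ROWS: list[tuple] = [
    ("f1", "any pregnancy risk factor", "M", "binary", None, dict(effect=0.6, base_probs=(0.85, 0.15))),
    ("f2", "gestational diabetes", "M", "binary", None, dict(base_probs=(0.93, 0.07))),
    ("f3", "cardiovascular diseases", "M", "binary", None, dict(base_probs=(0.98, 0.02))),
    ("f4", "other maternal underlying diseases", "M", "binary", None, dict(base_probs=(0.95, 0.05))),
    ("f5", "chronic hypertension", "M", "binary", None, dict(base_probs=(0.97, 0.03))),
    ("f6", "fetal abnormalities", "P", "binary", None, dict(effect=1.0, effect_timing=0.5, base_probs=(0.985, 0.015))),
    ("f7", "HIV positive", "M", "binary", None, dict(base_probs=(0.999, 0.001))),
    ("f8", "VDRL positive", "M", "binary", None, dict(base_probs=(0.999, 0.001))),
    ("f9", "preeclampsia or eclampsia risk factors", "M", "binary", None, dict(effect=0.4, base_probs=(0.96, 0.04))),
    ("f10", "intrauterine growth restriction", "P", "binary", None, dict(effect=0.8, base_probs=(0.98, 0.02))),
    ("f11", "infant mortality after previous deliveries", "M", "binary", None, dict(base_probs=(0.97, 0.03))),
    ("f12", "stillbirth in previous pregnancies", "M", "binary", None, dict(effect=0.5, base_probs=(0.98, 0.02))),
    ("f13", "type 1 or 2 diabetes", "M", "binary", None, dict(base_probs=(0.97, 0.03))),
    ("f14", "hepatitis B", "M", "binary", None, dict(base_probs=(0.99, 0.01))),
    ("f15", "chorioamnionitis", "M", "binary", None, dict(base_probs=(0.995, 0.005))),
    ("f16", "maternal drug or alcohol addiction", "M", "binary", None, dict(base_probs=(0.99, 0.01))),
    ("f17", "smoking", "M", "binary", None, dict(base_probs=(0.97, 0.03))),
    ("f18", "placental abruption", "P", "binary", None, dict(effect=0.5, base_probs=(0.99, 0.01))),
    ("f19", "meconium-stained amniotic fluid", "P", "binary", None, dict(base_probs=(0.95, 0.05))),
    ("f20", "irregular fetal heartbeat", "P", "binary", None, dict(effect=0.5, base_probs=(0.97, 0.03))),
    ("f21", "early rupture of the amniotic sac", "P", "binary", None, dict(base_probs=(0.93, 0.07))),
    ("f22", "delivery risk factors", "M", "nominal", 6, dict(effect=0.4)),
    ("f24", "maternal autoimmune disease", "M", "binary", None, dict(base_probs=(0.99, 0.01))),
    ("f25", "epidural anesthesia", "M", "binary", None, dict(base_probs=(0.9, 0.1))),
    ("f26", "placenta accreta", "P", "binary", None, dict(base_probs=(0.995, 0.005))),
    ("f27", "IVF in the current pregnancy", "M", "binary", None, dict(base_probs=(0.985, 0.015))),
    ("f28", "number of pregnancies", "M", "numeric", None, dict(loc=2.61, scale=1.67, effect=0.263)),
    ("f29", "number of previous deliveries", "M", "numeric", None, dict(loc=1.5, scale=1.2)),
    ("f30", "miscarriage number", "M", "numeric", None, dict(loc=0.4, scale=0.8, effect=0.2, effect_timing=0.5)),
    ("f31", "gestational age", "P", "numeric", None, dict(
        loc=38.53, scale=1.57, effect_timing=0.3,
        stillbirth_mixture=((0.55, 32.0, 3.2), (0.45, 38.2, 1.7)))),
    ("f32", "fetal weight (g)", "P", "numeric", None, dict(loc=3122.90, scale=485.65, effect=-1.904)),
    ("f33", "birth number", "M", "numeric", None, dict(loc=1.05, scale=0.3)),
    ("f34", "live children from previous pregnancies", "M", "numeric", None, dict(loc=1.2, scale=1.1)),
    ("f35", "delivery type (vaginal/cesarean)", "M", "binary", None, dict(effect=0.3, base_probs=(0.55, 0.45))),
    ("f36", "cesarean main cause", "M", "nominal", 8, dict(effect_timing=0.6)),
    ("f37", "medical science university operating the hospital", "H", "nominal", 10, dict(effect_timing=0.4)),
    ("f38", "province", "E", "nominal", 31, dict(effect_timing=0.5)),
    ("f39", "hospital", "H", "nominal", 40, dict(effect_timing=0.7)),
    ("f40", "hospital type", "H", "nominal", 4, dict(effect=0.4)),
    ("f41", "fetal gender", "P", "nominal", 3, dict(effect=0.2, effect_timing=0.3, base_probs=(0.51, 0.47, 0.02))),
    ("f42", "delivery main cause", "M", "nominal", 8, dict(effect_timing=0.8)),
    ("f43", "delivery place", "H", "nominal", 3, dict(base_probs=(0.9, 0.08, 0.02))),
    ("f44", "maternal nationality", "M", "nominal", 4, dict(base_probs=(0.92, 0.05, 0.02, 0.01))),
    ("f45", "maternal education", "M", "ordinal", 6, dict(effect=-0.4, effect_timing=-0.3)),
    ("f46", "consanguinity with spouse", "M", "binary", None, dict(base_probs=(0.75, 0.25))),
    ("f47", "city", "E", "nominal", 50, dict(effect_timing=0.3)),
    ("f48", "maternal insurance type", "M", "nominal", 5, dict(effect=0.3)),
    ("f49", "fetal height (cm)", "P", "numeric", None, dict(loc=50.0, scale=3.2, effect=-1.3, effect_timing=0.4)),
    ("f52", "father nationality", "M", "nominal", 4, dict(base_probs=(0.92, 0.05, 0.02, 0.01))),
    ("f53", "maternal age", "M", "numeric", None, dict(loc=27.98, scale=6.27, effect=0.279, effect_timing=0.4)),
]


_COMPACT_CODES = (
    "f1", "f2", "f6", "f28", "f29", "f30", "f31", "f32",
    "f40", "f41", "f42", "f45", "f49", "f53",
)


def compact_schema(with_missing: bool = True) -> tuple[FeatureSpec, ...]:
    """A 14-feature subset of the default schema (all four dtypes, the
    strongly informative perinatal features plus noise features) for
    desk-scale experiments where refitting the full stack many times is
    required."""
    full = {f.code: f for f in default_schema(with_missing=with_missing)}
    return tuple(full[c] for c in _COMPACT_CODES)


def default_schema(with_missing: bool = True) -> tuple[FeatureSpec, ...]:
    """The registry-like default schema (50 features, codes f1-f53).

    Effect sizes and numeric moments follow the source registry's reported
    class-conditional statistics; missing rates are assigned so that the
    expected any-missing row fraction matches :data:`TARGET_ROW_MISSING`
    while no single feature exceeds :data:`DEFAULT_MISSING_MAX`.
    """
    specs = tuple(
        FeatureSpec(code=c, name=n, category=cat, dtype=dt, n_levels=nl, **kw)
        for c, n, cat, dt, nl, kw in _DEFAULT_ROWS
    )
    if with_missing:
        specs = assign_missing_rates(specs)
    return specs


# ---------------------------------------------------------------------------
# serialization

def schema_to_dicts(schema: Sequence[FeatureSpec]) -> list[dict]:
    out = []
    for f in schema:
        d = dataclasses.asdict(f)
        if d["stillbirth_mixture"] is not None:
            d["stillbirth_mixture"] = [list(c) for c in d["stillbirth_mixture"]]
        if d["base_probs"] is not None:
            d["base_probs"] = list(d["base_probs"])
        out.append(d)
    return out


def schema_from_dicts(rows: Sequence[dict]) -> tuple[FeatureSpec, ...]:
    specs = []
    for d in rows:
        d = dict(d)
        if d.get("stillbirth_mixture") is not None:
            d["stillbirth_mixture"] = tuple(tuple(c) for c in d["stillbirth_mixture"])
        if d.get("base_probs") is not None:
            d["base_probs"] = tuple(d["base_probs"])
        specs.append(FeatureSpec(**d))
    return tuple(specs)


def save_schema(schema: Sequence[FeatureSpec], path) -> None:
    path = str(path)
    rows = schema_to_dicts(schema)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(rows, fh)
        else:
            json.dump(rows, fh, indent=1)


def load_schema(path) -> tuple[FeatureSpec, ...]:
    path = str(path)
    with open(path) as fh:
        rows = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
    return schema_from_dicts(rows)
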