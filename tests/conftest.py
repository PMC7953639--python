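"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit loops, pairwise
enumeration, hand-run pool-adjacent-violators) and independent of the
package code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stillstack.schema import FeatureSpec, GeneratorConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles

def brute_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of s(i) = (b - a) / max(a, b); singletons get 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    svals = []
    for i in range(len(X)):
        own = labels == labels[i]
        if own.sum() == 1:
            svals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if own[j] and j != i])
        b = np.inf
        for c in np.unique(labels):
            if c == labels[i]:
                continue
            other = labels == c
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in np.flatnonzero(other)]))
        svals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(svals))


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise concordance count: P(score_pos > score_neg) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pava(y: np.ndarray) -> np.ndarray:
    """Hand-run pool-adjacent-violators on y ordered by score."""
    blocks = [[v, 1] for v in map(float, y)]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            m, n = blocks[i], blocks[i + 1]
            merged = [(m[0] * m[1] + n[0] * n[1]) / (m[1] + n[1]), m[1] + n[1]]
            blocks[i : i + 2] = [merged]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for val, cnt in blocks:
        out.extend([val] * cnt)
    return np.array(out)


# ---------------------------------------------------------------------------
# schema helpers

def planted_schema(n_noise: int = 7, effect: float = 1.0) -> tuple[FeatureSpec, ...]:
    """Three informative numeric features (location shift = ``effect`` SDs)
    among ``n_noise`` non-informative ones."""
    feats = [
        FeatureSpec(code=f"p{i}", dtype="numeric", effect=effect) for i in range(3)
    ]
    feats += [FeatureSpec(code=f"n{i}", dtype="numeric") for i in range(n_noise)]
    return tuple(feats)


def null_schema(n_features: int = 8) -> tuple[FeatureSpec, ...]:
    """Entirely non-informative features (global null)."""
    return tuple(FeatureSpec(code=f"x{i}", dtype="numeric") for i in range(n_features))


@pytest.fixture(scope="session")
def planted_table():
    """Balanced-ish case-control table with three planted features."""
    from stillstack.synth import generate_registry

    cfg = GeneratorConfig(
        n_total=1500, schema=planted_schema(), stillbirth_rate=0.3, seed=11
    )
    return generate_registry(cfg), planted_schema()


@pytest.fixture(scope="session")
def separable_xy():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-4, 0.5, (40, 2)), rng.normal(4, 0.5, (40, 2))])
    y = np.repeat([0, 1], 40)
    return X, y
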