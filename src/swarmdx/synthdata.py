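"""Synthetic heart-disease-like cohorts, sequence fixtures and optimizer benchmarks.

The generator emulates the shape of the classic 303-patient heart-disease
cohort: 13 mixed continuous/categorical predictors (age, sex, cp, trestbps,
chol, fbs, restecg, thalach, exang, oldpeak, slope, ca, thal), a binary
presence/absence label (165/138 by default), and a *known* planted subset of
informative predictors.  Labels follow a logistic score over the planted
predictors: the score is computed, seeded Gaussian noise is added, and the
``n_presence`` highest-scoring rows become the positive class.  Ranking (not
Bernoulli sampling) makes the class counts exact and every fixture
bit-reproducible under a fixed seed.

The generator matches the cohort only in type and shape; it makes no attempt
to match the real data's marginal distributions or inter-feature
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .table import FeatureMask, FeatureTable

__all__ = [
    "SynthSpec",
    "SynthDataset",
    "generate_hd_like",
    "logistic_scores",
    "assign_labels",
    "generate_sequences",
    "Benchmark",
    "benchmark_suite",
]

# 13 predictors of the heart-disease cohort; "num" is the label and is never
# a candidate feature.
HD_FEATURE_NAMES = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
)
HD_LABEL_NAME = "num"

# integer-coded columns and their level counts (sex 0/1, cp 1-4 style codes
# collapsed to 0-based, etc.); any other categorical column gets 3 levels
_HD_CATEGORICAL_LEVELS = {
    "sex": 2, "cp": 4, "fbs": 2, "restecg": 3,
    "exang": 2, "slope": 3, "ca": 4, "thal": 3,
}
_HD_CATEGORICAL_IDX = tuple(
    i for i, n in enumerate(HD_FEATURE_NAMES) if n in _HD_CATEGORICAL_LEVELS
)

# rough clinical location/scale pairs so continuous columns arrive on their
# natural units and genuinely need standardizing
_HD_CONTINUOUS_PARAMS = {
    "age": (54.0, 9.0),
    "trestbps": (131.0, 17.0),
    "chol": (246.0, 51.0),
    "thalach": (149.0, 22.0),
    "oldpeak": (1.0, 1.1),
}


@dataclass(frozen=True)
class SynthSpec:
    """Generating parameters for one synthetic cohort.

    Defaults reproduce the reference shape: 303 rows, 165 presence / 138
    absence, 13 mixed predictors with four strongly informative ones planted
    at indices 0 (age), 2 (cp), 7 (thalach) and 9 (oldpeak).
    """

    n_rows: int = 303
    n_presence: int = 165
    n_absence: int = 138
    n_features: int = 13
    informative_idx: tuple[int, ...] = (0, 2, 7, 9)
    effect_sizes: tuple[float, ...] = (3.0, -2.5, 2.0, 2.5)
    noise_sd: float = 0.5
    categorical_idx: tuple[int, ...] = _HD_CATEGORICAL_IDX
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows <= 0 or self.n_features <= 0:
            raise ValueError("n_rows and n_features must be positive")
        if self.n_presence + self.n_absence != self.n_rows:
            raise ValueError(
                f"n_presence ({self.n_presence}) + n_absence ({self.n_absence}) "
                f"must equal n_rows ({self.n_rows})"
            )
        if len(self.informative_idx) != len(self.effect_sizes):
            raise ValueError("effect_sizes must match informative_idx in length")
        if self.informative_idx and not set(self.informative_idx) <= set(range(self.n_features)):
            raise ValueError("informative_idx out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def feature_names(self) -> list[str]:
        if self.n_features == len(HD_FEATURE_NAMES):
            return list(HD_FEATURE_NAMES)
        return [f"f{i}" for i in range(self.n_features)]


@dataclass
class SynthDataset:
    table: FeatureTable
    truth_mask: FeatureMask
    generating_params: SynthSpec


def logistic_scores(
    X: np.ndarray, informative_idx: tuple[int, ...], effect_sizes: tuple[float, ...]
) -> np.ndarray:
    """Noise-free log-odds score: sum of effect sizes times per-column
    z-standardized informative values.

    Standardization happens inside the score so a column's contribution is
    invariant to its raw units; a constant column contributes zero.  Because
    the score touches columns only through their own values, permuting column
    order together with ``informative_idx`` leaves scores unchanged.
    """
    X = np.asarray(X, dtype=float)
    score = np.zeros(X.shape[0])
    for idx, w in zip(informative_idx, effect_sizes):
        col = X[:, idx]
        sd = col.std()
        if sd > 0:
            score += w * (col - col.mean()) / sd
    return score


def assign_labels(
    X: np.ndarray,
    informative_idx: tuple[int, ...],
    effect_sizes: tuple[float, ...],
    noise: np.ndarray,
    n_presence: int,
) -> np.ndarray:
    """Rank-threshold labeling: the ``n_presence`` rows with the highest
    noisy logistic score get label 1.  Ties break by row index (stable sort),
    so the labeling is fully deterministic."""
    score = logistic_scores(X, informative_idx, effect_sizes) + noise
    order = np.argsort(-score, kind="stable")
    y = np.zeros(X.shape[0], dtype=int)
    y[order[:n_presence]] = 1
    return y


def generate_hd_like(spec: SynthSpec = SynthSpec()) -> SynthDataset:
    """Generate one cohort according to ``spec``.

    Columns are drawn in index order from a single seeded generator:
    categorical columns as uniform integer codes over their small level sets,
    continuous columns as Gaussians on rough clinical scales.  If
    ``informative_idx`` is empty the labels are pure noise rankings and carry
    no signal about the features.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = spec.feature_names()
    cat = set(spec.categorical_idx)

    cols = {}
    for j, name in enumerate(names):
        if j in cat:
            levels = _HD_CATEGORICAL_LEVELS.get(name, 3)
            cols[name] = rng.integers(0, levels, size=spec.n_rows).astype(float)
        else:
            loc, scale = _HD_CONTINUOUS_PARAMS.get(name, (0.0, 1.0))
            cols[name] = rng.normal(loc, scale, size=spec.n_rows)
    X = pd.DataFrame(cols)

    noise = spec.noise_sd * rng.normal(size=spec.n_rows)
    y = assign_labels(
        X.to_numpy(dtype=float), spec.informative_idx, spec.effect_sizes, noise, spec.n_presence
    )

    bits = np.zeros(spec.n_features, dtype=int)
    bits[list(spec.informative_idx)] = 1
    return SynthDataset(
        table=FeatureTable(X, y, positive=1),
        truth_mask=FeatureMask(bits, feature_names=names),
        generating_params=spec,
    )


def no_signal_spec(seed: int = 0) -> SynthSpec:
    """Default shape with no planted features: labels independent of X."""
    return replace(SynthSpec(), informative_idx=(), effect_sizes=(), seed=seed)


def generate_sequences(
    n: int, length: int, separation: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class 1-D Gaussian sequence fixtures for the recurrent classifier.

    Class 0 sequences are standard normal per timestep; class 1 sequences are
    shifted up by ``separation``.  ``separation=0`` makes the classes
    indistinguishable.  Returns ``(X, y)`` with ``X`` of shape (n, length).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    n1 = n // 2
    y = np.repeat([0, 1], [n - n1, n1])
    X = rng.normal(size=(n, length)) + separation * y[:, None]
    return X, y


@dataclass(frozen=True)
class Benchmark:
    """A test objective with its box and known global minimum."""

    name: str
    fn: Callable[[np.ndarray], float]
    lower: float
    upper: float
    minimum: Callable[[int], np.ndarray]
    minimum_value: float

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        return np.full(dim, self.lower), np.full(dim, self.upper)


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x) ** 2))


def _rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def benchmark_suite() -> dict[str, Benchmark]:
    """Sphere, Rosenbrock and Rastrigin with standard boxes and known optima."""
    return {
        "sphere": Benchmark("sphere", _sphere, -5.12, 5.12, np.zeros, 0.0),
        "rosenbrock": Benchmark("rosenbrock", _rosenbrock, -5.0, 10.0, np.ones, 0.0),
        "rastrigin": Benchmark("rastrigin", _rastrigin, -5.12, 5.12, np.zeros, 0.0),
    }
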