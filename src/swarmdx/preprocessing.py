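"""Z-score standardization: x_new = (x - mu) / sigma.

Stats are fit on training rows only and applied to held-out rows, keeping
evaluation leakage-free.  Sample standard deviation (divisor n-1) is the
default, switchable to the population form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["NormalizationStats", "DegenerateColumnError", "fit_normalizer", "apply_zscore"]


class DegenerateColumnError(ValueError):
    """A column has zero variance and cannot be z-scored."""

    def __init__(self, names: list[str]):
        self.names = names
        super().__init__(f"zero-variance column(s): {', '.join(map(str, names))}")


@dataclass
class NormalizationStats:
    """Per-feature mean and standard deviation, with column names."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_names: list[str]
    ddof: int = 1

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.mu) == len(self.sigma) == len(self.feature_names)):
            raise ValueError("mu, sigma and feature_names must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    def to_json(self) -> str:
        doc = {
            name: {"mu": float(m), "sigma": float(s)}
            for name, m, s in zip(self.feature_names, self.mu, self.sigma)
        }
        return json.dumps({"ddof": self.ddof, "features": doc}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        doc = json.loads(text)
        names = list(doc["features"])
        mu = [doc["features"][n]["mu"] for n in names]
        sigma = [doc["features"][n]["sigma"] for n in names]
        return cls(np.array(mu), np.array(sigma), names, ddof=doc.get("ddof", 1))


def fit_normalizer(
    X: np.ndarray, feature_names: list[str] | None = None, ddof: int = 1
) -> NormalizationStats:
    """Column means and standard deviations of a (n x d) matrix.

    Raises :class:`DegenerateColumnError` naming every zero-variance column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        raise DegenerateColumnError([feature_names[i] for i in bad])
    return NormalizationStats(mu, sigma, list(feature_names), ddof=ddof)


def apply_zscore(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardize columns with previously fitted stats."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(stats.mu):
        raise ValueError(
            f"X has {X.shape[1]} columns but stats were fit on {len(stats.mu)}"
        )
    return (X - stats.mu) / stats.sigma
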