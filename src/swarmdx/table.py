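"""Core tabular containers shared across the pipeline.

A :class:`FeatureTable` is the single in-memory representation of a patient
cohort: a real-valued patient-by-feature matrix with named columns, a binary
label vector and a declared positive class.  A :class:`FeatureMask` is a
binary vector over the candidate predictors — the search state and the output
of wrapper feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "FeatureMask"]


@dataclass
class FeatureTable:
    """Patient-by-feature matrix with labels.

    Parameters
    ----------
    X : pandas.DataFrame
        Rows are patients, columns are named predictors (all numeric; integer
        codes for categorical predictors are stored as plain numbers).
    y : numpy.ndarray
        Label per row, drawn from a two-label alphabet.
    positive : object
        The label treated as the positive ("presence") class.
    """

    X: pd.DataFrame
    y: np.ndarray
    positive: object = 1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError(
                f"feature matrix has {len(self.X)} rows but label vector has {len(self.y)}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X.iloc[idx].reset_index(drop=True), self.y[idx], self.positive)

    def select_columns(self, mask: "FeatureMask") -> "FeatureTable":
        cols = [name for name, bit in zip(self.X.columns, mask.bits) if bit]
        return FeatureTable(self.X[cols].copy(), self.y.copy(), self.positive)

    def to_csv(self, path, label_name: str = "num") -> None:
        """Write as plain-decimal CSV with the label as the last column."""
        df = self.X.copy()
        df[label_name] = self.y
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, label_name: str = "num", positive: object = 1) -> "FeatureTable":
        df = pd.read_csv(path)
        if label_name not in df.columns:
            raise ValueError(f"label column {label_name!r} not found in {path}")
        y = df[label_name].to_numpy()
        return cls(df.drop(columns=[label_name]), y, positive)


@dataclass
class FeatureMask:
    """Binary inclusion vector over candidate predictors (never the label)."""

    bits: np.ndarray
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0/1")
        if self.feature_names is not None and len(self.feature_names) != self.bits.size:
            raise ValueError("feature_names length must match bits")

    @property
    def selected_count(self) -> int:
        """|R|: the number of set bits."""
        return int(self.bits.sum())

    @property
    def n_candidates(self) -> int:
        return int(self.bits.size)

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def selected_names(self) -> list[str]:
        if self.feature_names is None:
            raise ValueError("mask carries no feature names")
        return [n for n, b in zip(self.feature_names, self.bits) if b]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMask):
            return NotImplemented
        return bool(np.array_equal(self.bits, other.bits))
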