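"""Labeled expression-matrix container and delimited-text I/O.

The universal input throughout the package is a samples-by-features numeric
matrix with one class label per sample.  On disk a matrix is a TSV with a
header row of feature names and one sample per row; labels are a single
column, one label per line, aligned with the matrix rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledMatrix", "read_matrix", "write_matrix", "read_labels", "write_labels"]


@dataclass
class LabeledMatrix:
    """Samples x features values plus class labels.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
    y : ndarray, shape (n_samples,)
        Class labels; any hashable dtype (ints or strings).
    feature_names : list of str, optional
        Defaults to ``f0, f1, ...``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"label count {len(self.y)} does not match sample count {self.X.shape[0]}"
            )
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match number of features")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def class_matrix(self, label) -> np.ndarray:
        """Rows of ``X`` belonging to class ``label``."""
        return self.X[self.y == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.feature_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, y) -> "LabeledMatrix":
        return cls(frame.to_numpy(dtype=float), np.asarray(y), list(map(str, frame.columns)))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples-by-features TSV (header row of feature names)."""
    return pd.read_csv(path, sep="\t")


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> np.ndarray:
    """Read one label per line; integer labels are parsed as ints."""
    raw = Path(path).read_text().split()
    try:
        return np.array([int(v) for v in raw])
    except ValueError:
        return np.array(raw)


def write_labels(y, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(v) for v in np.asarray(y)) + "\n")
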