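"""Labeled correlation matrices and their I/O.

The central data container is :class:`LabeledCorrelationMatrix`: a symmetric
unit-diagonal matrix of Pearson correlations between p observed variables,
together with the variable labels and the sample size n the matrix
summarizes.  All network estimation starts from this object, whether it was
computed from raw scores or read from a published table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EstimationError


def repair_psd(values: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and re-standardize to unit diagonal.

    Resampled or hand-entered correlation matrices can be indefinite or
    numerically singular; the repaired matrix is the closest convenient
    positive-definite correlation matrix (eigenvalue clipping followed by
    rescaling rows/columns so the diagonal is exactly one).
    """
    vals = np.asarray(values, dtype=float)
    w, v = np.linalg.eigh((vals + vals.T) / 2.0)
    if w.min() >= floor:
        return vals
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


@dataclass(frozen=True)
class LabeledCorrelationMatrix:
    """A p x p correlation matrix with item labels and sample size.

    Parameters
    ----------
    labels : tuple of str
        Names of the p variables, in matrix order.
    values : ndarray, shape (p, p)
        Correlations; must be symmetric with unit diagonal.
    n : int or None
        Number of observations the matrix summarizes.  ``None`` marks a
        population (model-implied) matrix; estimation requires a finite n.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    n: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {vals.shape}")
        p = vals.shape[0]
        if len(self.labels) != p:
            raise ValueError(f"{len(self.labels)} labels for a {p}x{p} matrix")
        if len(set(self.labels)) != p:
            raise ValueError("labels must be unique")
        if np.max(np.abs(vals - vals.T)) > 1e-8:
            raise ValueError("correlation matrix is not symmetric")
        if np.max(np.abs(np.diag(vals) - 1.0)) > 1e-8:
            raise ValueError("correlation matrix must have a unit diagonal")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 1.0)
        vals.setflags(write=False)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "values", vals)
        if self.n is not None:
            object.__setattr__(self, "n", int(self.n))
            if self.n <= p:
                warnings.warn(
                    f"sample size n={self.n} does not exceed the number of "
                    f"variables p={p}; estimates will be unstable",
                    stacklevel=2,
                )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def require_n(self) -> int:
        if self.n is None:
            raise EstimationError(
                "this operation needs the sample size; construct the matrix with n"
            )
        return self.n

    def with_n(self, n: int) -> "LabeledCorrelationMatrix":
        return LabeledCorrelationMatrix(self.labels, np.array(self.values), n)

    def repaired(self, floor: float = 1e-6) -> "LabeledCorrelationMatrix":
        """Return a positive-definite version of this matrix (see
        :func:`repair_psd`); a no-op when already well conditioned."""
        w = np.linalg.eigvalsh(self.values)
        if w.min() >= floor:
            return self
        warnings.warn(
            f"correlation matrix is not positive definite (min eigenvalue "
            f"{w.min():.3e}); repairing by eigenvalue clipping",
            stacklevel=2,
        )
        return LabeledCorrelationMatrix(self.labels, repair_psd(self.values, floor), self.n)

    def subset(self, keep: list[str]) -> "LabeledCorrelationMatrix":
        """Submatrix restricted to ``keep`` (in the stored label order)."""
        missing = [k for k in keep if k not in self.labels]
        if missing:
            raise KeyError(f"unknown labels: {missing}")
        idx = [i for i, lab in enumerate(self.labels) if lab in set(keep)]
        sub = np.array(self.values[np.ix_(idx, idx)])
        return LabeledCorrelationMatrix(tuple(self.labels[i] for i in idx), sub, self.n)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    # ---- I/O ------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as CSV with a header row and a leading label column,
        at 15 significant digits (lossless round-trip for float64 inputs
        printed at that precision)."""
        self.to_dataframe().to_csv(path, float_format="%.15g")

    @classmethod
    def from_csv(cls, path, n: int | None = None) -> "LabeledCorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("correlation CSV must have matching row and column labels")
        return cls(tuple(df.columns), df.to_numpy(dtype=float), n)

    @classmethod
    def from_scores(cls, scores, labels=None) -> "LabeledCorrelationMatrix":
        """Pearson correlations of an n x p matrix of raw scores.

        ``scores`` may be a DataFrame (labels from columns) or an array with
        ``labels`` given.  Complete data are required; missing values raise.
        """
        if isinstance(scores, pd.DataFrame):
            labels = tuple(scores.columns)
            arr = scores.to_numpy(dtype=float)
        else:
            arr = np.asarray(scores, dtype=float)
            if labels is None:
                labels = tuple(f"V{i + 1}" for i in range(arr.shape[1]))
        if np.isnan(arr).any():
            raise ValueError("raw scores contain missing values; complete data required")
        if arr.shape[0] < 2:
            raise ValueError("need at least two observations")
        vals = np.corrcoef(arr, rowvar=False)
        return cls(tuple(labels), vals, arr.shape[0])

    @classmethod
    def from_scores_csv(cls, path) -> "LabeledCorrelationMatrix":
        return cls.from_scores(pd.read_csv(path))
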