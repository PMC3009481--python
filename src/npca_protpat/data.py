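"""Core data container, delimited-text I/O and the t-test prefilter.

A preprocessed mass-spectral serum profile is held as an
:class:`IntensityMatrix`: a nonnegative ``(d, m)`` array of ion intensities
with rows indexing biological samples and columns indexing m/z positions
("pseudo-genes"), an optional ±1 label vector (``+1`` = cancer) and the
strictly increasing m/z axis.

Before classification, profiles are usually reduced with a two-sample
t-test keeping the most class-discriminative columns; the conventional
budget is about ``10 * d`` features for ``d`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IntensityMatrix",
    "read_matrix",
    "write_matrix",
    "ttest_prefilter",
    "TTestPrefilter",
]

LABEL_COLUMN = "label"


class ValidationError(ValueError):
    """Input data violates an IntensityMatrix invariant."""


@dataclass
class IntensityMatrix:
    """Nonnegative samples-by-pseudo-genes intensity matrix.

    Parameters
    ----------
    values : ndarray of shape (d, m)
        Nonnegative intensities; rows are biological samples.
    mz : ndarray of shape (m,)
        Strictly increasing mass/charge value per column.
    labels : ndarray of shape (d,), optional
        Class labels in {-1, +1}; +1 denotes the positive (cancer) class.
    feature_ids : sequence of str, optional
        Identifiers per column; defaults to the formatted m/z values.
    """

    values: np.ndarray
    mz: np.ndarray
    labels: np.ndarray | None = None
    feature_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x features matrix")
        if self.mz.shape != (self.values.shape[1],):
            raise ValidationError(
                f"mz length {self.mz.shape} does not match number of "
                f"columns {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative intensity {self.values[r, c]} at row {r}, column {c}"
            )
        if np.any(np.diff(self.mz) <= 0):
            j = int(np.flatnonzero(np.diff(self.mz) <= 0)[0])
            raise ValidationError(
                f"m/z axis not strictly increasing at columns {j}..{j + 1} "
                f"({self.mz[j]} -> {self.mz[j + 1]})"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.values.shape[0],):
                raise ValidationError(
                    f"labels length {self.labels.shape[0] if self.labels.ndim else 0} "
                    f"does not match number of samples {self.values.shape[0]}"
                )
            if not np.all(np.isin(self.labels, (-1, 1))):
                raise ValidationError("labels must take values in {-1, +1}")
            if np.unique(self.labels).size < 2:
                raise ValidationError("both classes must occur at least once")
            self.labels = self.labels.astype(int)
        if self.feature_ids is not None:
            self.feature_ids = [str(f) for f in self.feature_ids]
            if len(self.feature_ids) != self.values.shape[1]:
                raise ValidationError("feature_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: np.ndarray) -> "IntensityMatrix":
        """Return a column subset (order as given in ``indices``)."""
        idx = np.asarray(indices, dtype=int)
        return IntensityMatrix(
            values=self.values[:, idx],
            mz=self.mz[idx],
            labels=None if self.labels is None else self.labels.copy(),
            feature_ids=None
            if self.feature_ids is None
            else [self.feature_ids[i] for i in idx],
        )

    def with_labels(self, labels: np.ndarray) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.mz.copy(), np.asarray(labels))


def read_matrix(path, delimiter: str = ",", labels_path=None) -> IntensityMatrix:
    """Read an intensity matrix from delimited text.

    The first (header) row carries the m/z value of each column.  Labels may
    be stored either in a reserved first column named ``"label"`` (values
    -1/+1) or in a separate single-column file passed as ``labels_path``.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    labels = None
    if df.columns[0] == LABEL_COLUMN:
        labels = df[LABEL_COLUMN].to_numpy()
        df = df.drop(columns=[LABEL_COLUMN])
    try:
        mz = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValidationError(
            f"header of {path} must contain numeric m/z values: {exc}"
        ) from exc
    if labels_path is not None:
        labels = np.loadtxt(labels_path, dtype=float).reshape(-1)
    return IntensityMatrix(df.to_numpy(dtype=float), mz, labels)


def write_matrix(data: IntensityMatrix, path, delimiter: str = ",",
                 labels_path=None) -> None:
    """Write ``data`` in the format accepted by :func:`read_matrix`.

    Labels, when present, go into the reserved ``"label"`` first column
    unless ``labels_path`` is given, in which case they are written there
    as a single column instead.
    """
    df = pd.DataFrame(data.values, columns=[repr(float(v)) for v in data.mz])
    if data.labels is not None and labels_path is None:
        df.insert(0, LABEL_COLUMN, data.labels)
    df.to_csv(path, sep=delimiter, index=False)
    if data.labels is not None and labels_path is not None:
        np.savetxt(labels_path, data.labels, fmt="%d")


def _welch_pvalues(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    a = values[labels == 1]
    b = values[labels == -1]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("each class needs >= 2 samples for the t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    # constant-in-both-classes columns yield NaN; rank them last
    return np.where(np.isfinite(p), p, 1.0)


def ttest_prefilter(data: IntensityMatrix, n_keep="auto"):
    """Keep the columns most significant under a Welch two-sample t-test.

    ``n_keep="auto"`` keeps ``min(m, 10 * d)`` columns.  Returns the column
    subset (original column order preserved) and the selected indices into
    the input matrix.  Ties in the p-value are broken toward the smaller
    column index.
    """
    if data.labels is None:
        raise ValidationError("ttest_prefilter requires labels")
    m = data.n_features
    if n_keep == "auto":
        n_keep = min(m, 10 * data.n_samples)
    n_keep = int(n_keep)
    if not 1 <= n_keep <= m:
        raise ValidationError(f"n_keep={n_keep} outside [1, m={m}]")
    p = _welch_pvalues(data.values, data.labels)
    # stable argsort on p => ties broken by smaller column index
    order = np.argsort(p, kind="stable")[:n_keep]
    selected = np.sort(order)
    return data.select_columns(selected), selected


class TTestPrefilter(TransformerMixin, BaseEstimator):
    """Welch two-sample t-test feature selector.

    scikit-learn transformer wrapping :func:`ttest_prefilter`: keeps the
    ``n_keep`` columns with the smallest two-sided p-values (``"auto"`` →
    ``min(m, 10 * d)``).

    Attributes
    ----------
    support_ : ndarray of int
        Selected column indices, in increasing order.
    pvalues_ : ndarray of shape (m,)
        Welch p-value per input column.
    """

    def __init__(self, n_keep="auto"):
        self.n_keep = n_keep

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        m = X.shape[1]
        n_keep = min(m, 10 * X.shape[0]) if self.n_keep == "auto" else int(self.n_keep)
        if not 1 <= n_keep <= m:
            raise ValidationError(f"n_keep={n_keep} outside [1, m={m}]")
        self.pvalues_ = _welch_pvalues(X, y)
        order = np.argsort(self.pvalues_, kind="stable")[:n_keep]
        self.support_ = np.sort(order)
        self.n_features_in_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        return X[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_.copy()
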