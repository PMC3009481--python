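"""Filter-wrapper biomarker capture.

Candidate pseudo-genes are first *filtered* by a two-sample Bayesian
t-test: per column, the Bayes factor BF01 of the equal-means null against
an unequal-means alternative is computed in closed form, and the columns
with the smallest BF01 (strongest differential evidence) form the
candidate set ``S_b`` (at least the top 1%, ``|S_b| = ceil(m * 0.01)``).
Nonnegative PCA then supplies a second, variance-based ranking: after the
decomposition ``X^T ~ P U^T``, pseudo-gene ``i`` receives the coefficient

    tau_i = sum_j w_j * P_ij,

with ``w_j`` the share of total score variance explained by component
``j``.  Finally a *wrapper* runs greedy forward selection over ``S_b``:
at each step the candidate maximizing SVM leave-one-out (LOOCV) accuracy
joins the panel, ties broken by larger ``|tau|`` then smaller column
index, and selection stops when no candidate strictly improves accuracy
(or it reaches 100%).  The wrapper SVM sees raw intensity columns, so each
selected biomarker's standalone LOOCV ratio is directly interpretable.

Bayes factor
------------
With pooled two-sample t statistic ``t``, degrees of freedom
``nu = n1 + n2 - 2`` and effective size ``N_e = n1 n2 / (n1 + n2)``, a
zero-centered g-prior (unit information, g = 1) on the standardized mean
difference gives

    BF01 = sqrt(1 + g N_e) * [ (1 + t^2 / (nu (1 + g N_e)))
                               / (1 + t^2 / nu) ] ** ((nu + 1) / 2).

BF01 exceeds 1 at t = 0, is symmetric in the two groups and strictly
decreasing in |t|; differential pseudo-genes therefore have very small
BF01 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fast_svm import loocv_predict
from .data import IntensityMatrix
from .npca import NPCAModel, npca_fit

__all__ = [
    "bayes_factor",
    "bayes_factor_table",
    "BayesFactorResult",
    "build_candidates",
    "npca_rank",
    "loocv_accuracy",
    "greedy_forward_select",
    "BiomarkerResult",
    "discover_biomarkers",
    "GreedyBiomarkerSelector",
]


def _pooled_t(a, b):
    n1, n2 = a.size, b.size
    nu = n1 + n2 - 2
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 = ss / nu
    ne = n1 * n2 / (n1 + n2)
    if sp2 == 0.0:
        if a.mean() == b.mean():
            raise ValueError("degenerate groups: zero variance and equal means")
        return np.inf, nu, ne
    t = (a.mean() - b.mean()) / np.sqrt(sp2 / ne)
    return t, nu, ne


def bayes_factor(group_a, group_b, g: float = 1.0) -> float:
    """Closed-form two-sample Bayes factor BF01 (null = equal means)."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    t, nu, ne = _pooled_t(a, b)
    return bf01_from_t(t, nu, ne, g=g)


def bf01_from_t(t: float, nu: float, ne: float, g: float = 1.0) -> float:
    """BF01 as a function of the pooled t statistic (see module docstring)."""
    shrink = 1.0 + g * ne
    if not np.isfinite(t):
        return float(shrink ** (-nu / 2.0))
    # computed in log space: the ratio underflows for |t| of a few dozen
    log_bf = 0.5 * np.log(shrink) + 0.5 * (nu + 1.0) * (
        np.log1p(t * t / (nu * shrink)) - np.log1p(t * t / nu)
    )
    return float(np.exp(log_bf))


@dataclass
class BayesFactorResult:
    """Per-pseudo-gene Bayesian t-test results."""

    index: np.ndarray          # column index into the input matrix
    mz: np.ndarray
    bayes_factor_01: np.ndarray
    t_statistic: np.ndarray


def bayes_factor_table(X: IntensityMatrix, g: float = 1.0) -> BayesFactorResult:
    """Bayesian two-sample t-test of every pseudo-gene (vectorized)."""
    if X.labels is None:
        raise ValueError("bayes_factor_table requires labels")
    a = X.values[X.labels == 1]
    b = X.values[X.labels == -1]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs >= 2 samples")
    n1, n2 = a.shape[0], b.shape[0]
    nu = n1 + n2 - 2
    ne = n1 * n2 / (n1 + n2)
    ss = ((a - a.mean(0)) ** 2).sum(0) + ((b - b.mean(0)) ** 2).sum(0)
    sp2 = ss / nu
    diff = a.mean(0) - b.mean(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 / ne)
    t = np.where(sp2 == 0, np.where(diff == 0, 0.0, np.inf), t)
    bf = np.array([bf01_from_t(ti, nu, ne, g=g) for ti in t])
    return BayesFactorResult(index=np.arange(X.n_features), mz=X.mz.copy(),
                             bayes_factor_01=bf, t_statistic=t)


def build_candidates(X: IntensityMatrix, size="auto"):
    """Indices of the ``size`` smallest-BF01 pseudo-genes, ascending BF01.

    ``"auto"`` keeps the top 1%: ``ceil(m * 0.01)``.
    """
    m = X.n_features
    size = int(np.ceil(m * 0.01)) if size == "auto" else int(size)
    if not 1 <= size <= m:
        raise ValueError(f"size={size} outside [1, m={m}]")
    table = bayes_factor_table(X)
    order = np.argsort(table.bayes_factor_01, kind="stable")
    return order[:size]


def npca_rank(X: IntensityMatrix, model: NPCAModel) -> np.ndarray:
    """NPCA contribution coefficient per pseudo-gene: tau = P w."""
    P = model.P
    m = X.n_features if isinstance(X, IntensityMatrix) else np.asarray(X).shape[1]
    if P.shape[0] != m:
        raise ValueError(
            f"model has loadings for {P.shape[0]} pseudo-genes, X has {m}"
        )
    return P @ model.w


def _loocv_predictions(values, y, kernel, C, gamma):
    return loocv_predict(values, y, kernel=kernel, C=C, gamma=gamma)


def loocv_accuracy(X_subset, y, kernel="linear", C=1.0, gamma="auto") -> float:
    """SVM leave-one-out accuracy (%) on the given feature columns."""
    values = np.asarray(X_subset, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    y = np.asarray(y).astype(int).ravel()
    if values.shape[0] != y.size:
        raise ValueError("X_subset and y length mismatch")
    counts = [np.sum(y == c) for c in np.unique(y)]
    if len(counts) < 2 or min(counts) < 2:
        raise ValueError("LOOCV needs >= 2 samples in each class")
    preds = _loocv_predictions(values, y, kernel, C, gamma)
    return 100.0 * float(np.mean(preds == y))


@dataclass
class BiomarkerResult:
    """Ordered biomarker panel with its cumulative LOOCV accuracy trace."""

    selected: list[dict]            # index, mz, bayes_factor, tau, cumulative_accuracy
    final_accuracy: float
    final_sensitivity: float
    final_specificity: float
    kernel: str
    candidate_set_size: int

    @property
    def indices(self):
        return [rec["index"] for rec in self.selected]

    def to_dict(self):
        return {
            "selected": self.selected,
            "final_accuracy": self.final_accuracy,
            "final_sensitivity": self.final_sensitivity,
            "final_specificity": self.final_specificity,
            "kernel": self.kernel,
            "candidate_set_size": self.candidate_set_size,
        }


def greedy_forward_select(X: IntensityMatrix, S_b, tau, kernel="linear",
                          C=1.0, gamma="auto", bayes_factors=None) -> BiomarkerResult:
    """Greedy forward selection over ``S_b`` under SVM-LOOCV accuracy.

    Each accepted step must strictly improve accuracy; ties at a step are
    broken by larger ``|tau|``, then smaller column index.  ``tau`` and the
    optional ``bayes_factors`` are indexed like the columns of ``X``.
    """
    if X.labels is None:
        raise ValueError("greedy_forward_select requires labels")
    S_b = [int(i) for i in S_b]
    if not S_b:
        raise ValueError("empty candidate set S_b")
    tau = np.asarray(tau, dtype=float)
    y = X.labels
    remaining = list(S_b)
    selected: list[int] = []
    trace: list[float] = []
    records: list[dict] = []
    best_acc = -np.inf
    while remaining:
        accs = np.array([
            loocv_accuracy(X.values[:, selected + [c]], y, kernel, C, gamma)
            for c in remaining
        ])
        top = accs.max()
        if top <= best_acc + 1e-9:
            break
        tied = [c for c, a in zip(remaining, accs) if a >= top - 1e-9]
        tied.sort(key=lambda c: (-abs(tau[c]), c))
        choice = tied[0]
        selected.append(choice)
        remaining.remove(choice)
        best_acc = top
        trace.append(top)
        records.append({
            "index": choice,
            "mz": float(X.mz[choice]),
            "bayes_factor": None if bayes_factors is None
            else float(bayes_factors[choice]),
            "tau": float(tau[choice]),
            "cumulative_accuracy": float(top),
        })
        if top >= 100.0 - 1e-9:
            break
    preds = _loocv_predictions(X.values[:, selected], y, kernel, C, gamma)
    from .classify import confusion_metrics
    rate, sens, spec = confusion_metrics(y, preds)
    return BiomarkerResult(selected=records, final_accuracy=rate,
                           final_sensitivity=sens, final_specificity=spec,
                           kernel=kernel, candidate_set_size=len(S_b))


def discover_biomarkers(X: IntensityMatrix, candidates="auto", kernel="linear",
                        alpha=10.0, C=1.0, gamma="auto", n_components="auto",
                        solver="hybrid", seed=0) -> BiomarkerResult:
    """Full filter-wrapper pipeline on a labeled IntensityMatrix.

    Bayes-factor filter -> candidate set ``S_b`` -> NPCA tau ranking fit
    once on the candidate submatrix (alpha = 10 by default) -> greedy
    SVM-LOOCV forward selection.
    """
    S_b = build_candidates(X, size=candidates)
    table = bayes_factor_table(X)
    sub = X.select_columns(np.sort(S_b))
    k = sub.n_samples - 1 if n_components == "auto" else int(n_components)
    model = npca_fit(sub.values, k=k, alpha=alpha, solver=solver, seed=seed)
    tau_sub = model.P @ model.w
    tau = np.zeros(X.n_features)
    tau[np.sort(S_b)] = tau_sub
    return greedy_forward_select(X, S_b, tau, kernel=kernel, C=C, gamma=gamma,
                                 bayes_factors=table.bayes_factor_01)


class GreedyBiomarkerSelector:
    """scikit-learn-style wrapper around :func:`discover_biomarkers`.

    ``fit(X, y)`` accepts a plain array plus ±1 labels; the selected column
    indices are exposed as ``selected_`` and the full result as
    ``result_``.  ``transform`` returns the selected columns.
    """

    def __init__(self, candidates="auto", kernel="linear", alpha=10.0, C=1.0,
                 gamma="auto", solver="hybrid", random_state=0):
        self.candidates = candidates
        self.kernel = kernel
        self.alpha = alpha
        self.C = C
        self.gamma = gamma
        self.solver = solver
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "candidates", "kernel", "alpha", "C", "gamma", "solver", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        data = IntensityMatrix(X, np.arange(1.0, X.shape[1] + 1.0),
                               np.asarray(y))
        self.result_ = discover_biomarkers(
            data, candidates=self.candidates, kernel=self.kernel,
            alpha=self.alpha, C=self.C, gamma=self.gamma, solver=self.solver,
            seed=self.random_state,
        )
        self.selected_ = np.array(self.result_.indices, dtype=int)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
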