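"""Nonnegative principal component analysis (NPCA).

Classic PCA extracts global variance directions whose loadings mix positive
and negative weights; the partial cancellations hide local features, which
for mass-spectral profiles are exactly the class-discriminative ones.  NPCA
removes the cancellations by constraining the principal-component matrix to
be nonnegative, maximizing the penalized variance objective

    J(U, alpha) = 1/2 ||U^T X||_F^2 - alpha ||U^T U - I||_F^2,   U >= 0,

over ``U`` of shape ``(d, k)`` for data ``X`` of shape ``(d, m)`` whose
columns (pseudo-gene profiles, points in sample space R^d) are the
observations.  The penalty ``alpha >= 0`` controls how close ``U`` stays to
column-orthonormality.  Rows of the optimum ``U`` are *meta-samples* — the
locality-preserving low-dimensional representation of each biological
sample — and ``P = X^T U`` holds the per-pseudo-gene loadings, so that
``X^T ~ P U^T``.

Two solvers are provided:

* ``"gradient"`` — projected normalized-gradient ascent,
  ``U <- max(U + eta * grad J / ||grad J||, 0)`` with fixed step
  ``eta = 1`` (no trust-region search) and termination at
  ``||grad J|| <= tol``; the best-objective iterate seen is returned
  because the fixed normalized step is not monotone.
* ``"coordinate"`` — exact per-entry maximization: J restricted to a single
  entry ``u_sl`` is a quartic with leading coefficient ``-alpha``, so each
  update solves a cubic and takes the nonnegative argmax; the objective is
  non-decreasing at every update.  Requires ``alpha > 0``.

``"hybrid"`` (the estimator default) runs the gradient phase then polishes
with coordinate sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import IntensityMatrix

__all__ = [
    "NPCAModel",
    "objective",
    "gradient",
    "coordinate_update",
    "npca_fit",
    "variance_explained",
    "save_model",
    "load_model",
    "NonnegativePCA",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, IntensityMatrix):
        X = X.values
    return np.asarray(X, dtype=float)


def _check_pair(U, X):
    U = np.asarray(U, dtype=float)
    X = _as_array(X)
    if U.ndim != 2 or X.ndim != 2:
        raise ValueError("U and X must be 2-D")
    if U.shape[0] != X.shape[0]:
        raise ValueError(
            f"row mismatch: U has {U.shape[0]} rows, X has {X.shape[0]}"
        )
    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite entries in U or X")
    return U, X


def objective(U, X, alpha: float) -> float:
    """Penalized variance objective J(U, alpha); higher is better."""
    U, X = _check_pair(U, X)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    B = U.T @ U
    pen = B - np.eye(U.shape[1])
    return 0.5 * np.linalg.norm(U.T @ X) ** 2 - alpha * np.linalg.norm(pen) ** 2


def gradient(U, X, alpha: float) -> np.ndarray:
    """Analytic gradient of :func:`objective` with respect to U (d x k)."""
    U, X = _check_pair(U, X)
    B = U.T @ U
    return X @ (X.T @ U) + 4.0 * alpha * (U - U @ B)


def _entry_coefficients(u_old, Ass, Gsl, Bl, Us_row, row_sq, l, alpha):
    """Quartic coefficients of J restricted to one entry.

    J(u) = -alpha * u**4 + c2 * u**2 + c1 * u + const, where the constant
    (c0 = -k*alpha plus terms free of u) is irrelevant to the argmax.
    """
    r = Bl[l] - u_old * u_old          # sum over other rows of column l, squared
    q = row_sq - u_old * u_old         # sum over other columns of row s, squared
    c2 = 0.5 * Ass - 2.0 * alpha * (r - 1.0) - 2.0 * alpha * q
    cross = float(Us_row @ Bl) - u_old * Bl[l] - u_old * q
    c1 = (Gsl - Ass * u_old) - 4.0 * alpha * cross
    return c2, c1


def _depressed_cubic_roots(p, q):
    """Real roots of u^3 + p*u + q = 0 (closed form; no u^2 term arises
    because the per-entry quartic has no cubic term)."""
    disc = -4.0 * p**3 - 27.0 * q * q
    if disc > 0.0:  # three distinct real roots: trigonometric form
        rho = 2.0 * np.sqrt(-p / 3.0)
        theta = np.arccos(np.clip(3.0 * q / (p * rho), -1.0, 1.0))
        return [rho * np.cos(theta / 3.0 - 2.0 * np.pi * i / 3.0) for i in range(3)]
    # one real root: Cardano
    half_q = -q / 2.0
    rad = np.sqrt(max(half_q * half_q + (p / 3.0) ** 3, 0.0))
    return [np.cbrt(half_q + rad) + np.cbrt(half_q - rad)]


def _quartic_argmax(alpha, c2, c1):
    """Nonnegative argmax of -alpha*u^4 + c2*u^2 + c1*u (alpha > 0).

    Stationary points solve -4a u^3 + 2 c2 u + c1 = 0, i.e. the depressed
    cubic u^3 - (c2 / 2a) u - (c1 / 4a) = 0.
    """
    best_u, best_v = 0.0, 0.0
    for r in _depressed_cubic_roots(-c2 / (2.0 * alpha), -c1 / (4.0 * alpha)):
        if r > 0.0:
            v = (-alpha * r * r + c2) * r * r + c1 * r
            if v > best_v:
                best_u, best_v = float(r), v
    return best_u


def coordinate_update(U, X, alpha: float, s: int, l: int) -> float:
    """Exact constrained maximizer of J over the single entry ``u_sl``.

    All other entries held fixed; returns the new (nonnegative) value.
    Substituting it never decreases the objective.
    """
    U, X = _check_pair(U, X)
    if alpha <= 0:
        raise ValueError("coordinate update requires alpha > 0 "
                         "(the per-entry maximum is otherwise unbounded)")
    d, k = U.shape
    if not (0 <= s < d and 0 <= l < k):
        raise IndexError(f"entry ({s}, {l}) out of range for {U.shape}")
    a_s = X[s] @ X.T                    # row s of X X^T
    u_old = U[s, l]
    Bl = U[:, l] @ U                    # row l of U^T U, shape (k,)
    c2, c1 = _entry_coefficients(
        u_old, a_s[s], float(a_s @ U[:, l]), Bl, U[s], float(U[s] @ U[s]), l, alpha
    )
    return _quartic_argmax(alpha, c2, c1)


def _initial_U(d, k, seed):
    rng = np.random.default_rng(seed)
    U = np.abs(rng.standard_normal((d, k)))
    return U * (np.sqrt(k) / np.linalg.norm(U))


def _objective_from_parts(U, G_data, B, alpha):
    # G_data = (X X^T) U ; avoids reforming U^T X
    pen = B - np.eye(B.shape[1])
    return 0.5 * float(np.sum(U * G_data)) - alpha * float(np.sum(pen * pen))


def _gradient_solve(X, U, alpha, max_iter, tol, trace):
    A = X @ X.T
    best_U = U.copy()
    G_data = A @ U
    B = U.T @ U
    best_J = _objective_from_parts(U, G_data, B, alpha)
    trace.append(best_J)
    gnorm = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        G = G_data + 4.0 * alpha * (U - U @ B)
        gnorm = float(np.linalg.norm(G))
        if gnorm <= tol:
            n_iter -= 1
            break
        U = np.maximum(U + G / gnorm, 0.0)
        G_data = A @ U
        B = U.T @ U
        J = _objective_from_parts(U, G_data, B, alpha)
        trace.append(J)
        if J > best_J:
            best_J = J
            best_U = U.copy()
    converged = gnorm <= tol
    return best_U, converged, n_iter, gnorm


def _coordinate_solve(X, U, alpha, max_iter, tol, trace, rtol=1e-8):
    d, k = U.shape
    A = X @ X.T
    U = U.copy()
    G_data = A @ U
    B = U.T @ U
    row_sq = np.einsum("ij,ij->i", U, U)
    J = _objective_from_parts(U, G_data, B, alpha)
    trace.append(J)
    n_sweep = 0
    for n_sweep in range(1, max_iter + 1):
        for s in range(d):
            for l in range(k):
                u_old = U[s, l]
                c2, c1 = _entry_coefficients(
                    u_old, A[s, s], G_data[s, l], B[l], U[s], row_sq[s], l, alpha
                )
                u_new = _quartic_argmax(alpha, c2, c1)
                delta = u_new - u_old
                if delta == 0.0:
                    continue
                U[s, l] = u_new
                G_data[:, l] += A[:, s] * delta
                B[l, :] += delta * U[s]
                B[l, l] += delta * u_old
                B[:, l] = B[l, :]
                row_sq[s] += u_new * u_new - u_old * u_old
        J_new = _objective_from_parts(U, G_data, B, alpha)
        trace.append(J_new)
        if abs(J_new - J) <= rtol * max(1.0, abs(J)):
            J = J_new
            break
        J = J_new
    G = G_data + 4.0 * alpha * (U - U @ B)
    gnorm = float(np.linalg.norm(G))
    return U, gnorm <= max(tol, 1e-3) or n_sweep < max_iter, n_sweep, gnorm


@dataclass
class NPCAModel:
    """Result of an NPCA fit (see module docstring for conventions)."""

    U: np.ndarray                # (d, k) nonnegative PC / meta-sample matrix
    P: np.ndarray                # (m, k) pseudo-gene loadings, P = X^T U
    alpha: float
    k: int
    converged: bool
    n_iter: int
    objective_trace: np.ndarray
    grad_norm_final: float
    w: np.ndarray                # variance-explained ratios, sums to 1
    seed: int

    def meta_samples(self) -> np.ndarray:
        """Rows of U: one nonnegative k-vector per biological sample."""
        return self.U


def npca_fit(X, k: int, alpha="auto", solver: str = "gradient",
             init: np.ndarray | None = None, max_iter: int = 2000,
             tol: float = 1e-4, seed: int = 0, center: bool = False) -> NPCAModel:
    """Fit nonnegative PCA to a nonnegative matrix ``X`` (d samples x m).

    Parameters
    ----------
    k : int
        Number of nonnegative components, ``1 <= k <= d``.
    alpha : float or "auto"
        Orthonormality penalty (>= 0; > 0 required by the coordinate
        solver).  "auto" applies the alpha-proportional-to-d rule as
        ``alpha = 5 * d``, appropriate for unsupervised factor recovery;
        supervised pipelines conventionally fix ``alpha = 10``.
    solver : {"gradient", "coordinate", "hybrid"}
        See module docstring.
    init : ndarray of shape (d, k), optional
        Warm start; defaults to seeded |N(0, 1)| scaled to ||U||_F = sqrt(k).
    tol : float
        Gradient-norm termination threshold (default 1e-4).
    center : bool
        Experimental: subtract column means and clip at 0 before fitting.
    """
    Xa = _as_array(X)
    if Xa.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.any(Xa < 0):
        raise ValueError("X must be entrywise nonnegative")
    d, m = Xa.shape
    if not 1 <= k <= d:
        raise ValueError(f"k={k} must satisfy 1 <= k <= d={d}")
    if alpha == "auto":
        alpha = 5.0 * d
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if solver not in ("gradient", "coordinate", "hybrid"):
        raise ValueError(f"unknown solver {solver!r}")
    if solver in ("coordinate", "hybrid") and alpha == 0:
        raise ValueError("coordinate solver requires alpha > 0")
    if center:
        Xa = np.maximum(Xa - Xa.mean(axis=0), 0.0)
    if init is not None:
        U0 = np.asarray(init, dtype=float)
        if U0.shape != (d, k):
            raise ValueError(f"init has shape {U0.shape}, expected {(d, k)}")
        if np.any(U0 < 0):
            raise ValueError("init must be nonnegative")
        U0 = U0.copy()
    else:
        U0 = _initial_U(d, k, seed)

    trace: list[float] = []
    if solver == "gradient":
        U, converged, n_iter, gnorm = _gradient_solve(Xa, U0, alpha, max_iter, tol, trace)
    elif solver == "coordinate":
        U, converged, n_iter, gnorm = _coordinate_solve(Xa, U0, alpha, max_iter, tol, trace)
    else:
        # short normalized-ascent phase to land in a good basin, then
        # exact coordinate sweeps to polish
        U, converged, n_g, gnorm = _gradient_solve(Xa, U0, alpha,
                                                   min(max_iter, 200), tol, trace)
        trace.pop()  # coordinate phase re-records its starting objective
        U, converged, n_c, gnorm = _coordinate_solve(Xa, U, alpha, max_iter, tol, trace)
        n_iter = n_g + n_c

    P = Xa.T @ U
    try:
        w = _variance_ratios(P)
    except ValueError:
        # all score columns constant (degenerate X); fall back to uniform
        w = np.full(k, 1.0 / k)
    return NPCAModel(U=U, P=P, alpha=float(alpha), k=int(k), converged=bool(converged),
                     n_iter=int(n_iter), objective_trace=np.asarray(trace),
                     grad_norm_final=float(gnorm), w=w, seed=int(seed))


def _variance_ratios(P: np.ndarray) -> np.ndarray:
    var = P.var(axis=0)
    total = var.sum()
    if total <= 0:
        raise ValueError("all score columns are constant; "
                         "variance-explained ratios undefined")
    return var / total


def variance_explained(model: NPCAModel, X) -> np.ndarray:
    """Per-component share of total score variance, w_j; sums to 1."""
    Xa = _as_array(X)
    if Xa.shape[0] != model.U.shape[0]:
        raise ValueError("X does not match the fitted model's sample count")
    return _variance_ratios(Xa.T @ model.U)


def save_model(model: NPCAModel, path) -> None:
    """Serialize a fitted model to a single versioned JSON archive."""
    payload = {"format": "npca-protpat-model", "version": 1}
    for key, val in asdict(model).items():
        payload[key] = val.tolist() if isinstance(val, np.ndarray) else val
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> NPCAModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "npca-protpat-model":
        raise ValueError(f"{path} is not an NPCA model archive")
    kwargs = {k: v for k, v in payload.items() if k not in ("format", "version")}
    for key in ("U", "P", "objective_trace", "w"):
        kwargs[key] = np.asarray(kwargs[key], dtype=float)
    return NPCAModel(**kwargs)


class NonnegativePCA(TransformerMixin, BaseEstimator):
    """Nonnegative PCA as a scikit-learn transformer.

    ``fit`` learns the nonnegative PC matrix on the training samples;
    ``fit_transform`` returns their meta-samples (rows of ``U_``), and
    ``transform`` embeds unseen samples inductively by nonnegative least
    squares against the learned loadings ``P``:
    ``u' = argmin_{u >= 0} ||x' - P u||_2``.

    Parameters
    ----------
    n_components : int or "auto"
        k; "auto" uses d - 1 for d training samples.
    alpha : float
        Orthonormality penalty (default 10, the usual experimental value).
    sparseness : float or None
        If set, project each meta-sample (row of U) to this Hoyer
        sparseness after fitting.
    solver : {"hybrid", "gradient", "coordinate"}

    Attributes
    ----------
    U_ : ndarray (d, k)           meta-samples of the training data
    loadings_ : ndarray (m, k)    P = X^T U
    explained_variance_ratio_ : ndarray (k,)
    model_ : NPCAModel
    """

    def __init__(self, n_components="auto", alpha=10.0, sparseness=None,
                 sparse_axis="rows", solver="hybrid", max_iter=2000,
                 tol=1e-4, center=False, random_state=0):
        self.n_components = n_components
        self.alpha = alpha
        self.sparseness = sparseness
        self.sparse_axis = sparse_axis
        self.solver = solver
        self.max_iter = max_iter
        self.tol = tol
        self.center = center
        self.random_state = random_state

    def _resolve_k(self, d):
        return d - 1 if self.n_components == "auto" else int(self.n_components)

    def fit(self, X, y=None, init=None):
        Xa = _as_array(X)
        k = self._resolve_k(Xa.shape[0])
        model = npca_fit(Xa, k=k, alpha=self.alpha, solver=self.solver,
                         init=init, max_iter=self.max_iter, tol=self.tol,
                         seed=self.random_state, center=self.center)
        if self.sparseness is not None:
            from .sparse_coding import sparsify_meta_samples
            model = sparsify_meta_samples(model, self.sparseness,
                                          axis=self.sparse_axis, X=Xa)
        self.model_ = model
        self.U_ = model.U
        self.loadings_ = model.P
        self.explained_variance_ratio_ = model.w
        self.n_iter_ = model.n_iter
        self.converged_ = model.converged
        self.n_features_in_ = Xa.shape[1]
        return self

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).U_.copy()

    def transform(self, X):
        check_is_fitted(self, "model_")
        Xa = _as_array(X)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} columns, expected {self.n_features_in_}"
            )
        out = np.empty((Xa.shape[0], self.model_.k))
        for i, row in enumerate(Xa):
            out[i], _ = nnls(self.loadings_, row)
        if self.sparseness is not None and out.shape[0]:
            from .sparse_coding import project_to_sparseness
            for i in range(out.shape[0]):
                if out[i].any():
                    out[i] = project_to_sparseness(out[i], self.sparseness)
        return out
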