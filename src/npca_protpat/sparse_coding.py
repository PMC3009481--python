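"""Hoyer sparseness measurement and projection.

The sparseness of a nonnegative vector ``v`` of length ``n >= 2`` is the
norm ratio

    delta(v) = (sqrt(n) - ||v||_1 / ||v||_2) / (sqrt(n) - 1),

which is 1 when exactly one entry is positive and 0 when all entries are
equal, and is invariant to positive scaling.  Projection to a target
sparseness finds the nearest nonnegative vector (in the L1/L2 sense) with
the same L2 norm and the L1 norm that realizes the target: geometrically
the nonnegative intersection of the L1 hyperplane and the L2 hypersphere.
The alternating algorithm (shift onto the hyperplane, rescale onto the
sphere, clip negatives, repeat) is Hoyer's.

Meta-samples carry concentrated, locality-preserving structure when they
are sparse; a mild target (delta <= 0.5, typically 0.20) is applied to the
rows — or, under the alternative reading, the columns — of the nonnegative
PC matrix after fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .npca import NPCAModel, _variance_ratios

__all__ = [
    "sparseness",
    "target_l1",
    "project_to_sparseness",
    "sparsify_meta_samples",
]


def _check_vector(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.any(v < 0):
        raise ValueError("vector must be nonnegative")
    if not v.any():
        raise ValueError("sparseness undefined for the zero vector")
    return v


def sparseness(v) -> float:
    """Hoyer sparseness of a nonnegative vector, in [0, 1]."""
    v = _check_vector(v)
    n = v.size
    rt = np.sqrt(n)
    raw = (rt - v.sum() / np.linalg.norm(v)) / (rt - 1.0)
    # the extreme cases (one-hot -> 1, constant -> 0) are analytic
    # identities; snap the few-ulp sqrt roundoff onto them and keep the
    # result in [0, 1]
    if raw < 1e-12:
        return 0.0
    if raw > 1.0 - 1e-12:
        return 1.0
    return float(raw)


def target_l1(l2: float, n: int, delta: float) -> float:
    """L1 norm a length-``n`` vector of L2 norm ``l2`` needs for sparseness ``delta``."""
    if l2 <= 0:
        raise ValueError("l2 must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    rt = np.sqrt(n)
    return float(l2 * (rt - delta * (rt - 1.0)))


def project_to_sparseness(u, delta: float) -> np.ndarray:
    """Project ``u`` to Hoyer sparseness ``delta`` preserving its L2 norm.

    Implements the alternating hyperplane/hypersphere projection with
    clipping of negatives; raises if it fails to land in the nonnegative
    orthant within ``n + 1`` rounds (does not occur for valid inputs).
    """
    u = _check_vector(u)
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    n = u.size
    l2 = float(np.linalg.norm(u))
    if delta == 0.0:
        return np.full(n, l2 / np.sqrt(n))
    s1 = target_l1(l2, n, delta)
    v = u + (s1 - u.sum()) / n
    zero = np.zeros(n, dtype=bool)
    for _ in range(n + 1):
        mid = np.where(zero, 0.0, s1 / max(n - zero.sum(), 1))
        w = v - mid
        # largest a >= 0 with ||mid + a w||_2 = l2
        aa = float(w @ w)
        bb = 2.0 * float(mid @ w)
        cc = float(mid @ mid) - l2 * l2
        if aa <= 1e-300:
            v = mid
        else:
            disc = max(bb * bb - 4.0 * aa * cc, 0.0)
            a = (-bb + np.sqrt(disc)) / (2.0 * aa)
            v = mid + a * w
        if np.all(v >= 0):
            return v
        zero |= v < 0
        v[zero] = 0.0
        active = n - zero.sum()
        if active == 0:
            break
        v[~zero] -= (v.sum() - s1) / active
    raise RuntimeError(
        f"sparseness projection did not converge (n={n}, delta={delta}, "
        f"zeroed={int(zero.sum())})"
    )


def sparsify_meta_samples(model: NPCAModel, delta: float, axis: str = "rows",
                          X=None) -> NPCAModel:
    """Project every meta-sample (row of U) — or loading vector (column) —
    of a fitted model to sparseness ``delta``.

    Per-vector L2 norms and nonnegativity are preserved; zero vectors are
    skipped with a warning.  ``X`` (the training matrix) is needed to
    recompute the loadings ``P = X^T U`` and the variance-explained ratios;
    without it the stale ``P`` is kept and a warning issued.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    U = model.U.copy()
    vectors = U if axis == "rows" else U.T
    for i, vec in enumerate(vectors):
        if not vec.any():
            warnings.warn(f"skipping zero {axis[:-1]} {i} in sparse coding")
            continue
        vectors[i] = project_to_sparseness(vec, delta)
    if X is not None:
        from .npca import _as_array
        P = _as_array(X).T @ U
        w = _variance_ratios(P)
    else:
        warnings.warn("X not supplied; keeping loadings P from the un-sparsified fit")
        P, w = model.P, model.w
    return replace(model, U=U, P=P, w=w)
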