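"""Low-overhead soft-margin SVM fit/predict for tiny problems.

The greedy biomarker wrapper evaluates SVM leave-one-out accuracy for
hundreds of candidate feature subsets, each fit involving a few dozen
samples and 1-5 features; estimator-level overhead dominates the actual
quadratic-programming time there.  This module calls scikit-learn's
bundled libsvm bindings directly (same solver, same solution as
:class:`sklearn.svm.SVC`) and falls back to ``SVC`` when the low-level
interface is unavailable.  Agreement with ``SVC`` is covered by tests.
"""

from __future__ import annotations

import numpy as np

try:  # scikit-learn's libsvm bindings (private but stable in practice)
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None

from sklearn.svm import SVC


def _resolve_gamma(gamma, n_features):
    return 1.0 / n_features if gamma == "auto" else float(gamma)


def fit_predict(X_train, y_train, X_test, kernel="linear", C=1.0, gamma="auto"):
    """Train a binary SVC and predict ``X_test`` labels in one call."""
    X_train = np.ascontiguousarray(X_train, dtype=np.float64)
    X_test = np.ascontiguousarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train)
    if _libsvm is None:  # pragma: no cover
        svc = SVC(kernel=kernel, C=C, gamma=gamma)
        return svc.fit(X_train, y_train).predict(X_test)
    classes = np.unique(y_train)
    y_enc = np.searchsorted(classes, y_train).astype(np.float64)
    g = _resolve_gamma(gamma, X_train.shape[1])
    model = _libsvm.fit(X_train, y_enc, svm_type=0, kernel=kernel, C=C, gamma=g)
    idx = _libsvm.predict(X_test, *model[:7], svm_type=0, kernel=kernel,
                          gamma=g).astype(int)
    return classes[idx]


def loocv_predict(X, y, kernel="linear", C=1.0, gamma="auto"):
    """Leave-one-out predictions for every sample.

    Uses the exact support-vector shortcut: removing a point with zero
    dual coefficient leaves the KKT conditions — hence the solution —
    unchanged, so only support vectors require a refit.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    d = X.shape[0]
    preds = np.empty(d, dtype=y.dtype)
    mask = np.ones(d, dtype=bool)
    if _libsvm is None:  # pragma: no cover
        for i in range(d):
            mask[i] = False
            preds[i] = fit_predict(X[mask], y[mask], X[i:i + 1], kernel, C, gamma)[0]
            mask[i] = True
        return preds
    classes = np.unique(y)
    y_enc = np.searchsorted(classes, y).astype(np.float64)
    g = _resolve_gamma(gamma, X.shape[1])
    model = _libsvm.fit(X, y_enc, svm_type=0, kernel=kernel, C=C, gamma=g)
    support = set(int(i) for i in model[0])
    full = _libsvm.predict(X, *model[:7], svm_type=0, kernel=kernel,
                           gamma=g).astype(int)
    for i in range(d):
        if i not in support:
            preds[i] = classes[full[i]]
            continue
        mask[i] = False
        sub = _libsvm.fit(np.ascontiguousarray(X[mask]), y_enc[mask],
                          svm_type=0, kernel=kernel, C=C, gamma=g)
        p = _libsvm.predict(X[i:i + 1], *sub[:7], svm_type=0, kernel=kernel,
                            gamma=g)
        preds[i] = classes[int(p[0])]
        mask[i] = True
    return preds
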