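"""NPCA-SVM proteomic pattern classifier and the holdout evaluation harness.

The classifier reduces each biological sample to its nonnegative
*meta-sample* (a row of the NPCA matrix ``U``, optionally sparse-coded to a
target Hoyer sparseness), then trains a soft-margin SVM on the
meta-samples.  Two ways of embedding unseen samples are supported:

* ``"transductive"`` — refit NPCA on the training and test rows jointly
  (warm-started from the trained ``U``), mirroring the original workflow in
  which the PC matrix is cached between trials; test information leaks into
  the unsupervised embedding, which is why the inductive mode exists.
* ``"nnls"`` — embed each unseen sample by nonnegative least squares
  against the trained loadings ``P``; fully inductive.

Evaluation follows the repeated 50% holdout protocol (HOCV): ``n_trials``
stratified random splits, reporting the mean and standard deviation of the
classification rate, sensitivity and specificity (positive class = cancer
= +1).  Peer baselines (k-NN, SVM, PCA-SVM, NMF-SVM, ICA-SVM, PCA-LDA) run
on the identical split sequence for paired comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import NMF, PCA, FastICA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .data import IntensityMatrix, TTestPrefilter
from .npca import NonnegativePCA

__all__ = [
    "NPCASVMClassifier",
    "CVReport",
    "train",
    "predict",
    "confusion_metrics",
    "evaluate_hocv",
    "run_baseline",
    "BASELINES",
]

SUPPORTED_KERNELS = ("linear", "rbf")


def _check_kernel(kernel):
    if kernel not in SUPPORTED_KERNELS:
        raise ValueError(
            f"unsupported kernel {kernel!r}; supported kernels: "
            f"{', '.join(SUPPORTED_KERNELS)}"
        )


def _make_svc(kernel, C, gamma):
    _check_kernel(kernel)
    return SVC(kernel=kernel, C=C, gamma="auto" if gamma == "auto" else gamma)


class NPCASVMClassifier(ClassifierMixin, BaseEstimator):
    """SVM over sparse-coded nonnegative-PCA meta-samples.

    Parameters
    ----------
    n_components : int or "auto"
        NPCA dimension k; "auto" uses d - 1 (d = training samples).
    alpha : float
        NPCA orthonormality penalty (default 10).
    delta : float or None
        Target Hoyer sparseness of each meta-sample (default 0.20);
        None disables sparse coding.
    kernel : {"linear", "rbf"}
    C, gamma : SVM regularization and rbf width; gamma "auto" means 1/k.
    projection_mode : {"transductive", "nnls"}
        How unseen samples are embedded (see module docstring).

    Attributes
    ----------
    npca_ : fitted :class:`NonnegativePCA`
    svm_ : fitted :class:`sklearn.svm.SVC` over the training meta-samples
    classes_ : ndarray, the sorted class labels (-1, +1)
    """

    def __init__(self, n_components="auto", alpha=10.0, delta=0.2,
                 kernel="linear", C=1.0, gamma="auto",
                 projection_mode="transductive", solver="hybrid",
                 max_iter=2000, tol=1e-4, random_state=0):
        self.n_components = n_components
        self.alpha = alpha
        self.delta = delta
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.projection_mode = projection_mode
        self.solver = solver
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y, npca_init=None):
        if isinstance(X, IntensityMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        _check_kernel(self.kernel)
        if self.projection_mode not in ("transductive", "nnls"):
            raise ValueError("projection_mode must be 'transductive' or 'nnls'")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        d = X.shape[0]
        k = d - 1 if self.n_components == "auto" else int(self.n_components)
        if k > d:
            raise ValueError(f"n_components={k} exceeds n_samples={d}")
        self.npca_ = NonnegativePCA(
            n_components=k, alpha=self.alpha, sparseness=self.delta,
            sparse_axis="rows", solver=self.solver, max_iter=self.max_iter,
            tol=self.tol, random_state=self.random_state,
        )
        U = self.npca_.fit(X, init=npca_init).U_
        if self.projection_mode == "nnls":
            # embed the training rows through the same inductive map the
            # test rows will see, so the SVM operates in one scale-consistent
            # space; normalize that scale for the soft-margin SVM
            U = self.npca_.transform(X)
            norms = np.linalg.norm(U, axis=1)
            self.embedding_scale_ = float(norms.mean()) or 1.0
            U = U / self.embedding_scale_
        self.svm_ = _make_svc(self.kernel, self.C, self.gamma).fit(U, y)
        self.X_train_ = X
        self.y_train_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _embed_transductive(self, X_new):
        d_tr = self.X_train_.shape[0]
        stacked = np.vstack([self.X_train_, X_new])
        k = self.npca_.model_.k
        rng = np.random.default_rng(self.random_state)
        pad = np.abs(rng.standard_normal((X_new.shape[0], k)))
        pad *= max(self.npca_.U_.mean(), 1e-3)
        init = np.vstack([self.npca_.U_, pad])
        joint = NonnegativePCA(
            n_components=k, alpha=self.alpha, sparseness=self.delta,
            sparse_axis="rows", solver=self.solver, max_iter=self.max_iter,
            tol=self.tol, random_state=self.random_state,
        ).fit(stacked, init=init)
        U = joint.U_
        svm = _make_svc(self.kernel, self.C, self.gamma)
        svm.fit(U[:d_tr], self.y_train_)
        return svm, U[d_tr:]

    def predict(self, X):
        check_is_fitted(self, "svm_")
        if isinstance(X, IntensityMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has shape {X.shape}, expected (*, {self.n_features_in_})"
            )
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        if self.projection_mode == "transductive":
            svm, U_new = self._embed_transductive(X)
            return svm.predict(U_new).astype(int)
        U_new = self.npca_.transform(X) / self.embedding_scale_
        return self.svm_.predict(U_new).astype(int)


def train(X: IntensityMatrix, k="auto", alpha=10.0, delta=0.2,
          kernel="linear", C=1.0, gamma="auto", seed=0,
          projection_mode="transductive", solver="hybrid") -> NPCASVMClassifier:
    """Fit an :class:`NPCASVMClassifier` on a labeled IntensityMatrix."""
    if X.labels is None:
        raise ValueError("train requires a labeled IntensityMatrix")
    clf = NPCASVMClassifier(
        n_components=k, alpha=alpha, delta=delta, kernel=kernel, C=C,
        gamma=gamma, projection_mode=projection_mode, solver=solver,
        random_state=seed,
    )
    return clf.fit(X.values, X.labels)


def predict(model: NPCASVMClassifier, X_new) -> np.ndarray:
    """Predict ±1 labels for unseen samples."""
    return model.predict(X_new)


def confusion_metrics(y_true, y_pred):
    """(classification rate %, sensitivity %, specificity %); positive = +1.

    Sensitivity (specificity) is NaN, with a warning, when the true
    positives (negatives) are absent.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_pred has {y_pred.size}"
        )
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == -1) & (y_pred == -1))
    pos = np.sum(y_true == 1)
    neg = np.sum(y_true == -1)
    rate = 100.0 * (tp + tn) / y_true.size
    if pos == 0:
        warnings.warn("no positive samples; sensitivity undefined")
        sens = np.nan
    else:
        sens = 100.0 * tp / pos
    if neg == 0:
        warnings.warn("no negative samples; specificity undefined")
        spec = np.nan
    else:
        spec = 100.0 * tn / neg
    return float(rate), float(sens), float(spec)


@dataclass
class CVReport:
    """Per-trial holdout metrics with their means and standard deviations."""

    per_trial: list[tuple[float, float, float]]
    n_trials: int
    holdout_fraction: float
    seed: int
    algorithm: str
    mean_rate: float = field(init=False)
    sd_rate: float = field(init=False)
    mean_sens: float = field(init=False)
    sd_sens: float = field(init=False)
    mean_spec: float = field(init=False)
    sd_spec: float = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.per_trial, dtype=float)
        means = np.nanmean(arr, axis=0)
        sds = np.nanstd(arr, axis=0, ddof=0)
        if self.n_trials == 1:
            warnings.warn("single-trial report: standard deviations are 0 by convention")
            sds = np.zeros(3)
        (self.mean_rate, self.mean_sens, self.mean_spec) = map(float, means)
        (self.sd_rate, self.sd_sens, self.sd_spec) = map(float, sds)

    def to_dict(self):
        return {
            "algorithm": self.algorithm,
            "n_trials": self.n_trials,
            "holdout_fraction": self.holdout_fraction,
            "seed": self.seed,
            "mean_rate": self.mean_rate, "sd_rate": self.sd_rate,
            "mean_sensitivity": self.mean_sens, "sd_sensitivity": self.sd_sens,
            "mean_specificity": self.mean_spec, "sd_specificity": self.sd_spec,
            "per_trial": [list(t) for t in self.per_trial],
        }


def make_splits(labels, n_trials, holdout, seed):
    """Stratified random train/test splits; fully determined by the seed.

    Per trial and per class, a fraction ``holdout`` (rounded, at least one
    sample kept on each side) goes to the test set.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    splits = []
    for _ in range(n_trials):
        train_idx, test_idx = [], []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            perm = rng.permutation(idx)
            n_test = int(np.clip(round(holdout * idx.size), 1, idx.size - 1))
            test_idx.append(perm[:n_test])
            train_idx.append(perm[n_test:])
        splits.append((np.sort(np.concatenate(train_idx)),
                       np.sort(np.concatenate(test_idx))))
    return splits


BASELINES = ("knn", "svm", "pca-svm", "nmf-svm", "ica-svm", "pca-lda")


def _baseline_factory(name, params, seed):
    p = dict(params or {})
    kernel = p.get("kernel", "linear")
    C = p.get("C", 1.0)
    k = p.get("n_components", None)

    def build(d_train, m):
        kk = min(d_train - 1, m) if k is None else int(k)
        if name == "knn":
            return KNeighborsClassifier(n_neighbors=p.get("k_neighbors", 5))
        if name == "svm":
            return _make_svc(kernel, C, p.get("gamma", "auto"))
        if name == "pca-svm":
            return Pipeline([("pca", PCA(n_components=kk, random_state=seed)),
                             ("svm", _make_svc(kernel, C, p.get("gamma", "auto")))])
        if name == "nmf-svm":
            return Pipeline([("nmf", NMF(n_components=kk, init="nndsvda",
                                         max_iter=500, random_state=seed)),
                             ("svm", _make_svc(kernel, C, p.get("gamma", "auto")))])
        if name == "ica-svm":
            return Pipeline([("ica", FastICA(n_components=kk, random_state=seed,
                                             max_iter=1000, whiten="unit-variance")),
                             ("svm", _make_svc(kernel, C, p.get("gamma", "auto")))])
        if name == "pca-lda":
            return Pipeline([("pca", PCA(n_components=kk, random_state=seed)),
                             ("lda", LinearDiscriminantAnalysis())])
        if name == "majority":
            return DummyClassifier(strategy="prior")
        raise ValueError(
            f"unknown algorithm {name!r}; options: npca-svm, majority, "
            + ", ".join(BASELINES)
        )

    return build


def evaluate_hocv(X: IntensityMatrix, algorithm="npca-svm", n_trials=100,
                  holdout=0.5, seed=0, prefilter=None,
                  prefilter_per_fold=False, **params) -> CVReport:
    """Repeated stratified holdout evaluation of one algorithm.

    ``prefilter`` (int or "auto") applies the two-sample t-test feature
    filter; by default it is fit on the full labeled data before the
    trials, matching the original protocol, while ``prefilter_per_fold``
    restricts it to each training split for leakage-free figures.

    Splits are generated from ``seed`` alone, so different algorithms run
    with the same seed see the identical split sequence.  For the NPCA-SVM,
    the PC matrix is warm-started from the previous trial (transductive
    mode on unfiltered data reduces to a single joint fit).
    """
    if X.labels is None:
        raise ValueError("evaluate_hocv requires labels")
    if not 0 < holdout < 1:
        raise ValueError("holdout must be in (0, 1)")
    values, labels = X.values, X.labels

    if prefilter is not None and not prefilter_per_fold:
        filt = TTestPrefilter(n_keep=prefilter).fit(values, labels)
        values = filt.transform(values)

    splits = make_splits(labels, n_trials, holdout, seed)
    rows = []

    if algorithm == "npca-svm":
        mode = params.get("projection_mode", "transductive")
        clf_kw = dict(
            n_components=params.get("n_components", "auto"),
            alpha=params.get("alpha", 10.0), delta=params.get("delta", 0.2),
            kernel=params.get("kernel", "linear"), C=params.get("C", 1.0),
            gamma=params.get("gamma", "auto"), projection_mode=mode,
            solver=params.get("solver", "hybrid"),
            max_iter=params.get("max_iter", 2000), tol=params.get("tol", 1e-4),
            random_state=seed,
        )
        if mode == "transductive" and not prefilter_per_fold:
            # joint embedding is split-independent: one NPCA fit serves all
            # trials (the cached-U trick taken to its fixed point)
            d = values.shape[0]
            k = d - 1 if clf_kw["n_components"] == "auto" else clf_kw["n_components"]
            npca = NonnegativePCA(
                n_components=k, alpha=clf_kw["alpha"], sparseness=clf_kw["delta"],
                solver=clf_kw["solver"], max_iter=clf_kw["max_iter"],
                tol=clf_kw["tol"], random_state=seed,
            )
            U = npca.fit(values).U_
            for tr, te in splits:
                svm = _make_svc(clf_kw["kernel"], clf_kw["C"], clf_kw["gamma"])
                svm.fit(U[tr], labels[tr])
                rows.append(confusion_metrics(labels[te], svm.predict(U[te])))
        else:
            cached_U = None
            for tr, te in splits:
                Xtr, Xte = values[tr], values[te]
                if prefilter_per_fold and prefilter is not None:
                    filt = TTestPrefilter(n_keep=prefilter).fit(Xtr, labels[tr])
                    Xtr, Xte = filt.transform(Xtr), filt.transform(Xte)
                clf = NPCASVMClassifier(**clf_kw)
                init = cached_U if (cached_U is not None
                                    and cached_U.shape[0] == Xtr.shape[0]) else None
                clf.fit(Xtr, labels[tr], npca_init=init)
                cached_U = clf.npca_.model_.U
                rows.append(confusion_metrics(labels[te], clf.predict(Xte)))
    else:
        build = _baseline_factory(algorithm, params, seed)
        mode = params.get("projection_mode", "transductive")
        transductive = mode == "transductive" and not prefilter_per_fold
        if transductive and algorithm in ("pca-svm", "nmf-svm", "ica-svm", "pca-lda"):
            d = values.shape[0]
            pipe = build(d + 1, values.shape[1])  # joint fit uses all d samples
            extractor, clf_proto = pipe.steps[0][1], pipe.steps[1][1]
            F = extractor.fit_transform(values)
            for tr, te in splits:
                clf = clone(clf_proto).fit(F[tr], labels[tr])
                rows.append(confusion_metrics(labels[te], clf.predict(F[te])))
        else:
            for tr, te in splits:
                Xtr, Xte = values[tr], values[te]
                if prefilter_per_fold and prefilter is not None:
                    filt = TTestPrefilter(n_keep=prefilter).fit(Xtr, labels[tr])
                    Xtr, Xte = filt.transform(Xtr), filt.transform(Xte)
                est = build(Xtr.shape[0], Xtr.shape[1])
                est.fit(Xtr, labels[tr])
                rows.append(confusion_metrics(labels[te], est.predict(Xte)))

    return CVReport(per_trial=rows, n_trials=n_trials, holdout_fraction=holdout,
                    seed=seed, algorithm=algorithm)


def run_baseline(name, X: IntensityMatrix, params=None, seed=0, n_trials=100,
                 holdout=0.5, prefilter=None, prefilter_per_fold=False) -> CVReport:
    """Evaluate one peer algorithm on the same split sequence as NPCA-SVM."""
    if name != "npca-svm" and name not in BASELINES and name != "majority":
        raise ValueError(
            f"unknown baseline {name!r}; options: " + ", ".join(BASELINES)
        )
    return evaluate_hocv(X, algorithm=name, n_trials=n_trials, holdout=holdout,
                         seed=seed, prefilter=prefilter,
                         prefilter_per_fold=prefilter_per_fold, **(params or {}))
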