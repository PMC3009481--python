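"""Seeded generators for serum-profile-like data and low-rank fixtures.

``generate_profiles`` emulates *preprocessed* SELDI/MALDI-TOF serum
profiles at desk scale: a decaying exponential baseline with Gaussian
peaks at random m/z positions, entrywise multiplicative lognormal noise,
and a small set of planted marker columns whose mean is shifted upward in
the cancer (+1) class by a chosen multiple of the within-class standard
deviation.  It does not model raw-spectrum artefacts (isotope envelopes,
instrument drift, baseline wander) — those are removed by preprocessing in
real pipelines.

``generate_lowrank`` builds X = U* S + |noise| from a known nonnegative
near-orthonormal factor U* with disjoint dominant supports, for
parameter-recovery experiments on the NPCA solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IntensityMatrix

__all__ = ["SyntheticSpec", "generate_profiles", "generate_lowrank"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic labeled serum-profile dataset.

    Defaults reflect a desk-scale two-class study: 30 controls + 30
    cancers, 300 m/z features of which 10 are markers shifted by two
    within-class standard deviations, 30% multiplicative noise.
    """

    n_per_class: tuple[int, int] = (30, 30)   # (controls -1, cancers +1)
    n_features: int = 300
    n_markers: int = 10
    effect_size: float = 2.0                  # mean shift in within-class sd units
    peak_density: float = 0.08                # fraction of columns that are peak centers
    noise_cv: float = 0.3                     # CV of the lognormal multiplicative noise
    baseline_decay: float = 3.0               # e-folds of baseline decay across the axis
    seed: int = 0

    def __post_init__(self):
        if self.n_markers > self.n_features:
            raise ValueError("n_markers cannot exceed n_features")
        if self.effect_size < 0 or self.noise_cv < 0:
            raise ValueError("effect_size and noise_cv must be >= 0")


def generate_profiles(spec: SyntheticSpec):
    """Generate a labeled IntensityMatrix plus the planted marker indices.

    The mean spectrum is ``baseline + peaks``; sample ``i``, column ``j``
    draws ``mu_j * exp(eps)`` with lognormal ``exp(eps)`` of unit mean and
    coefficient of variation ``noise_cv``.  Marker columns — placed at
    peak centers — have their +1-class mean multiplied by
    ``1 + effect_size * noise_cv`` so the shift equals ``effect_size``
    within-class standard deviations.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_features
    n_ctrl, n_case = spec.n_per_class
    d = n_ctrl + n_case

    mz = 900.0 + np.cumsum(rng.uniform(0.5, 1.5, size=m))  # strictly increasing Da axis
    pos = np.arange(m) / m
    baseline = 10.0 * np.exp(-spec.baseline_decay * pos)

    n_peaks = max(1, int(round(spec.peak_density * m)))
    centers = rng.choice(m, size=n_peaks, replace=False)
    widths = rng.uniform(1.0, 3.0, size=n_peaks)
    heights = rng.lognormal(mean=np.log(20.0), sigma=0.7, size=n_peaks)
    mu = baseline.copy()
    cols = np.arange(m)
    for c, wdt, h in zip(centers, widths, heights):
        mu += h * np.exp(-0.5 * ((cols - c) / wdt) ** 2)

    labels = np.concatenate([-np.ones(n_ctrl, dtype=int), np.ones(n_case, dtype=int)])
    # biomarkers are differential peptide peaks, so markers are planted at
    # peak centers (falling back to arbitrary columns only if peaks run out)
    if spec.n_markers <= n_peaks:
        markers = np.sort(rng.choice(centers, size=spec.n_markers, replace=False))
    else:
        extra = rng.choice(np.setdiff1d(cols, centers),
                           size=spec.n_markers - n_peaks, replace=False)
        markers = np.sort(np.concatenate([centers, extra]))

    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(d, m))
    else:
        noise = np.ones((d, m))
    values = np.tile(mu, (d, 1)) * noise
    # mean-only shift: the within-class sd of column j is mu_j * noise_cv,
    # so add effect_size of those units to the cancer class after the
    # noise draw (variances stay equal across classes)
    shift = spec.effect_size * spec.noise_cv * mu[markers]
    values[np.ix_(labels == 1, markers)] += shift
    values = np.maximum(values, 0.0)
    return IntensityMatrix(values, mz, labels), markers


def generate_lowrank(d: int, m: int, k: int, noise: float, seed: int):
    """Nonnegative X = U_true S_true + |eps| with known factors.

    ``U_true`` (d x k) has disjoint dominant row-blocks per column and unit
    column norms, hence is nonnegative and near column-orthonormal;
    ``S_true`` (k x m) is nonnegative with entries O(1).  ``noise`` scales
    a folded-Gaussian perturbation relative to the mean signal magnitude.
    """
    if not 1 <= k <= min(d, m):
        raise ValueError(f"need 1 <= k <= min(d, m); got k={k}, d={d}, m={m}")
    rng = np.random.default_rng(seed)
    U = np.abs(rng.normal(0.0, 0.02, size=(d, k)))
    blocks = np.array_split(np.arange(d), k)
    for j, rows in enumerate(blocks):
        U[rows, j] = np.abs(rng.normal(1.0, 0.2, size=rows.size))
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    S = np.abs(rng.normal(1.0, 0.5, size=(k, m)))
    X = U @ S
    if noise > 0:
        X = X + np.abs(rng.normal(0.0, noise * X.mean(), size=(d, m)))
    return X, U, S
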