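# Methods

## Problem setting

Serum proteomic profiling (SELDI/MALDI-TOF) represents each biological
sample as intensities over thousands of m/z positions ("pseudo-genes").
Class-discriminative information is carried by *local* features — a few
m/z positions — while classic PCA mixes positive and negative loading
weights and captures mostly global spectrum shape, diluting exactly the
features a classifier needs.  This package implements nonnegative PCA
(NPCA): a variance-maximizing decomposition constrained to the nonnegative
orthant, whose purely additive components preserve locality, plus the two
pipelines built on it — an NPCA-SVM pattern classifier and a filter-wrapper
biomarker selector.

## Nonnegative PCA

For a nonnegative data matrix `X ∈ R^{d×m}` (rows = samples) whose columns
are treated as observations in sample space `R^d`, NPCA maximizes

    J(U, α) = ½‖UᵀX‖²_F − α‖UᵀU − I‖²_F,    U ∈ R^{d×k}, U ≥ 0,

with gradient `∇J = XXᵀU + 4α U(I − UᵀU)`.  The penalty `α ≥ 0` presses
`U` toward column-orthonormality; rows of the optimum are the
*meta-samples* (low-dimensional nonnegative representations of each
sample) and `P = XᵀU` holds per-pseudo-gene loadings, giving the
decomposition `Xᵀ ≈ P Uᵀ`.

Note on orientation and centering: the classical "zero-mean" premise of
PCA conflicts with nonnegativity of both the data and the components, so
no centering is applied by default; `center=True` (subtract column means,
clip at 0) is available and documented as experimental.

### Solvers

* **gradient** — projected normalized-gradient ascent
  `U ← max(U + η ∇J/‖∇J‖, 0)` with fixed step `η = 1` (no line/trust-region
  search) and termination at `‖∇J‖ ≤ tol` (default `1e-4`, max 2000
  iterations).  A fixed unit-Frobenius step is not monotone, so the
  best-objective iterate seen is returned.  This is the scheme as
  originally printed; note the update direction there carries a minus sign
  while the problem is a maximization — we implement ascent.
* **coordinate** — exact cyclic per-entry maximization.  Restricted to a
  single entry `u_sl`, `J` is a quartic `−α u⁴ + c₂u² + c₁u + c₀` (the
  cubic term vanishes; `c₀ = −kα` does not affect the argmax), derived by
  expanding both Frobenius terms.  Each update solves the depressed cubic
  stationarity condition in closed form and takes the nonnegative argmax,
  so the objective is non-decreasing at every single update.  Requires
  `α > 0` (negative leading coefficient ⇒ bounded maximum).  Sweeps stop
  at relative objective change ≤ 1e-8.
* **hybrid** (estimator default) — a short gradient phase (≤ 200
  normalized-ascent steps) to reach a good basin, then coordinate sweeps to
  polish.  The unit-length fixed step limits the gradient solver's final
  resolution (it random-walks in a ball around the optimum), which is why
  polishing is worthwhile; on small instances the gradient solver's final
  objective is still within 2% of the coordinate solver's (tested).

Initialization is entrywise `|N(0,1)|` scaled to `‖U₀‖_F = √k`, seeded;
identical inputs and seed give bit-identical models.  Warm starts are
supported (`init=`), which is how repeated cross-validation trials reuse
the previous trial's PC matrix.

### Choosing α

The classification pipelines use the conventional experimental value
`α = 10`.  For unsupervised factor recovery the penalty must balance the
data term, which grows with problem size; `alpha="auto"` applies the
α-proportional-to-d rule as `α = 5d`.  The constant 5 was fixed once on
the low-rank recovery task (d = 20) and is not otherwise tuned.

## Sparse coding (Hoyer)

Sparseness of a nonnegative vector: `δ(v) = (√n − ‖v‖₁/‖v‖₂)/(√n − 1)`,
which is 1 for a one-hot vector, 0 for a constant vector, and
scale-invariant.  Projection to a target δ finds the nonnegative
intersection of the L1 hyperplane (L1 implied by δ and the preserved L2
norm) with the L2 hypersphere, by alternating projection: shift onto the
hyperplane, rescale onto the sphere, clip negatives, repeat (at most n + 1
rounds).  Meta-samples (rows of U) are sparse-coded by default with
δ = 0.20; mild targets (δ ≤ 0.5) are recommended because nonnegativity
already induces sparseness.  Columns (loading vectors) can be projected
instead via `axis="columns"` — the literature is ambiguous about which
axis was used, so both are exposed.

## NPCA-SVM classifier

Training: NPCA with `k = d − 1`, `α = 10`, row sparse-coding at δ = 0.20,
then a soft-margin SVM (`C = 1`; linear or rbf kernel, rbf `γ = 1/k`) on
the meta-samples.  The SVM quadratic program is delegated to libsvm via
scikit-learn — the contribution here is the feature extraction, not the
QP solver.

Embedding unseen samples is genuinely under-determined in this framework
(U rows exist only for fitted samples).  Two modes:

* **transductive** (default, mirrors the original protocol): refit NPCA on
  training + test rows jointly, warm-started from the trained `U`, retrain
  the SVM on the training rows, classify the test rows.  Test feature
  values (not labels) influence the embedding — a leakage caveat that
  matters for evaluation.
* **nnls** (inductive): embed `x'` as `argmin_{u≥0} ‖x' − P u‖₂` against
  the trained loadings.  Because `UᵀU` is far from the identity at
  practical α, NNLS re-embeddings differ from U rows by per-component
  scale, so in this mode the SVM is trained on NNLS re-embeddings of the
  training rows (the same map test rows pass through), normalized by the
  mean training-embedding norm.  This keeps train and test in one space
  and makes the mode fully deployable.

Evaluation: repeated stratified 50% holdout (HOCV), by convention 100
trials (20 in the test suite for runtime), reporting mean ± sd of
classification rate, sensitivity and specificity (positive class = cancer
= +1).  Splits are derived from the seed only, so every algorithm
evaluated at the same seed sees identical splits (paired comparison).  In
transductive mode without per-fold prefiltering the joint embedding is
split-independent, so one NPCA fit serves all trials — the fixed point of
the cached-U warm-start trick.  Baselines: k-NN, SVM, PCA-SVM, NMF-SVM,
ICA-SVM, PCA-LDA (scikit-learn implementations behind the same harness).

The two-sample t-test prefilter (Welch; smallest p first, ties to the
smaller column index; `"auto"` keeps `min(m, 10·d)` columns) is fit on the
full labeled data by default — reproducing the original protocol — with
`prefilter_per_fold=True` restricting it to each training split for
leakage-free figures.  The no-leakage control in the test suite (shuffled
labels, nnls mode, per-fold prefilter) must and does stay at chance.

## Bayes-factor filter

Per pseudo-gene, the two-sample Bayesian t-test is summarized as BF01 =
evidence(null: equal means)/evidence(alternative).  The original source
defers the prior to its reference; we use the closed-form g-prior
(unit-information, g = 1) Bayes factor

    BF01 = √(1+gN_e) · [(1 + t²/(ν(1+gN_e))) / (1 + t²/ν)]^((ν+1)/2),

with pooled t, `ν = n₁+n₂−2`, `N_e = n₁n₂/(n₁+n₂)`, evaluated in log
space (BF01 underflows around |t| ≈ 30 otherwise).  Properties relied on
downstream: BF01 > 1 at t = 0, symmetry in the groups, strict decrease in
|t|.  Differential pseudo-genes therefore have very small BF01; the
candidate set `S_b` keeps at least the top 1% (`⌈m·0.01⌉`) smallest, or a
caller-specified size.

## Filter-wrapper biomarker capture

NPCA is fit once on the candidate submatrix (α = 10) and each pseudo-gene
ranked by `τ_i = Σ_j w_j P_ij`, `w_j` the share of total score variance of
component j.  Greedy forward selection then grows a panel: at each step
the candidate maximizing SVM leave-one-out accuracy on the raw selected
intensity columns joins (ties by larger |τ|, then smaller index — |τ| not
signed τ, since reported coefficients can be negative under centering
conventions).

Stopping implements "maximum accuracy with the fewest biomarkers" as:
accept a step only if it strictly improves the panel's LOOCV accuracy;
stop at the first step where no candidate improves, or when accuracy
reaches 100%.  (An exploration variant — accept each step's maximizer
unconditionally, then truncate to the shortest prefix attaining the
running maximum — was evaluated and recovers planted markers no better,
because the same selection noise drives both; the simpler strict rule is
kept.)

LOOCV is computed exactly, with two speedups that do not change results:
scikit-learn's bundled libsvm is called directly (same solver, per-fit
overhead removed), and folds whose held-out point has zero dual
coefficient reuse the full-data model (removing a non-support vector
provably leaves the solution unchanged).  Agreement with per-fold SVC
fits is tested.

## Synthetic data

`generate_profiles` emulates *preprocessed* serum profiles at desk scale:
a decaying exponential baseline (10·exp(−3·pos)), ~8% of columns carrying
Gaussian peaks (width 1-3 channels, lognormal heights around 20), and
entrywise multiplicative lognormal noise of unit mean with coefficient of
variation `noise_cv = 0.3` — multiplicative noise is the dominant residual
variation in normalized MS intensities.  Markers are planted at peak
centers (differential biomarkers are peptide peaks; a relative shift on a
near-zero baseline column would carry no usable absolute signal) and
receive a mean-only shift of `effect_size` within-class standard
deviations (`effect·noise_cv·μ_j`), added after the noise draw so class
variances stay equal and t-type filters have a well-defined target.
Default study conditions: 30 + 30 samples, 300 features, 10 markers at
2σ.  Not modeled: raw-spectrum artefacts (baseline wander, isotope
envelopes, calibration drift), inter-column correlation, and
batch/instrument effects — so passing tests demonstrate method behavior
under clean planted signal, not robustness to preprocessing failures.

`generate_lowrank` builds `X = U*S + |ε|` with a nonnegative, unit-norm,
disjoint-dominant-support `U*` (near column-orthonormal) and nonnegative
`S`, for factor-recovery experiments (d = 20, m = 200, k = 3, 5% noise in
the test suite; recovery is scored as mean matched |column correlation|).

## Numerical choices and degenerate inputs

* Sparseness values are clipped to [0, 1] against a few-ulp roundoff.
* Zero rows/columns are skipped (with a warning) during sparse coding;
  a zero vector has no defined sparseness and is rejected.
* All-constant score matrices make variance-explained ratios undefined:
  `variance_explained` raises; `npca_fit` falls back to uniform weights so
  degenerate fits remain serializable.
* Zero pooled variance with equal means is rejected by the Bayes factor
  (degenerate); with unequal means the |t| → ∞ limit `(1+gN_e)^{−ν/2}` is
  returned.
* Accuracy ties anywhere are broken deterministically (|τ|, then smaller
  index); all stochastic components draw from `numpy` Generators seeded
  from the caller's single seed.

## Problem sizes in the test suite

The end-to-end suite runs at the documented study conditions: factor
recovery at (20 × 200, k = 3, 10 seeds), classification at (60 × 300, 10
markers, 20 holdout trials plus a shuffled-label control), biomarker
recovery at (60 × 200, 3 markers, 10 seeds), oracle comparisons at 50-100
random instances each.  Unit tests use smaller instances of the same
generators.

## Known limitations

* The fixed-step gradient solver is faithful to the printed scheme but
  rarely reaches the `‖∇J‖ ≤ 1e-4` criterion; treat `converged=False`
  with a good objective trace as normal for it, or use the hybrid solver.
* Transductive evaluation shares the optimistic bias of the original
  protocol; inductive (nnls, per-fold prefilter) numbers are the
  deployment-relevant ones.
* Greedy LOOCV selection at a few dozen samples is noisy: with ~200
  candidates the maximum over null candidates routinely matches genuine
  signal within one or two leave-one-out samples, so selected panels can
  include passengers, and reported cumulative LOOCV accuracies are
  optimistic for generalization.
* BF01 values depend on the g-prior; rankings (what the filter uses) are
  prior-robust, absolute values are not.
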