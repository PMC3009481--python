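# npca-protpat

Nonnegative principal component analysis (NPCA) with sparse coding for
mass-spectral serum proteomic profiles: pattern classification (NPCA-SVM)
and filter-wrapper biomarker discovery.

## Why

A serum profile is a nonnegative intensity vector over thousands of m/z
positions ("pseudo-genes"); cancer/control status is carried by a handful
of *local* features.  Classic PCA loadings mix positive and negative
weights whose cancellations wash local features out of the leading
components.  NPCA constrains the decomposition to the nonnegative
orthant, making the representation purely additive and locality
preserving:

    maximize  J(U, α) = ½‖UᵀX‖²_F − α‖UᵀU − I‖²_F   subject to U ≥ 0,

for data `X ∈ R^{d×m}` (d samples × m pseudo-genes), `U ∈ R^{d×k}`
(`k ≤ d`), with the penalty `α` controlling how near `U` stays to
column-orthonormality.  Rows of `U` are *meta-samples* — nonnegative
k-dimensional representations of each biological sample — and `P = XᵀU`
holds per-pseudo-gene loadings (`Xᵀ ≈ PUᵀ`).  On top of this sit:

* **NPCA-SVM** — sparse-coded meta-samples (Hoyer sparseness δ = 0.20)
  fed to a soft-margin SVM (linear/rbf), evaluated by repeated stratified
  50% holdout with sensitivity/specificity reporting;
* **biomarker capture** — a Bayesian two-sample t-test filter (smallest
  BF01 = strongest differential evidence) proposes candidates, NPCA ranks
  each pseudo-gene by `τ_i = Σ_j w_j P_ij`, and a greedy SVM-LOOCV wrapper
  selects a minimal panel.

Everything is exercised end-to-end on seeded synthetic serum profiles
(exponential baseline, Gaussian peaks, multiplicative lognormal noise,
planted differential peaks), so no external data is needed.  See
`docs/methods.md` for the full model account.

## Worked example

```
$ npca-protpat simulate --n-controls 30 --n-cancers 30 --n-features 300 \
      --n-markers 10 --seed 7 --out X.csv --truth truth.json
wrote 60 x 300 matrix to X.csv

$ npca-protpat classify --input X.csv --kernel linear --trials 20 --seed 1 \
      --out report.json
mean rate 97.17% (sens 99.00%, spec 95.33%)

$ npca-protpat biomarkers --input X.csv --candidates 100 --seed 1 \
      --out biomarkers.json
selected 3 biomarkers; final LOOCV accuracy 100.00%
```

The simulated dataset plants ten differential peaks (indices in
`truth.json`: 30, 42, 86, 99, 122, 139, 161, 214, 215, 245).  The
classifier's 97.17% is the mean classification rate over 20 random 50%
holdout splits, with mean sensitivity 99.00% (cancers called cancer) and
specificity 95.33% (controls called control).  The biomarker run selects
the panel (214, 122, 86) — all three are planted markers — with Bayes
factors around 1e-10 (strong differential evidence), NPCA coefficients
τ, and a cumulative leave-one-out accuracy trace 90% → 95% → 100%, at
which point selection stops.  Every run writes a `*.manifest.json`
recording the resolved configuration and seed for exact reproduction.

The same pipeline from Python, scikit-learn style:

```python
from npca_protpat import (NonnegativePCA, NPCASVMClassifier,
                          SyntheticSpec, generate_profiles, evaluate_hocv)

data, markers = generate_profiles(SyntheticSpec(seed=7))
U = NonnegativePCA(n_components=10, alpha=10.0, sparseness=0.2).fit_transform(data.values)
report = evaluate_hocv(data, algorithm="npca-svm", n_trials=20, seed=1)
print(f"{report.mean_rate:.2f} ± {report.sd_rate:.2f}%")   # 97.17 ± 2.18%
```

`NPCASVMClassifier` supports two ways to embed unseen samples:
`"transductive"` (joint refit, mirrors the original protocol) and
`"nnls"` (inductive nonnegative least squares against the trained
loadings; the deployable mode).  `npca-protpat benchmark` runs k-NN, SVM,
PCA-SVM, NMF-SVM, ICA-SVM and PCA-LDA on the identical split sequence for
paired comparison.

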