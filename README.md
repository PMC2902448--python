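# sspca — super-sparse principal component analysis

Principal component analysis of high-dimensional genomic matrices (samples ×
genes) produces loadings that are nonzero on essentially every gene, which
makes the components hard to interpret and reflects the high variance of the
unconstrained estimator. `sspca` implements a sparse PCA whose loadings can
be *extremely* sparse — thousands of genes forced exactly to zero — by
combining two ingredients:

1. **A random-effect penalty unbounded at the origin.** Each loading
   coefficient is modeled hierarchically as v | u ~ N(0, uθ) with a gamma
   scale u of mean 1 and variance w. Profiling u out of the h-likelihood
   yields a penalty family indexed by w: quadratic (ridge) at w = 0, a
   LASSO-like cusp at w = 2, and unbounded at the origin for w > 2. The
   default w = 30 gives an infinite gain for exact zeros, far sparser than
   LASSO or the elastic net. The penalized loading is computed inside a
   modified NIPALS power iteration whose regression step is solved by
   iterative weighted least squares with weights p′_λ(|ṽ_j|)/|ṽ_j|,
   ṽ_j = √(v_j² + δ), δ = 1e-8.

2. **Condition-number shrinkage of the singular values.** The sample
   covariance spectrum is more dispersed than the truth; constraining its
   condition number to κ_max (chosen by K-fold cross-validated Gaussian
   likelihood) truncates the inverse spectrum to an interval
   [t*, κ_max t*] and reconstructs a matrix X* with the same singular
   vectors but shrunken singular values. Fitting the penalized loadings on
   X* instead of X ("super-sparse PCA", SSPCA) further improves both
   estimation and support recovery, dramatically so when p ≫ n.

Tuning is automatic: θ by a moment estimator from the ordinary-PCA loading,
λ by 5-fold cross-validation maximizing held-out score variance. The number
of components can be chosen by a permutation test (shuffling values within
each sample), and explained variance of the correlated sparse scores is
reported as QR-based adjusted variance. LASSO, SCAD, elastic-net and ridge
penalties are available through the same interface for comparison.

## Worked example

Fit one super-sparse component to data drawn from a single-factor model
where only the first 4 of 20 variables carry signal:

```python
import numpy as np
import sspca

scen = sspca.SimScenario(n=80, p=20, beta_sq=2.0, phi=0.1)
X_raw, truth = sspca.generate(scen, np.random.default_rng(1))
X = sspca.center_columns(X_raw)

fit = sspca.fit(
    X, k=1,
    spec=sspca.PenaltySpec(family="hl", w=30.0),
    use_condition_shrinkage=True,
    tuning=sspca.TuningConfig(K=5, seed=1),
)
print("nonzero loadings:", fit.nonzero_counts[0])
print("loading:", np.round(fit.loadings[:6, 0], 4))
print("sine distance to truth:",
      round(sspca.loading_distance(truth["v1_true"], fit.loadings[:, 0]), 4))
```

```
nonzero loadings: 4
loading: [0.4901 0.508  0.4753 0.5252 0.     0.    ]
sine distance to truth: 0.0375
```

The fit keeps exactly the four signal variables (true loading
(1/2, 1/2, 1/2, 1/2, 0, …, 0)) and zeroes the other sixteen; the sine of the
angle to the true loading is ≈ 0.04, versus ≈ 0.05–0.06 for ordinary PCA on
the same draw.

The same analysis from the shell, with the component count chosen by
permutation test:

```sh
sspca fit --input expression.tsv --method sspca --penalty hl --w 30 \
          --k auto --permutations 1000 --alpha 0.001 --seed 1 --out results/
sspca simulate --reps 100 --seed 1 --out sim/
```

`fit` writes loadings (full precision plus a sparsity mask at the 5e-5
reporting threshold), scores, singular values, adjusted variances,
permutation p-values and a JSON manifest; `simulate` reproduces the full
simulation benchmark as a tidy table and a readable report.

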