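# robustridge

Shrinkage regression that survives two problems at once: **multicollinearity**
(near-linear dependence among predictors, which inflates ordinary
least-squares variance) and **y-direction outliers** (gross response errors,
which bias any least-squares-based fit). The package implements the
two-parameter ridge-type M-estimator (RTMME) together with the five
estimators it is compared against, the closed-form mean-squared-error
theory that ranks them, robust data-driven selection of the biasing
parameters, and a Monte Carlo engine for factorial simulation studies.

It is aimed at statisticians and quantitative scientists fitting linear
models to collinear, contamination-prone data — e.g. epidemiological or
chemometric regressions with a handful of strongly correlated covariates.

## The estimator family

For the standardized model `y = Xβ + ε` write the canonical form
`y = Zα + ε` with `Z = XT`, `α = T'β`, where `T` holds the eigenvectors of
`X'X` and `Z'Z = Λ = diag(λ₁,…,λ_p)`. All six estimators are component-wise
shrinkages of a base fit:

| estimator | base fit | shrinkage factor |
|---|---|---|
| OLS | least squares | 1 |
| M | Huber M (IRLS) | 1 |
| ridge | least squares | λᵢ/(λᵢ+k) |
| ridge-M | Huber M | λᵢ/(λᵢ+k) |
| MRT | least squares | λᵢ/(λᵢ+k(1+d)) |
| **RTMME** | **Huber M** | **λᵢ/(λᵢ+k(1+d))** |

The scalar risk `MSE(α̂) = E‖α̂ − α‖²` has a closed form for each of them;
for RTMME

```
MSE(α̂_RTMME) = Σᵢ λᵢ²Ωᵢᵢ/(λᵢ+k(1+d))² + Σᵢ k²(1+d)²αᵢ²/(λᵢ+k(1+d))²
```

with `Ω = Cov(α̂_M) ≈ A²Λ⁻¹` (Huber's variance statistic `A²`). The
`mse_theory` module evaluates these risks, the pairwise differences
(RTMME vs MRT / ridge-M / M), and the `k` threshold above which RTMME
dominates the ridge M-estimator. Biasing parameters are selected by
harmonic-mean rules: `k = pA²/Σ(1+d)α̂²_Mi` with an iterative update of
`d` and a fallback to the initial `d̂ = min A²/α̂²_Mi` when the harmonic
mean turns negative.

## Worked example

Generate a small collinear dataset (pairwise predictor correlation 0.9,
true coefficients 1.5, 1.0, 0.5) with one gross +15 outlier in `y`, then
select `(k, d)` and fit:

```
$ robustridge select --input demo.csv --response y
{ ... "A2": 0.7642, "k_final": 0.02546, "d_final": 0.52458, "used_fallback": false ... }

$ robustridge fit --input demo.csv --response y --estimator rtmme --k 0.0255 --d 0.5246
{ ... "beta_raw": [1.4772, 1.3792, -0.1413], "intercept": 3.417, "iterations": 14 ... }

$ robustridge fit --input demo.csv --response y --estimator ols
{ ... "beta_raw": [4.1381, 0.8488, -2.9572], "intercept": 10.271 ... }
```

OLS is wrecked by the collinearity-plus-outlier combination (note the
sign flip on the third coefficient); the RTMME fit at the selected
parameters is close to the truth. `robustridge theorems` prints the
theorem-condition quantities (`ΣΩ̂ᵢᵢ` vs `Σσ̂²/λᵢ`, the `k₁ᵢ` thresholds,
all six theoretical MSEs) for any dataset, and `robustridge simulate`
runs a YAML-configured scenario grid into a long-format CSV.

All of this is equally available as a library:

```python
import robustridge as rr
data = rr.standardize_design(X_raw, y_raw)
sel = rr.select_kd(data)
fit = rr.fit_named("RTMME", data, k=sel.k_final, d=sel.d_final)
```

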