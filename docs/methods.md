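# Methods

## Model and estimators

The package works with the centered linear model `y = Xβ + ε`,
`E ε = 0`, `Cov ε = σ²I`, where `X` (n×p, full column rank) is in
correlation form: columns centered and scaled to unit Euclidean norm,
response centered. The intercept is handled implicitly by the centering
and recovered by `back_transform`. Unit-norm scaling (rather than
unit-variance) keeps the eigenvalue spectrum of `X'X` comparable across
sample sizes.

Everything is computed in the canonical coordinates `Z = XT`,
`α = T'β`, where `T` diagonalizes `X'X` (eigenvalues descending,
eigenvector signs fixed so each first non-negligible entry is positive —
needed only for reproducibility; fitted values are invariant). The six
estimators form a lattice of special cases of one operator,

    α̂(k, d; base)_i = λᵢ/(λᵢ + k(1+d)) · α̂_base,i ,

with base ∈ {OLS, Huber-M} and (k, d) ≥ 0: ridge and MRT shrink the OLS
base; ridge-M and RTMME shrink the M base; k = 0 recovers the base fit.
The identities RIDGE(k)=MRT(k,0), MRT(k,d)=RIDGE(k(1+d)),
RTMME(k,0)=RIDGE_M(k), RTMME(0,0)=M hold exactly in floating point and
are asserted in the test suite. The d-scaled variant with combined
constant `k·d` is the same operator evaluated at `(kd, 0)`.

## Huber M-fit

The M base fit solves `Σ ψ(eᵢ/s) zᵢ = 0` with the Huber score
`ψ(u) = max(−c, min(u, c))`. Choices (the literature the estimator
builds on leaves them open):

- tuning constant `c = 1.345` (95% Gaussian efficiency), configurable;
- scale `s` = median(|e|)/0.6745, re-estimated every IRLS iteration
  (`mad_iterated`, default) or frozen at the initial OLS residual scale
  (`mad_fixed`);
- IRLS from the OLS start with weights `wᵢ = min(1, c·s/|eᵢ|)`,
  convergence when `max|Δα| / (1 + max|α|) < 1e-8`, hard cap of 100
  iterations with a `converged` flag;
- a zero MAD triggers a fallback scale of `mean|e| × 1.2533` (flagged,
  never NaN); an exactly interpolating fit short-circuits with unit
  weights, since the estimating equations hold trivially.

The implementation agrees with statsmodels' RLM (HuberT, MAD scale) to
~1e-10 on test problems; statsmodels is used only as an independent
oracle, never as the fitting path.

## Risk theory

`theoretical_mse` evaluates the closed-form scalar risks; the difference
functions Δ1 (RTMME−MRT), Δ2 (RTMME−ridge-M), Δ3 (RTMME−M) are separate
closed forms checked against direct subtraction to 1e-12. Three
documented printing defects in the source algebra are handled explicitly
rather than silently repaired:

- The RTMME-vs-MRT condition is stated at the sum level
  (`ΣΩᵢᵢ < Σσ²/λᵢ`) but only the componentwise condition
  (`Ωᵢᵢ < σ²/λᵢ ∀i`) guarantees Δ1 < 0 for all k, d. `check_theorem1`
  therefore returns both booleans plus the realized Δ1 instead of a
  single verdict.
- The dominance threshold `k₁ᵢ` is printed with `8αᵢ²Ωᵢᵢ(d+1)` under the
  radical and a `(d+1)` denominator, but solving the quadratic
  inequality it is derived from gives `16αᵢ²Ωᵢᵢ` and no `(d+1)` factors
  — and the printed form returns a nonzero threshold at d = 0 where
  Δ2 ≡ 0. Both closed forms are exposed (`k1_threshold`,
  `k1_threshold_quadratic`) and an independent numeric sign-change
  locator (`sign_change_points`: 1000-point log grid on (0, k_max] plus
  bisection to 1e-10) arbitrates. The acceptance run tabulates
  agreement counts for both forms without grading them; on random
  settings neither form reliably matches the numeric crossing points,
  which is the honest summary of that algebra.
- The necessary condition for RTMME to beat M is printed with opposite
  inequality directions in its statement and its proof; `check_theorem3`
  reports the bound, the Ω trace and the realized Δ3 and asserts
  nothing. Δ3 itself uses the difference-of-sums form because the
  printed per-component expression omits its denominator (the
  cross-check restores it).

## Parameter selection

`A²` is estimated from the converged M-fit residuals as
`s²/(n−p−1) · Σψ(eᵢ/s)² / [(1/n)Σψ′(eᵢ/s)]²` with the sums over all n
residuals (the printed index runs to p, but only the n-reading is
consistent with the (1/n) factor), and `Ω̂ᵢᵢ = Â²/λᵢ`. Steps:
d̂ = min Â²/α̂²_Mi; k̃ = pÂ²/Σ(1+d̂)α̂²_Mi (harmonic-mean rule); d̃ =
harmonic mean of the per-component Â²/(k̃α̂²_Mi) − 1; fall back to d̂ when
d̃ < 0. Geometric- and arithmetic-mean k variants are computed for
reporting; the classical mean inequality HMR ≤ GMR ≤ AMR is verified in
tests. The selected d is deliberately not clipped to (0,1) — the
iterative rules never clip, and on weak-signal data d̃ routinely exceeds
1 — but a warning is emitted and `clip_d=True` caps it at 1 for users
who want the theoretical range. The scalar d̂ from Step 1 (not
per-component values) enters Step 2, matching the procedure's wording.

## Synthetic-data generator

`generate_design` draws `xᵢⱼ = (1−ρ²)^{1/2} zᵢⱼ + ρ zᵢ,p+1` with iid
standard-normal z, giving every raw column pair population correlation
ρ² (at ρ = 0.99 an empirical check at n = 100,000 reproduces 0.9801
within 0.01), then standardizes to correlation form. True coefficients
are the unit-norm leading eigenvector of `X'X` (so β′β = 1 and the
signal sits in the best-conditioned direction), responses are Gaussian
with zero intercept, and contamination shifts observation 10 by +20σ
(one outlier) or observations 5 and 10 by ±20σ (two). The design is
drawn once per scenario and held fixed across replications by default,
in the fixed-X tradition of this simulation design; `redraw_design=True`
re-draws it every replication. Replication streams come from
`SeedSequence(seed, rep)`, so scenarios are bit-reproducible and
order-independent.

What the generator emulates: severe, equal-strength collinearity among
Gaussian predictors with a small number of gross symmetric y-outliers.
What it does not: leverage (x-direction) outliers, heavy-tailed or
skewed errors, heteroscedasticity, and structured correlation patterns.
Passing tests therefore demonstrate the estimator ordering under the
stated stylized conditions, not under arbitrary real-data pathologies.

The empirical criterion is `mse(α̂) = (1/reps)Σ‖α̂ⱼ − α‖²` with a Monte
Carlo standard error attached to every cell. It is computed on the
canonical coefficients; the original-scale coefficient error is the
same number, since `‖T(α̂−α)‖ = ‖α̂−α‖` for orthogonal `T`.

## Problem sizes and numerical choices

The default test/acceptance workloads are sized for a laptop-class
single core: 100 random instances for the exact reduction identities,
20,000 replications for the closed-form-vs-Monte-Carlo agreement (3
MC-SE tolerance), 1,000 random settings for the theorem property and
the Δ-oracle equivalence, and 500 replications for the scenario
orderings at n = 20, p = 3, ρ = 0.99, σ = 1 — the hardest cell of the
factorial design, where the contrast between OLS-based and M-based
shrinkage is widest. Full-size runs (2,000 replications, the complete
ρ × σ × n × p grid) are available through `run_grid`/`robustridge
simulate` with a YAML scenario list.

Degenerate inputs are errors, not warnings: rank-deficient or constant
columns, non-positive eigenvalues, negative biasing parameters, zero
M-coefficients in the selection rules, and an all-rejected ψ′ sum in
A². Eigenvalue ties in `true_coefficients` keep the stable-sort first
eigenvector and warn.

## Known limitations

- The dominance-threshold algebra is internally inconsistent in its
  source; the package reports rather than resolves it (see above).
- Asymptotic `Ω ≈ A²Λ⁻¹` is a large-n approximation; at n = 20 the
  plug-in theorem checks are indicative, not exact.
- No leverage-point robustness: the Huber M-estimator protects against
  y-outliers only, and the simulation engine deliberately mirrors that
  scope.
- Standard errors and inference for the shrunken coefficients are out
  of scope.
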