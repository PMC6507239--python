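# Methods

## Model and procedure

The package estimates a linear exposure–outcome model

y = β₀ + Σⱼ βⱼ xⱼ + Σ₍ₐ,ᵦ₎ β₍ₐᵦ₎ xₐ x_b + Σ_c θ_c z_c + ε

for a continuous outcome y, standardized exposures xⱼ, optional pairwise
products, and confounders z_c, under the working assumptions of additive
homoscedastic Gaussian error and effects linear on the log-exposure
scale. Selection proceeds in two stages.

**Stage 1 — screening.** A regression random forest (bootstrap samples;
`mtry` random split candidates per node) is grown on the main-effect
candidates only. Permutation variable importance is the mean, over
trees, of the increase in that tree's out-of-bag MSE when the variable's
out-of-bag values are permuted; a variable a tree never splits on
contributes exactly zero for that tree. The default retention rule keeps
VIMP > 0 — "predicts better than noise" — because any fixed quantile or
top-k rule would need a tuning argument the data cannot supply; top-k
and fraction-of-max rules exist for sensitivity analysis. The comparator
screen is a single CART tree, cost-complexity pruned at the
one-standard-error α from K-fold cross-validation; the kept set is the
variables appearing in any split of the pruned tree. An empty screen
falls back, loudly logged, to the unscreened single-step analysis rather
than erroring. Confounders never enter screening; they are force-carried
into stage 2.

**Stage 2 — adaptive lasso.** The objective is the residual sum of
squares plus λ Σ wⱼ|βⱼ| — deliberately *without* a 1/(2n) factor, so λ
values are not comparable to conventions that normalize by sample size
(`lambda_to_mean_scale` converts). Weights are wⱼ = |β̂ⱼ^init|^(−γ),
capped at 10⁶ so a zero initial estimate renders a variable effectively
unselectable without producing infinities; confounder weights are 0.
Initial estimates come from OLS, or ridge when the design is
ill-conditioned (condition number > 10³ or p ≥ n/2), with the ridge
penalty chosen by its own cross-validation. The solver is cyclic
coordinate descent on the Gram system with soft-threshold updates and
warm starts along the λ path; unpenalized coordinates get plain
least-squares updates. Convergence is declared when the largest
coefficient change in a sweep falls below `tol` (default 1e-9); the
objective is non-increasing across sweeps and KKT certificates are
asserted in the test suite.

**Tuning.** For each γ in {0.5, 1, 2} (Zou's candidate exponents), a
100-point log-spaced λ path runs from λ_max (the smallest λ that zeroes
every penalized coefficient, max over j of 2|xⱼᵀy|/wⱼ after
residualizing on unpenalized columns) down to 10⁻⁴ λ_max. K-fold CV
(default K = 10) shares one fold assignment across the whole (γ, λ)
grid. The design is standardized inside each training fold and the
stored statistics applied to the held-out fold; the final refit
standardizes on all data. Adaptive weights default to first-stage
estimates on the full data, shared across folds (the glmnet
`penalty.factor` workflow); recomputing them per training fold is
available as `weight_mode='per-fold'`.

**Selection rule.** The default picks the sparsest pair — largest λ,
then smallest γ — whose CV error lies within one standard error of the
minimum (SE taken across fold-level MSEs at the minimizing pair). The
exact CV minimizer is available as `selection='min'`, but CV-min is
known to drag one or two null variables into the model in most
replicates; on 50 replicates of the calibrated correlated design it
recovers exactly the true support in 14/50 runs versus 42/50 for the
1-SE rule, and it can even invert the expected parsimony ordering
between the two-step and single-step workflows. The 1-SE band is the
same convention used for the CART pruning.

**Interactions.** For two-step methods, pairwise products are formed
*after* screening and only among survivors — a variable that fails the
screen contributes neither a main effect nor any product. The
single-step comparator expands over all candidates. Product columns are
computed from the standardized mains and then re-standardized
themselves (an assumption; unstandardized products would carry unequal
effective penalties). No main-effect/interaction hierarchy is imposed by
default, since interaction-only signals are scientifically reportable;
a strong-hierarchy filter exists and is off by default. Confounders
never enter products.

**Inference.** Reported coefficients and 95% confidence intervals come
from a naive OLS refit of the outcome on the selected support plus
forced confounders (Wald t-intervals). These condition on the selected
model: coverage is nominal for a support fixed a priori (verified by
simulation in the test suite) and no post-selection validity is claimed.

**Performance evaluation.** R² = 1 − SSE/SST; adjusted R² uses
p_effective = the number of nonzero estimated coefficients excluding the
intercept (selected mains, interactions, and forced confounders);
MSE = SSE/n. The cross-validated MSPE is fold-size weighted,
Σₖ (nₖ/n) Σ_{i∈Cₖ} (yᵢ − ŷᵢ)²/nₖ, which equals the pooled held-out mean
squared error for any fold sizes. MSE.CV is reported as the
fold-size-weighted mean of the K training-fold MSEs — an interpretation,
recorded in the report metadata, since the quantity's definition is a
convention. By default the performance CV re-runs the *entire*
procedure (screening included) inside each training fold so that no
selection information leaks into the held-out folds
(`cv_mode='nested'`); `'fixed-screen'` keeps the full-data screen and
re-runs only the penalized stage.

## Synthetic designs

Two generators define the validation conditions.

**Correlated design (`dataset2_default`).** n = 500 draws of 20
zero-mean unit-variance Gaussians: equicorrelation 0.1 within X1..X15,
0.05 within X16..X20, 0 across blocks (positive definite iff
ρ > −1/(block size − 1)). Outcome: positive mains on X1, X2, X12, X15,
negative on X9, X16, one synergistic X1·X12 product, plus N(0, 1) noise.
All six main magnitudes and the interaction coefficient are equal, and
the common magnitude (0.2405) is calibrated analytically so the true
model's population R² is exactly 0.30 — the moderate signal-to-noise
regime the design targets. The signal variance is computed in closed
form: the linear part contributes βᵀCβ, each product pair contributes
c₍ₐᵦ₎c₍꜀ᑯ₎(C₍ₐ꜀₎C₍ᵦᑯ₎ + C₍ₐᑯ₎C₍ᵦ꜀₎) by Isserlis' theorem, and the
linear-product cross terms vanish (odd Gaussian moments). At n = 500
the realized pairwise sample correlations typically span about −0.13 to
0.22. `correlation_sweep_config(rho)` replaces both block correlations
to study degradation as collinearity grows; values above 0.8 warn, since
no selection method is reliable under near-collinear exposures.

**Cohort-style design (`niehs_like`).** Seven correlated exposures plus
a confounder Z (standard normal, correlation 0.2 with X1 — a mild,
configurable entanglement, since no structure is prescribed). True
coefficients honor fixed potency ratios exactly: β₁ = 2β₂ > 0,
β₅ = 4.5β₄ with both negative, β₇ > 0, β₃ = β₆ = 0, plus an additive Z
effect. The default correlation matrix mixes a moderately correlated
triple (0.6), one tight pair (0.85), a mild pair (0.3), weak positive
background (0.1) and a few mild negatives, spanning realized sample
correlations from slightly negative to ~0.9. The noise SD defaults to
the value that makes the true model's population R² 0.90 (a
strong-signal, well-specified regime). This generator is a **linear
surrogate**: the dose-response surface it stands in for is biologically
based and unspecified, so only the stated signs, ratios and correlation
character are emulated, not any particular published dataset.

What the generators deliberately omit: non-Gaussian exposure marginals
(real concentrations are log-normal-ish and are log-transformed by the
preprocessing layer before modeling), detection-limit censoring,
missingness, heteroscedastic or skewed outcome noise, and nonlinear
dose-response. Passing tests therefore demonstrate correct behavior of
the estimators under the stated linear-Gaussian conditions — not
robustness to the full messiness of field data.

## Preprocessing rules

Raw concentration tables pass through: (1) below-detection-limit cells
imputed as LOD/√2 (the conventional substitution for left-censored
lognormal measurements); (2) exclusion of variables whose combined
missing + below-LOD fraction *exceeds* 40% (strict inequality — exactly
40% is retained); whether below-LOD cells count toward the 40% is
configurable and on by default; (3) natural-log transform (base is
irrelevant after z-scoring but fixed for reproducibility) and per-column
z-scoring with the sample (ddof = 1) standard deviation, with fitted
means/SDs stored for held-out data. Structurally missing cells that
survive the filter are handled by complete-case row deletion by default;
mean imputation exists but is off. A creatinine-correction hook divides
urine analyte columns by a supplied creatinine vector for data not
already corrected upstream.

## Numerical choices and edge cases

- λ_max is nudged up by one part in 10¹⁰ so "λ ≥ λ_max ⇒ all-zero" holds
  exactly in floating point.
- Exact CV ties resolve to larger λ, then smaller γ (sparser first);
  deterministic.
- Zero-variance columns: standardization substitutes SD 1 (relevant for
  near-constant one-hot confounders); all-zero design columns keep
  coefficient 0; a constant outcome raises a degenerate-data error.
- Support is defined by exact zeros of the standardized-scale
  coefficients (hard zeros from the soft-threshold update), never by
  thresholding floats.
- VIMP permutation streams are keyed to the *name* of the variable (via
  a stable CRC32) and the forest is grown on name-sorted columns, so
  importances are exactly invariant to the order columns arrive in.
- Degenerate screens (nothing kept) fall back to the single-step
  analysis with a logged warning; an empty selected support is a legal
  result (null model), reported rather than raised.
- The coordinate-descent inner loop is JIT-compiled with numba when
  available; a pure-Python equivalent runs otherwise.

## Problem sizes used in the test suite

Stochastic guarantees are checked at the designs' native scale
(n = 500, 20 predictors) with 50 replicates for null behavior and
support recovery; forests use 500–1000 trees there and 150–300 trees in
smaller unit fixtures; nested-CV performance checks run at n ≈ 120–200
with K = 4 folds and shortened λ paths. These sizes were chosen to make
the Monte-Carlo assertions stable while keeping the suite comfortably
runnable on a laptop core.

## Known limitations

- The second stage captures only linear (and specified product) effects;
  a nonlinear relationship that survives the forest screen will be
  approximated linearly or dropped.
- Under very high collinearity (|r| > 0.8) all three workflows misselect;
  the package warns and recommends removing one member of each highly
  correlated pair upstream, but does not do so automatically.
- Confidence intervals are naive post-selection refits (see above).
- The elastic net, group penalties, generalized-linear outcomes, and
  repeated-measures designs are out of scope.
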