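# mixselect

Two-step variable selection for chemical-mixture exposure studies:
a regression **random forest** screens candidate exposures by permutation
variable importance, and the **adaptive lasso** then selects and
quantifies main effects and pairwise interactions among the survivors.

## The problem

Biomonitoring studies measure dozens of correlated chemical exposures
(metals in blood, serum and urine, say) on a few hundred participants and
ask which components of the mixture — alone or in interaction — drive a
continuous health outcome. Ordinary regression handles neither the
dimensionality nor the collinearity; the lasso over-selects under
correlation and biases large coefficients; and expanding all pairwise
products (190 terms for 20 exposures) makes the multiplicity problem
worse. Screening first, with a learner that tolerates correlation and
nonlinearity, shrinks the search space before the penalized fit.

## The method

Stage 1 grows a random forest on the candidate exposures and computes,
for each variable *j*, the permutation importance

> VIMP_j = mean over trees of (out-of-bag MSE with X_j permuted − out-of-bag MSE),

keeping the variables whose VIMP is positive (better than noise; top-*k*
and fraction-of-max rules are also available). Confounders bypass
screening entirely.

Stage 2 solves the adaptive lasso on the retained variables (plus their
pairwise products, if requested):

> β̂ = argmin_β ‖y − Σ_j x_j β_j‖² + λ Σ_j w_j |β_j|,  w_j = |β̂_j^initial|^(−γ)

with first-stage estimates β̂^initial from OLS (or ridge under
multicollinearity), solved by cyclic coordinate descent, and the pair
(γ, λ) tuned jointly by K-fold cross-validation over a two-dimensional
grid. Confounders enter with w_j = 0 (never penalized). A naive OLS
refit on the selected support supplies coefficient estimates and Wald
95% confidence intervals.

Comparator workflows (single-step adaptive lasso; CART screening with
1-SE cost-complexity pruning followed by adaptive lasso) and the
evaluation metrics used to benchmark them — R², adjusted R², MSE, and
fold-weighted cross-validated MSE / MSPE — are included, as are
synthetic-data generators for the block-correlated designs the method is
validated on.

## Worked example

```python
import mixselect as mx

# 500 samples, 20 block-correlated exposures, six true main effects
# (X1, X2, X12, X15 positive; X9, X16 negative) and a synergistic
# X1*X12 interaction; population R^2 of the true model is 0.30.
ds = mx.simulate_dataset(mx.dataset2_default(), seed=11)

cfg = mx.AnalysisConfig(method="rf_alasso", with_interactions=True, seed=11)
res = mx.run_two_step(ds, cfg)
print(res.support)
print(res.performance)
```

prints (abridged):

```
selected support: ['X1', 'X2', 'X9', 'X12', 'X15', 'X16', 'X1:X12', 'X2:X17', 'X3:X20']
R2=0.353 adjR2=0.341 MSE=0.953 MSE.CV=0.946 MSPE.CV=1.008

       term  estimate    se  ci_low  ci_high
(Intercept)    -0.026 0.043  -0.111    0.059
         X1     0.302 0.045   0.214    0.391
         X2     0.236 0.043   0.152    0.319
         X9    -0.267 0.043  -0.352   -0.182
        X12     0.243 0.044   0.156    0.329
        X15     0.201 0.044   0.115    0.286
        X16    -0.236 0.045  -0.324   -0.148
     X1:X12     0.309 0.044   0.223    0.395
     X2:X17    -0.104 0.044  -0.191   -0.017
     X3:X20    -0.110 0.044  -0.195   -0.024
```

All six true main effects and the true X1:X12 interaction are selected
with the correct signs (true coefficient magnitude 0.240); two null
product terms slip in with small estimates, the typical residual false
discovery when 120 interaction candidates are searched at this
signal-to-noise level. The fit explains ~34% of outcome variance and the
cross-validated prediction error (MSPE.CV ≈ 1.01) sits at the noise
floor (σ² = 1).

The same workflows run from the shell:

```bash
mixselect simulate --design dataset2 --seed 11 --out-prefix sim
mixselect analyze --input sim_data.csv --method rf_alasso \
    --interactions --seed 11 --out-dir run/
mixselect compare --input sim_data.csv --seed 11 --out comparison.tsv
```

`analyze` writes `coefficients.tsv`, `ci_table.tsv`, `vimp.tsv`,
`performance.json` and `screen.json`; `compare` runs all three methods
with and without interactions under one shared CV plan. A `preprocess`
subcommand applies the quality-control rules for raw concentration
tables: below-detection-limit values imputed as LOD/√2, exclusion of
variables with more than 40% missing or censored cells, natural-log
transform, and z-score standardization.

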