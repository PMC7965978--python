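# crossclass

A Monte Carlo study of what happens when one factor of a two-way
cross-classified random effects model (CCREM) is ignored and the data are
analyzed with an ordinary hierarchical linear model (HLM).

Individuals often carry two non-nested memberships at once — students belong
to a school *and* a feeder neighborhood, patients to a physician *and* a
clinic.  The correct model gives each factor its own random intercept:

    Y_ijk = γ000 + γ100·X_ijk + γ010·W_j + γ020·Z_k + b_0j0 + c_00k + e_ijk

with b ~ N(0, τ_col), c ~ N(0, τ_row), e ~ N(0, σ²).  The misspecified
analysis keeps a single random intercept on one factor and demotes the other
factor's predictor to the individual level.  This package generates
cross-classified data with feeder-structured membership (each "column" group
draws its members from f "row" groups), fits both models by full maximum
likelihood, and quantifies:

* relative parameter bias (θ̄ − θ)/θ and relative SE bias
  (mean model SE − empirical SD)/empirical SD, per condition × model ×
  parameter, with the |0.05| / |0.10| acceptability flags;
* AIC/BIC (deviance + 2q, deviance + ln N·q) correct-identification rates;
* factorial-ANOVA screening of the bias metrics over the six design factors
  (coefficient magnitude, feeders, residual correlation, group count, group
  size, IUCC) with partial η² effect sizes.

The design grid crosses 3×3×2×2×2×2 = 144 conditions; the full published
profile runs 500 replications per cell, and reduced profiles are the
default here.  The mixed-model fitter is the package's own profiled-ML
implementation (Woodbury reduction to group-level cross-products, analytic
gradients), verified against a dense-matrix oracle and lme4.

## Worked example

`python analysis/02_single_condition_fits.py` generates one dataset from the
condition γ = 0.2, J = K = 30 groups, mean size 20, IUCC 0.15
(τ_col = τ_row = 0.2143), residual correlation 0.4, two feeders, and fits
both models:

```
condition mc0.2_fd2_rho0.4_ng30_gs20_iucc0.15: N = 614
truth: tau_col = tau_row = 0.2143, sigma2 = 1, rho = 0.4

crossed fit (q = 7, deviance = 1859.69)
  intercept   99.9983  (SE 0.7927)
  slope_x      0.1988  (SE 0.0041)
  slope_w      0.2007  (SE 0.0083)
  slope_z      0.1962  (SE 0.0125)
  sigma2_e     1.0533
  tau_col      0.2010
  tau_row      0.2997

nested fit (q = 6, deviance = 1922.90)
  intercept  100.2270  (SE 0.6877)
  slope_x      0.1985  (SE 0.0044)
  slope_w      0.1991  (SE 0.0105)
  slope_z      0.1949  (SE 0.0060)
  sigma2_e     1.2143
  tau_col      0.3986
```

Both models recover the fixed effects, but the misspecified fit inflates its
single level-2 variance (0.40 vs the generating 0.21) and the level-1
residual (1.21 vs 1.00), and its model SE for the demoted predictor z drops
to 0.0060 from the crossed model's 0.0125 — the anticonservative SE that
makes this misspecification dangerous.  Across replications
(`analysis/05_headline_aggregates.py`, 144 conditions × 50 replications)
those single-fit symptoms become aggregate numbers: mean SE bias −0.49 for
the demoted predictor z and −0.19 for the intercept, level-2 parameter bias
+0.18 and level-1 +0.09 on the zero-correlation half-grid, while the
correctly specified crossed fits stay unbiased and calibrated.

Other drivers: `analysis/01_design_grid.py` (grid export),
`analysis/03_grid_study.py [reps]` (full-grid study with bias/selection/
ANOVA tables under `results/study/`), `analysis/04_example_condition.py`
(500-replication single-condition variance comparison),
`analysis/05_headline_aggregates.py [reps]` (the aggregate numbers above).
A `crossclass` CLI exposes the same steps (`grid`, `simulate`, `fit`,
`study`, `anova`, `report`).

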