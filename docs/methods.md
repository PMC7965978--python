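# Methods

## The problem

Individuals often belong to two non-nested grouping factors at once —
students to the school they attend and the neighborhood they come from,
patients to a treating physician and a home clinic.  A two-way
cross-classified random effects model (CCREM) gives each factor its own
random intercept.  Analysts frequently drop one factor (because its
identifier was never collected, or to simplify the model) and fit an
ordinary hierarchical linear model (HLM) on the remaining one.  This package
is a Monte Carlo study of what that misspecification costs: bias in point
estimates, bias in model standard errors, and the ability of AIC/BIC to flag
the richer model as correct.

## Generating model

For individual *i* in column group *j* (receiver, e.g. school) and row group
*k* (feeder, e.g. neighborhood):

    Y_ijk = γ000 + γ100·X_ijk + γ010·W_j + γ020·Z_k + b_j + c_k + e_ijk

with X (individual), W (receiver-level) and Z (feeder-level) predictors all
drawn N(50, 10²) and not centered; b_j ~ N(0, τ_col), c_k ~ N(0, τ_row),
e ~ N(0, σ²).  The intercept is fixed at 100, σ² = 1, and the three slopes
share one value γ ∈ {0.2, 0.5, 0.8} (the "magnitude of coefficients"
factor).

The misspecified analysis keeps the receiver factor as its only level-2
structure — the classic "students nested in schools, neighborhoods ignored"
situation.  W therefore stays a cluster-level predictor, while Z is demoted
to the individual level and the feeder grouping is discarded.  (Published
accounts of this design label the factors inconsistently; retaining the
receiver is the reading under which the misspecification has the magnitudes
this design is known for.  Retaining the feeder instead makes the retained
groups' absorbed receiver effects cross-correlated — each receiver feeds
several retained groups — which attenuates both the variance overestimation
and the SE underestimation by roughly a third.  Both variants are available
via the ``retained`` switch.)

Membership is feeder-structured: each of the J column groups draws f
distinct feeder rows uniformly from the K rows (J = K in every condition),
and each of its members picks one of those f feeders uniformly.  Column
group sizes are drawn N(20 or 40, SD 2), rounded and floored at 1.  Row
groups that receive nobody stay in the design with zero records; fits use
the observed levels only.

### Level-2 variances and the IUCC

Both factors share a per-factor variance τ chosen so that the intra-unit
correlation coefficient (IUCC) τ/(2τ + σ²) equals 0.05 or 0.15, giving
τ = 0.0556 and 0.2143 at σ² = 1.  Note the alternative "total" convention
(τ_col + τ_row)/(τ_col + τ_row + σ²) evaluates to exactly 2·IUCC (0.10 /
0.30) for the same variances; the grid export records both ratios so there
is no ambiguity about which convention the labels refer to.

### Correlated level-2 residuals

Half the conditions make the two residual sets dependent (ρ = 0.4).  A
correlation between b and c only has observable consequences if it runs
along the membership links, and there are several defensible generators.
The package implements two:

* **aggregate** (default): b_j = ρ·Σ_{k∈feeders(j)} c_k/√(f·τ) ·√τ +
  √(1−ρ²)·√τ·η_j.  Marginal variances are preserved and the correlation
  between a column group's residual and the standardized combined residual
  of its own feeders is exactly ρ — the "school effect tracks its catchment
  area" reading.  Under this mechanism the misspecified model's single
  level-2 variance absorbs both the scattered b variance and the b–c
  covariance, reproducing the characteristic overestimation pattern
  (roughly τ(1 + 1/f + 2ρ/√f) at the example condition).
* **matched**: index-matched bivariate pairs (b_j, c_j) with correlation ρ
  (requires J = K).  Because the pairing is independent of the (random)
  feeder map, the induced covariance between a row's residual and the
  residuals of the columns feeding it is O(1/K) — the correlation is nearly
  invisible to either fitted model.  It is kept for comparison and for the
  unit contract of `generate_level2_effects`.

The aggregate mechanism is the default because it is the one under which the
correlated conditions actually differ from the independent ones in the
fitted models — which is the point of including ρ in the design — and under
it the single-condition variance comparison reproduces the magnitudes this
design is known for.  With ρ = 0 the mechanisms coincide.

## Estimation

Both models are fitted by full maximum likelihood (not REML).  The fixed
design is [1, x, w, z] in both; the crossed model has V = σ²I +
τ_col·Z_c Z_c' + τ_row·Z_r Z_r' (q = 7 parameters), the misspecified model
keeps a single random intercept on the receiver factor and treats z as a
plain level-1 covariate (q = 6).  Fixed effects are profiled out by GLS and σ² is
profiled analytically, leaving a bounded optimization over the variance
ratios θ = τ/σ² ≥ 0.  Because the random-effect design is indicator-coded,
every likelihood and gradient evaluation reduces via the Woodbury identity
to dense algebra on (J + K)-dimensional group-level cross-products, so a fit
costs milliseconds at any N.

Numerical choices:

* Optimizer: L-BFGS-B on θ with analytic gradients (envelope theorem for the
  residual term, trace identity for log|V|), three fixed starts
  (θ₀ ∈ {0.02, 0.15, 1.0}), ftol 1e-12.  Multi-start guards against
  line-search stalls at the θ = 0 boundary.
* Convergence is declared from first-order (KKT) conditions at the best
  point found — near-zero gradient for interior ratios, non-negative
  gradient at the zero boundary — because L-BFGS-B's own status flag can
  read "abnormal" at boundary optima it has in fact reached.
* Variance estimates are truncated at 0; q is not reduced at the boundary.
* Full-ML variance-component estimates carry the usual finite-sample downward
  shrinkage of order p_between/J (the between-group dimensions spanned by the
  fixed effects — intercept, the cluster predictor, and the group means of
  the demoted covariates — are absorbed before the variance is estimated;
  roughly 10% at J = 30).  REML would remove it but is out of scope here;
  when comparing against results produced by software whose default is REML,
  expect level-2 variance estimates and their biases to sit correspondingly
  lower under this package's full-ML fits.
* Fixed-effect SEs are model-based, √diag(σ̂²(X'V₀⁻¹X)⁻¹), with no
  small-sample (Kenward–Roger/Satterthwaite) adjustment — these are the SEs
  whose calibration the study measures.
* Deviance is −2·max log-likelihood including the 2π constant, so it is
  directly comparable with lme4's ML deviance (a unit test checks this).
* Non-converged replications are dropped from summaries and counted in the
  run manifest; a condition losing more than 10% of its replications raises
  a manifest warning.

The fitter is verified against (a) an explicit N×N dense-covariance oracle
for likelihood values (1e-8) and grid-plus-polish optima (1e-4), and
(b) lme4 via Rscript on a medium dataset.

## Evaluation

* Parameter bias (θ̄ − θ)/θ, flagged at |0.05|; SE bias (mean model SE −
  SD of estimates across replications)/SD, flagged at |0.10|; the empirical
  SD uses R − 1 and the point estimates of the same model being evaluated.
* Variance-component biases are computed only on the ρ = 0 half-grid (under
  ρ = 0.4 the implied population value of the retained component is not
  defined by the generator alone); there the raw means/SDs are reported.
  The misspecified model's single τ is compared against the retained
  factor's generating τ.
* AIC = deviance + 2q, BIC = deviance + ln(N)·q with N the level-1 count;
  smaller wins, ties count against correct identification.  Note that with
  ln(N) > 2 and the crossed model one parameter richer, AIC selects the
  crossed model whenever BIC does, so per-replication BIC hit rates cannot
  exceed AIC hit rates at these sample sizes.
* Screening ANOVA: one row per condition (144 at the full grid; a
  per-replication table is available behind a flag), sum-coded balanced
  factorial with interactions up to order 3 and the remainder as error —
  the error term is a modelling choice and is configurable.  Effect sizes
  are partial η² = SS_eff/(SS_eff + SS_err) with labels at 0.010/0.059/
  0.138 (left-closed).  On the balanced grid all term SS are orthogonal
  (tested to 1e-8 against a projection oracle).

## Reproducibility and problem sizes

Every replication's generator stream derives from (master seed, condition
id, replication index) via a hash into `numpy` SeedSequence, so reruns are
bit-identical regardless of execution order or worker count.

The published profile is 500 replications for each of the 144 conditions.
The package's reduced default profiles are 25 replications per cell for the
quick study driver and 50 per cell for the aggregate checks, with the single
tabulated example condition always run at the full 500.  At 50 replications
the across-condition aggregate biases carry Monte-Carlo noise of roughly
±0.01–0.02 (and the SE-bias ratio estimator a small upward Jensen correction of
about 1.5% of the SE ratio, since the denominator SD is itself estimated),
which is why aggregate checks use absolute tolerances of 0.03.

## What the generator does and does not emulate

It emulates the study conditions exactly: factor levels, feeder structure,
group-size dispersion, predictor scales, residual correlation.  It does not
emulate features of real cross-classified data such as non-normal outcomes,
heteroscedastic residuals, informative group sizes, random slopes, more than
two membership factors, or missing membership identifiers.  Passing tests
therefore certify the estimator implementations and the study's internal
logic, not robustness of CCREM/HLM on data violating these assumptions.

## Known limitations

* J = K throughout; unbalanced numbers of row/column groups are untested.
* The correlated-residual generator is a modelling decision (see above);
  other linkage mechanisms would change the ρ = 0.4 variance comparisons.
* No REML, coverage rates, or Type-I-error tabulations.
* The per-replication ANOVA option inflates effect sizes' denominators with
  within-condition noise; the per-condition default matches how the bias
  metrics are defined.
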