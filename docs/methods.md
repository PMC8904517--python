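# Methods

## The analysis

`slhte` implements a transfer-based heterogeneous treatment effect (HTE)
analysis for a pair of randomized trials that share a baseline covariate
panel and a continuous glycaemic outcome (ΔHbA1c, change from baseline in
percentage points; negative = improvement):

1. **Training.** In the *source* trial, the treated arm is reduced to the
   analysis set (patients with an observed follow-up outcome), the outcome
   is dichotomized at the clinically significant threshold ΔHbA1c ≤ −0.5
   (5.5 mmol/mol), and a Super Learner is fitted to predict responder
   status from 12 baseline covariates: age, male sex, BMI, SBP, DBP,
   hypertension, LDL, HDL, baseline HbA1c, fasting plasma glucose,
   dyslipidemia and adiponectin. Hypertension (SBP ≥ 130 or DBP ≥ 80) and
   dyslipidemia (LDL ≥ 130, HDL < 35, triglyceride ≥ 150, or total
   cholesterol = LDL + HDL + TG/5 ≥ 200) are derived flags; triglycerides
   enter the model only through dyslipidemia.
2. **Transfer.** The fitted ensemble scores every patient of the *target*
   trial (covariates completed by imputation first) with a responder
   probability.
3. **Sweep.** The unique out-of-fold ensemble scores of the training set —
   the ROC operating points — form an ascending cut-off grid with 0
   prepended. Each cut-off keeps the patients (both arms) scoring at or
   above it, giving nested subgroups. In each subgroup a Gaussian
   identity-link linear model `ΔHbA1c ~ arm + adjusters` estimates the
   covariate-adjusted treatment effect with a Wald 95% CI. A flat effect
   trajectory over cut-offs is consistent with a homogeneous effect;
   systematically larger effects in high-probability subgroups indicate
   treatment-effect heterogeneity.

## Super Learner

With candidate learners Ψ₁…Ψ_L, classification error is assessed by
stratified 5-fold cross-validation (appropriate for training sets of a
few dozen patients). All learners are trained on the same 4 folds; their
out-of-fold predictions form the n×L matrix Z. Per-learner risk is
reported both as out-of-fold MSE (averaged over folds) and as 1 − AUC of
the out-of-fold predictions. Non-negative least squares regresses the
observed 0/1 outcome on Z; the solution is normalized to the simplex
(an all-zero NNLS solution falls back to uniform weights with a warning).
Surviving learners are refitted on all rows and combined convexly. This
stacked estimator is asymptotically as accurate as the best single
candidate in its menu (the oracle property); the test suite checks a
finite-sample relaxation (ensemble CV 1−AUC within 0.05 of the best
single learner on a majority of seeds).

The headline ensemble discrimination, `cv_auc`, is the AUC of the
out-of-fold combination Z·w. This is an *internal* CV estimate — the
weights have seen all out-of-fold columns; an honest outer-loop estimate
is available via `nested_cv_auc` / `--nested-cv` and is systematically
lower on small samples.

**Fold construction.** Stratified folds are built by dealing rows
round-robin into folds one outcome class at a time with the dealing
pointer carried across classes. This guarantees both per-class counts and
total fold sizes differ by at most 1 (43 rows in 5 folds always split
9/9/9/8/8); off-the-shelf stratified splitters balance within class only
and can produce 9/9/9/9/7 totals. The within-class order and fold
rotation are seeded.

**AUC** is computed by the rank (Mann–Whitney) identity: pairs with the
positive scored higher count 1, ties 0.5, divided by n₊·n₋. On a
validation set with p positives and q negatives the attainable values lie
on a grid of spacing 1/(2pq) — with 8–9 patients per fold, AUC moves in
coarse steps, which is why per-learner risks on small trials cluster.

**Learner menu.** The default 17-entry menu pairs eight families with and
without random-forest variable screening (top-k impurity importance,
default k = 6 of 12), plus a screened-only elastic net: a Bayesian
sum-of-trees slot, random forest, a single regression tree, bagged trees,
kernel SVM, plain and intercept-only logistic models, and adaptive
regression splines. Implementation notes:

- Boosting (`gbm` family, available for custom menus) uses 500 trees,
  interaction depth 5 and learning rate 0.1.
- The "not adjusted" logistic model is intercept-only: it predicts the
  training prevalence for every patient, anchoring the menu with an
  uninformative-but-calibrated candidate.
- The Bayesian sum-of-trees slot (`bart_like`) is a subsampled
  gradient-boosting surrogate. It is *not* a faithful backfitting-MCMC
  implementation and is flagged as a surrogate in the per-learner report.
- The spline learner is a from-scratch MARS-style model: forward
  stepwise addition of mirrored hinge pairs (interaction degree ≤ 2, knots
  at training quantiles) with backward pruning on the GCV score
  (penalty 3), least-squares fitted on the 0/1 outcome and clipped to
  [0, 1].
- SVM probabilities come from sigmoid (Platt) calibration fitted on
  internal training folds.
- Hyperparameters other than the boosting triple are fixed defaults, not
  tuned per fold.
- A learner that fails on any fold is dropped from the ensemble with a
  logged warning; NNLS runs on the survivors.

## Imputation

Target-trial covariates are completed by chained equations with
random-forest elementary imputers. Each sweep visits the incomplete
variables in a monotone sequence (ascending missing count, ties broken by
schema order; fully observed variables are skipped). Continuous variables
are imputed by drawing one donor at random from the observed rows sharing
the target row's terminal node in a randomly chosen tree; binary
variables by a Bernoulli draw from the forest's class probability. The
initial fill is a random draw from the observed marginal. Defaults: 10
sweeps, 1 completed dataset, 100 trees per imputer. The arm and the
outcome are excluded from the imputation model — the prediction model is
transferred to score covariates only, and conditioning the completed
covariates on the outcome would contaminate the transferred scores. For
m > 1 the per-dataset effect estimates can be averaged; no Rubin's-rules
variance pooling is provided.

## Subgroup effect estimation

- Subgroup membership is score ≥ cut-off (inclusive), ignoring the arm,
  so the randomized comparison is preserved within each subgroup.
- With no adjusters the arm coefficient equals the difference in arm
  means exactly (checked to machine precision).
- The default adjustment set mirrors the covariates used to balance
  allocation in the target trial (prior pharmacological treatment, statin
  use, age, gender, SBP, baseline HbA1c, maximum carotid intima-media
  thickness); entries absent from the shared covariate schema are dropped
  with a warning, leaving age, male, SBP and baseline HbA1c in the
  synthetic setting.
- Aliased design columns are dropped greedily by rank (intercept and arm
  first, so collinear adjusters are the casualties) with a warning.
- A subgroup is estimable only with at least (number of adjusters + 5)
  patients per arm; the sweep truncates at the first non-estimable
  cut-off and certifies nestedness of the retained sets on every run.
- The best cut-off is the one with the largest beneficial (most
  negative) estimated effect among estimable cut-offs.
- No multiplicity adjustment is applied across cut-offs; the trajectory
  is exploratory, mirroring the analysis design.
- Responder contingency tables are compared by Pearson's chi-squared
  without continuity correction (df = 1); a Yates-corrected variant is
  available by flag. Continuous arm comparisons in descriptive tables use
  the two-sided Wilcoxon rank-sum test; quartiles use linear
  interpolation between order statistics (quantile type 7). A
  standardized-mean-difference balance table is emitted for the selected
  subgroup without any pass/fail threshold.

## Synthetic twin trials

The generator draws covariates from location-scale marginals calibrated
to the published quartile summaries of the two diabetes trials (normal
for age, BMI, pressures, LDL, HDL and baseline HbA1c; log-normal for
adiponectin, triglycerides and fasting glucose; Bernoulli(0.68) for male
sex). HDL and triglycerides are not tabulated in those summaries and use
typical type-2-diabetes population values. The outcome model is

    ΔHbA1c = β·(x − μ) + (τ + γ·(x − μ))·1[treated] + ε,   ε ~ N(0, σ²)

with covariates centred at their generating means so that τ stays the
average treatment effect even when γ ≠ 0. Defaults: τ = −0.4 (the scale
of the published arm contrasts), σ = 0.6 (matching the published ΔHbA1c
IQRs), β loading on baseline HbA1c (−0.5 per %) and fasting glucose
(−0.05), γ = 0. Presets: a source trial of 103 patients with ~47%
treatment allocation and ~10% missing outcomes in the treated arm, and a
target trial of 385 patients with ~1:1 allocation and 10% MAR covariate
missingness.

Deliberate simplifications, hence what passing tests do **not** show
about real data:

- Covariates are independent by default (the published sources give no
  joint structure); an optional Gaussian-copula correlation matrix can be
  supplied. Real trials have correlated risk factors, which changes both
  screening behaviour and imputation difficulty.
- MAR missingness is a logistic function of age and baseline HbA1c (the
  always-observed anchors, exempt from masking), chosen so that chained
  equations have a recoverable signal; real missingness may be MNAR.
- The different follow-up horizons of the two trials are modelled as a
  per-trial scalar multiplier on τ (default 1, i.e. the effect transfers
  unchanged) — explicit and togglable, not estimated.
- One outcome per patient; no repeated measures, no vascular endpoints.

## Numerical and design choices

- The responder threshold is inclusive (≤ −0.5) by default, matching the
  reported contingency tables; a strict variant is configurable.
- Every stochastic stage (simulation, fold shuffling, learner seeds,
  imputation draws) derives an independent 31-bit stream from the
  top-level seed via `SeedSequence`, so one seed pins the entire run:
  two runs from one config produce byte-identical CSVs.
- Derived clinical flags are computed after imputation when their inputs
  are missing.
- Model bundles serialize by pickle and round-trip with bit-identical
  predictions.

## Problem sizes

The test suite and the acceptance script run the analysis at desk scale:
training sets of ~40–300 patients, target trials of 200–600, 20-seed
replications for the stochastic properties, 100 seeds for CI coverage at
n = 5000, and calibration checks up to n = 50 000. The published
real-data headline values (e.g. a cross-validated ensemble AUC of 92.05%
on the original source trial) depend on the deposited patient-level data
and are not reproduced here; an ingestion path (`read_trial_csv` with an
arm relabeling map) is provided for users who download them.

## Known limitations

- The Bayesian sum-of-trees learner is a surrogate (see above).
- NNLS weight normalization after optimization is standard stacking
  practice but not exactly the simplex-constrained least-squares optimum
  in degenerate cases; the report carries both risks for transparency.
- Internal `cv_auc` is optimistically biased on small training sets;
  use `--nested-cv` for an honest figure.
- With m > 1 imputations only point-estimate averaging is offered.
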