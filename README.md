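# slhte

Super Learner transfer between randomized trials for heterogeneous
treatment effect (HTE) subgroup targeting.

Average treatment effects from a randomized trial can hide systematic
variation in who benefits. `slhte` implements a transfer-based HTE
analysis for paired trials of an add-on glucose-lowering treatment that
share a baseline covariate panel and a continuous outcome (ΔHbA1c,
percentage points, negative = improvement):

1. train a **Super Learner** — a stacked ensemble Ψ = Σ_l w_l Ψ_l with
   simplex weights w fitted by non-negative least squares on the
   out-of-fold prediction matrix of a stratified 5-fold CV — on the
   treated arm of a *source* trial, predicting clinically significant
   response (ΔHbA1c ≤ −0.5);
2. transfer the model to a *target* trial (covariates completed by
   chained-equation imputation with random-forest imputers) to score each
   patient's responder probability;
3. sweep the training ROC operating points as probability cut-offs,
   forming **nested subgroups** (both arms, score ≥ cut-off), and
   estimate the covariate-adjusted treatment effect
   `ΔHbA1c ~ arm + adjusters` in each.

A flat effect trajectory over cut-offs is consistent with a homogeneous
effect; growing benefit in high-probability subgroups is evidence of
treatment-effect heterogeneity. A synthetic twin-trial generator with
configurable effect heterogeneity, covariate missingness (MCAR/MAR) and
outcome missingness makes every stage testable without any external
data. Intended users: biostatisticians and methods researchers working
on HTE analysis and responder targeting in RCTs.

## Worked example

```python
from slhte import (RunConfig, LearnerSpec, run_pipeline)

config = RunConfig(
    source={"sim": {"n_patients": 103, "allocation_ratio": 48/103,
                    "outcome_missing_rate": 5/48,
                    "gamma": {"hba1c_baseline": -0.5}}},   # planted HTE
    target={"sim": {"n_patients": 385, "missing_rate": 0.10,
                    "missing_mechanism": "MAR",
                    "gamma": {"hba1c_baseline": -0.5}}},
    seed=1,
)
manifest = run_pipeline(config, "scratch/demo")
```

This simulates the twin trials, trains the default 17-learner ensemble on
the treated source-arm analysis set, imputes the target covariates,
scores all 385 target patients and sweeps the cut-off grid. From
`scratch/demo/summary.json` (seed 1):

```json
{
  "best_cutoff": 0.961,
  "best_effect": -0.588,
  "best_ci": [-0.897, -0.279],
  "best_n": [36, 36],
  "full_sample_effect": -0.335,
  "n_train": 39,
  "cv_auc": 0.861
}
```

Read: the ensemble separates responders from non-responders in the
39-patient training set with an (internal) cross-validated AUC of 0.861;
on the full 385-patient target sample the adjusted treatment effect is
−0.335 % HbA1c, while the subgroup of 72 patients scoring above the best
cut-off shows −0.588 [−0.897, −0.279] — the planted interaction is
detected as a larger benefit among model-predicted responders.
`learner_report.csv` lists each learner's CV risk (MSE and 1−AUC) and NNLS
weight; `sweep.csv` is the plot-ready effect trajectory.

The same pipeline is available as a CLI (`slhte run --config run.yaml
--out-dir out/`), with stage-wise subcommands `simulate`, `prepare`,
`impute`, `train`, `sweep` and `report`.

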