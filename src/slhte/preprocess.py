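"""Derived clinical flags, responder dichotomization, analysis-set filtering.

The prediction model uses twelve baseline covariates: age, male sex, BMI,
SBP, DBP, hypertension, LDL, HDL, baseline HbA1c, fasting glucose,
dyslipidemia and adiponectin. Hypertension and dyslipidemia are derived
from the measured pressures and lipids; triglycerides and total
cholesterol enter the model only through the dyslipidemia flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import OUTCOME, TrialDataset

#: model feature columns, in order (flags are derived)
FEATURE_COLUMNS = [
    "age", "male", "bmi", "sbp", "dbp", "hypertension",
    "ldl", "hdl", "hba1c_baseline", "fpg", "dyslipidemia", "adiponectin",
]


@dataclass(frozen=True)
class ResponderRule:
    """Clinically significant HbA1c improvement: change of at least
    -0.5 percentage points (5.5 mmol/mol).

    ``inclusive=True`` counts a change of exactly -0.5 as response.
    """

    threshold: float = -0.5
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold!r}")


def derive_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Hypertension, dyslipidemia and total cholesterol from raw measures.

    hypertension   = SBP >= 130 mmHg or DBP >= 80 mmHg
    total_chol     = LDL + HDL + triglyceride/5  (mg/dl)
    dyslipidemia   = LDL >= 130 or HDL < 35 or triglyceride >= 150
                     or total_chol >= 200

    Row-local and deterministic. Rows with a missing input get missing
    flags (NaN); in the pipeline flags are computed after imputation.
    """
    for col in ("sbp", "dbp", "ldl", "hdl", "triglyceride"):
        if col not in df.columns:
            raise ValueError(f"derive_flags: required column {col!r} absent")
    total_chol = df["ldl"] + df["hdl"] + df["triglyceride"] / 5.0
    htn = (df["sbp"] >= 130) | (df["dbp"] >= 80)
    dys = (df["ldl"] >= 130) | (df["hdl"] < 35) | (df["triglyceride"] >= 150) | (total_chol >= 200)
    htn_in = df[["sbp", "dbp"]].isna().any(axis=1)
    dys_in = df[["ldl", "hdl", "triglyceride"]].isna().any(axis=1)
    return pd.DataFrame({
        "hypertension": htn.astype(float).mask(htn_in),
        "dyslipidemia": dys.astype(float).mask(dys_in),
        "total_cholesterol": total_chol,
    }, index=df.index)


def dichotomize_outcome(delta_hba1c: pd.Series | np.ndarray,
                        rule: ResponderRule = ResponderRule()) -> np.ndarray:
    """Binary responder status from the continuous HbA1c change.

    Raises on missing values: rows without a follow-up outcome must be
    filtered out first (:func:`filter_analysis_set`).
    """
    delta = np.asarray(delta_hba1c, float)
    if np.isnan(delta).any():
        raise ValueError("missing delta_hba1c: filter the analysis set before dichotomizing")
    if rule.inclusive:
        return (delta <= rule.threshold).astype(int)
    return (delta < rule.threshold).astype(int)


def filter_analysis_set(trial: TrialDataset, arm_filter: str | None = None
                        ) -> tuple[TrialDataset, dict]:
    """Drop patients without a follow-up outcome; optionally keep one arm.

    Returns the filtered dataset and a log record with the row accounting.
    Retained cell values are never altered.
    """
    df = trial.df
    n_in = len(df)
    if arm_filter is not None:
        if arm_filter not in ("treatment", "control"):
            raise ValueError(f"arm_filter must be 'treatment' or 'control', got {arm_filter!r}")
        df = df[df["arm"] == arm_filter]
    n_arm = len(df)
    kept = df[df[OUTCOME].notna()]
    report = {
        "rows_in": n_in,
        "rows_after_arm_filter": n_arm,
        "rows_dropped_missing_outcome": int(n_arm - len(kept)),
        "rows_out": len(kept),
        "arm_filter": arm_filter,
    }
    if len(kept) == 0:
        raise ValueError("no analyzable patients (all outcomes missing)")
    return trial.with_df(kept), report


def build_feature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Assemble the model's 12-covariate feature matrix.

    Expects complete covariates (impute first); raises naming any column
    still containing missing values.
    """
    flags = derive_flags(df)
    feats = pd.concat([df, flags[["hypertension", "dyslipidemia"]]], axis=1)
    X = feats[FEATURE_COLUMNS].astype(float)
    incomplete = [c for c in X.columns if X[c].isna().any()]
    if incomplete:
        raise ValueError(f"feature matrix has missing values in {incomplete}; impute covariates first")
    return X
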