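"""Patient-level trial dataset container and CSV round-trip.

A :class:`TrialDataset` wraps a pandas DataFrame with a fixed column
layout: ``patient_id``, ``arm`` ("treatment"/"control"), one column per
schema covariate, and ``delta_hba1c`` (change in HbA1c from baseline,
percentage points, negative = improvement). Missing cells are NaN in
memory and empty fields on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import CovariateSchema, default_schema

ARM_VALUES = ("treatment", "control")
OUTCOME = "delta_hba1c"
META_COLS = ("patient_id", "arm")


@dataclass
class TrialDataset:
    df: pd.DataFrame
    schema: CovariateSchema

    def __post_init__(self) -> None:
        expected = list(META_COLS) + self.schema.names + [OUTCOME]
        missing = [c for c in expected if c not in self.df.columns]
        extra = [c for c in self.df.columns if c not in expected]
        if missing or extra:
            raise ValueError(
                f"trial columns do not match schema: missing={missing}, extra={extra}"
            )
        if self.df["arm"].isna().any():
            raise ValueError("arm must be non-missing for every row")
        bad = set(self.df["arm"].unique()) - set(ARM_VALUES)
        if bad:
            raise ValueError(
                f"arm values outside {ARM_VALUES}: {sorted(bad)} "
                "(use a relabeling map at ingestion)"
            )
        # canonical column order
        self.df = self.df[expected].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.df[self.schema.names]

    @property
    def outcome(self) -> pd.Series:
        return self.df[OUTCOME]

    @property
    def arm(self) -> pd.Series:
        return self.df["arm"]

    @property
    def is_treated(self) -> np.ndarray:
        return (self.df["arm"] == "treatment").to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask over covariate cells (True = missing)."""
        return self.df[self.schema.names].isna()

    def n_per_arm(self) -> dict[str, int]:
        c = self.df["arm"].value_counts()
        return {a: int(c.get(a, 0)) for a in ARM_VALUES}

    def with_df(self, df: pd.DataFrame) -> "TrialDataset":
        return TrialDataset(df.copy(), self.schema)


def write_trial_csv(trial: TrialDataset, path: str | Path) -> None:
    """Write with header, empty fields for missing cells, dot decimals."""
    trial.df.to_csv(path, index=False, na_rep="")


def read_trial_csv(path: str | Path, schema: CovariateSchema | None = None,
                   arm_map: dict[str, str] | None = None) -> TrialDataset:
    """Read a trial CSV written by :func:`write_trial_csv` (lossless round-trip).

    Parameters
    ----------
    arm_map
        Optional relabeling of arm strings (e.g. {"Sitagliptin": "treatment"}).
    """
    schema = schema or default_schema()
    df = pd.read_csv(path)
    if "arm" not in df.columns:
        raise ValueError(f"{path}: no 'arm' column")
    if arm_map:
        df["arm"] = df["arm"].replace(arm_map)
    numeric = schema.names + [OUTCOME]
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: unparseable value {df[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        df[col] = coerced
    return TrialDataset(df, schema)
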