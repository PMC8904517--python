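"""Covariate schema shared by the paired trials.

Both trials collect the same panel of baseline clinical measures; the
analysis relies on that shared schema to transfer a model fitted on one
trial to patients of the other. Variables are either continuous (with a
unit) or binary (0/1 indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # "continuous" | "binary"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"variable {self.name!r}: kind must be 'continuous' or 'binary', got {self.kind!r}")


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered list of baseline covariates.

    The order is meaningful: it is the tie-break order for the imputation
    visit sequence and the canonical column order of every dataset.
    """

    variables: tuple[Variable, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def continuous(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "continuous"]

    @property
    def binary(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "binary"]

    def kind_of(self, name: str) -> str:
        for v in self.variables:
            if v.name == name:
                return v.kind
        raise KeyError(name)


def default_schema() -> CovariateSchema:
    """The shared clinical covariate panel of the two trials.

    age (years), male sex, BMI (kg/m2), systolic and diastolic blood
    pressure (mmHg), LDL and HDL cholesterol (mg/dl), triglycerides
    (mg/dl), baseline HbA1c (%), fasting plasma glucose (mmol/l) and
    adiponectin (mg/l).
    """
    return CovariateSchema((
        Variable("age", "continuous", "years"),
        Variable("male", "binary"),
        Variable("bmi", "continuous", "kg/m2"),
        Variable("sbp", "continuous", "mmHg"),
        Variable("dbp", "continuous", "mmHg"),
        Variable("ldl", "continuous", "mg/dl"),
        Variable("hdl", "continuous", "mg/dl"),
        Variable("triglyceride", "continuous", "mg/dl"),
        Variable("hba1c_baseline", "continuous", "%"),
        Variable("fpg", "continuous", "mmol/l"),
        Variable("adiponectin", "continuous", "mg/l"),
    ))
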