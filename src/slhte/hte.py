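"""Transfer-and-sweep heterogeneous treatment effect analysis.

The fitted outcome model scores every patient of the target trial with a
responder probability. Ascending probability cut-offs define *nested*
subgroups (patients scoring at or above each cut-off, both arms kept);
in each subgroup the treatment effect on the continuous HbA1c change is
estimated by a covariate-adjusted linear model, giving an effect
trajectory over cut-offs. Under a homogeneous true effect the trajectory
is flat; a systematically larger effect in high-probability subgroups is
evidence of treatment-effect heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, mannwhitneyu

from .dataset import OUTCOME, TrialDataset

log = logging.getLogger(__name__)

#: minimum rows per arm beyond the adjuster count for a subgroup to be
#: considered estimable
MIN_EXTRA_PER_ARM = 5


@dataclass(frozen=True)
class ThresholdGrid:
    """Ascending probability cut-offs, always starting at 0 (cut-off 0
    retains the full sample)."""

    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs, float)
        if len(c) == 0 or c[0] != 0.0:
            raise ValueError("grid must start at 0")
        if np.any(np.diff(c) <= 0):
            raise ValueError("cutoffs must be strictly ascending")

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self) -> int:
        return len(self.cutoffs)


def roc_cutoffs(training_scores, max_cutoffs: int | None = None) -> ThresholdGrid:
    """Cut-off grid from the training out-of-fold ensemble scores: the
    sorted unique score values (the ROC operating points), with 0
    prepended. Optionally thinned to ``max_cutoffs`` by quantiles."""
    s = np.asarray(training_scores, float)
    if s.size == 0:
        raise ValueError("empty training scores")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0,1]")
    u = np.unique(s)
    if max_cutoffs is not None and len(u) > max_cutoffs:
        q = np.linspace(0, 1, max_cutoffs)
        u = np.unique(np.quantile(u, q))
    cut = u[u > 0]
    return ThresholdGrid((0.0, *cut.tolist()))


def select_subgroup(target_scores, cutoff: float) -> np.ndarray:
    """Indices of patients with responder probability >= cutoff.

    Selection ignores the arm: both arms are retained, preserving the
    randomized comparison within the subgroup."""
    s = np.asarray(target_scores, float)
    return np.flatnonzero(s >= cutoff)


@dataclass
class SubgroupEffect:
    cutoff: float
    n_treatment: int
    n_control: int
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    estimable: bool = True
    dropped_covariates: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.n_treatment + self.n_control


def _rank_keep(columns: list[tuple[str, np.ndarray]]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily keep design columns that increase matrix rank (the
    intercept and arm indicator come first, so aliased adjusters are the
    ones dropped)."""
    kept_cols: list[np.ndarray] = []
    kept_names: list[str] = []
    dropped: list[str] = []
    rank = 0
    for name, col in columns:
        trial = np.column_stack(kept_cols + [col])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept_cols.append(col)
            kept_names.append(name)
            rank = r
        else:
            dropped.append(name)
    return np.column_stack(kept_cols), kept_names, dropped


def estimate_effect(df: pd.DataFrame, adjustment: list[str] = (),
                    cutoff: float = 0.0) -> SubgroupEffect:
    """Adjusted treatment effect in one subgroup.

    Fits the linear model  delta_hba1c ~ arm + adjusters  (Gaussian,
    identity link) and returns the arm coefficient (treatment minus
    control, % HbA1c units) with its Wald 95% CI and p-value. With no
    adjusters this equals the difference in arm means exactly. Aliased
    adjusters are dropped with a warning; an empty arm makes the result
    non-estimable rather than raising.
    """
    treat = (df["arm"] == "treatment").to_numpy(float)
    n_t, n_c = int(treat.sum()), int(len(df) - treat.sum())
    if n_t == 0 or n_c == 0:
        return SubgroupEffect(cutoff, n_t, n_c, np.nan, np.nan, np.nan, np.nan,
                              estimable=False)
    y = df[OUTCOME].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("missing outcomes in subgroup; filter the analysis set first")
    cols = [("const", np.ones(len(df))), ("arm", treat)]
    for a in adjustment:
        if a not in df.columns:
            raise ValueError(f"adjustment covariate {a!r} not in data")
        col = df[a].to_numpy(float)
        if np.isnan(col).any():
            raise ValueError(f"adjustment covariate {a!r} has missing values; impute first")
        cols.append((a, col))
    X, names, dropped = _rank_keep(cols)
    if dropped:
        log.warning("aliased design columns dropped: %s", dropped)
    if "arm" not in names:  # arm itself aliased with the intercept: degenerate
        return SubgroupEffect(cutoff, n_t, n_c, np.nan, np.nan, np.nan, np.nan,
                              estimable=False, dropped_covariates=dropped)
    res = sm.OLS(y, X).fit()
    i = names.index("arm")
    ci = res.conf_int(alpha=0.05)
    return SubgroupEffect(cutoff, n_t, n_c, float(res.params[i]),
                          float(ci[i, 0]), float(ci[i, 1]), float(res.pvalues[i]),
                          dropped_covariates=dropped)


@dataclass
class ThresholdSweepResult:
    effects: list[SubgroupEffect]
    best_cutoff: float
    nested: bool

    @property
    def best(self) -> SubgroupEffect:
        return next(e for e in self.effects if e.cutoff == self.best_cutoff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"cutoff": e.cutoff, "n": e.n, "n_treatment": e.n_treatment,
             "n_control": e.n_control, "effect": e.effect,
             "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p_value}
            for e in self.effects
        ])


def sweep(target: TrialDataset, scores, grid: ThresholdGrid,
          adjustment: list[str] = ()) -> ThresholdSweepResult:
    """Effect trajectory over the cut-off grid.

    One :class:`SubgroupEffect` per cut-off; the sweep truncates at the
    first non-estimable cut-off (one arm exhausted, or fewer than
    ``len(adjustment) + 5`` patients in either arm). Nestedness of the
    retained sets is certified on every run. The best cut-off is the one
    with the largest beneficial (most negative, i.e. greatest HbA1c
    reduction) estimated effect.
    """
    s = np.asarray(scores, float)
    if len(s) != len(target.df):
        raise ValueError("scores must align with the target trial rows")
    min_per_arm = len(adjustment) + MIN_EXTRA_PER_ARM
    effects: list[SubgroupEffect] = []
    prev: set[int] | None = None
    nested = True
    for cutoff in grid:
        idx = select_subgroup(s, cutoff)
        cur = set(idx.tolist())
        if prev is not None and not cur.issubset(prev):
            nested = False  # unreachable for a valid ascending grid
        prev = cur
        sub = target.df.iloc[idx]
        n_t = int((sub["arm"] == "treatment").sum())
        n_c = len(sub) - n_t
        if min(n_t, n_c) < min_per_arm:
            log.info("sweep truncated at cutoff %.4f: %d/%d per arm below minimum %d",
                     cutoff, n_t, n_c, min_per_arm)
            break
        eff = estimate_effect(sub, adjustment, cutoff=cutoff)
        if not eff.estimable:
            log.info("sweep truncated at non-estimable cutoff %.4f", cutoff)
            break
        effects.append(eff)
    if not effects:
        raise ValueError("no estimable cutoffs in the grid")
    best = min(effects, key=lambda e: e.effect)  # most negative = largest benefit
    return ThresholdSweepResult(effects, best.cutoff, nested)


def contingency_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 responder table (df=1).

    Continuity correction is off by default; enable with ``yates=True``.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    if np.allclose(t[0] / t[0].sum(), t[1] / t[1].sum()):
        # identical proportions: statistic exactly 0, p exactly 1
        return 0.0, 1.0
    stat, p, dof, _ = chi2_contingency(t, correction=yates)
    assert dof == 1
    return float(stat), float(p)


def group_summary(trial: TrialDataset, extra_binary: list[str] = ()) -> pd.DataFrame:
    """Per-arm descriptive table: Q1/median/Q3 for continuous variables
    (with a two-sided rank-sum p-value for the arm comparison), count and
    percentage for binary ones. Quartiles use linear interpolation
    between order statistics."""
    df = trial.df
    arms = {a: df[df["arm"] == a] for a in ("treatment", "control")}
    rows = []
    binary = set(trial.schema.binary) | set(extra_binary)
    for name in trial.schema.names + [OUTCOME]:
        entry: dict = {"variable": name}
        if name in binary:
            for a, sub in arms.items():
                v = sub[name].dropna()
                cnt = int(v.sum())
                pct = 100.0 * cnt / len(v) if len(v) else np.nan
                entry[a] = f"{pct:.0f}% ({cnt})"
            entry["p_value"] = np.nan
        else:
            vals = {}
            for a, sub in arms.items():
                v = sub[name].dropna().to_numpy()
                vals[a] = v
                if len(v):
                    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
                    entry[a] = f"{q1:.2f}/{med:.2f}/{q3:.2f}"
                else:
                    entry[a] = ""
            if len(vals["treatment"]) and len(vals["control"]):
                entry["p_value"] = float(mannwhitneyu(
                    vals["treatment"], vals["control"], alternative="two-sided").pvalue)
            else:
                entry["p_value"] = np.nan
        rows.append(entry)
    return pd.DataFrame(rows)


def balance_table(trial: TrialDataset) -> pd.DataFrame:
    """Standardized mean differences (treatment vs control) per covariate,
    for checking that a selected subgroup preserves arm balance. No
    pass/fail threshold is applied."""
    df = trial.df
    t = df[df["arm"] == "treatment"]
    c = df[df["arm"] == "control"]
    rows = []
    for name in trial.schema.names:
        vt, vc = t[name].dropna(), c[name].dropna()
        sd = np.sqrt((vt.var(ddof=1) + vc.var(ddof=1)) / 2)
        smd = (vt.mean() - vc.mean()) / sd if sd > 0 else 0.0
        rows.append({"variable": name, "mean_treatment": vt.mean(),
                     "mean_control": vc.mean(), "smd": float(smd)})
    return pd.DataFrame(rows)
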