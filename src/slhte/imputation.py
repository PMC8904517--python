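"""Chained-equation imputation with random-forest elementary imputers.

Each sweep visits the incomplete covariates in a *monotone* sequence
(ascending amount of missingness, ties broken by schema order). For each
visited variable a random forest is fitted on the rows where it is
observed, using all other covariates as predictors; missing entries are
then filled stochastically:

* continuous — one donor drawn at random from the observed rows sharing
  the target row's terminal node in a randomly chosen tree;
* binary — a Bernoulli draw from the forest's class probability.

The treatment arm and the outcome never enter the imputation model: the
fitted prediction model is transferred to score covariates only, and
leaking the outcome into the completed covariates would contaminate the
transferred predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._seeds import derive_seed
from .dataset import TrialDataset


@dataclass(frozen=True)
class ImputationConfig:
    n_iterations: int = 10
    n_imputations: int = 1
    rf_trees: int = 100
    visit_sequence: str = "monotone"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.visit_sequence != "monotone":
            raise ValueError(f"unsupported visit_sequence {self.visit_sequence!r}")


@dataclass
class ImputationResult:
    completed: list[TrialDataset]
    missing_counts: dict[str, int]
    visit_order: list[str]
    trace: list[dict[str, list[float]]] = field(default_factory=list)
    """Per imputation: variable -> per-sweep mean of the imputed cells."""


def monotone_visit_sequence(missing_counts: dict[str, int],
                            schema_order: list[str]) -> list[str]:
    """Variables with missingness, sorted ascending by missing count.

    Fully observed variables are excluded; ties keep schema order.
    """
    order = {name: i for i, name in enumerate(schema_order)}
    with_missing = [(cnt, order[name], name)
                    for name, cnt in missing_counts.items() if cnt > 0]
    return [name for _, _, name in sorted(with_missing)]


def _draw_continuous(forest: RandomForestRegressor, P_obs: np.ndarray,
                     y_obs: np.ndarray, P_mis: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    leaves_obs = forest.apply(P_obs)          # (n_obs, n_trees)
    leaves_mis = forest.apply(P_mis)          # (n_mis, n_trees)
    n_trees = leaves_obs.shape[1]
    out = np.empty(len(P_mis))
    for i in range(len(P_mis)):
        t = int(rng.integers(n_trees))
        donors = np.flatnonzero(leaves_obs[:, t] == leaves_mis[i, t])
        if donors.size == 0:  # cannot happen for in-forest leaves; guard anyway
            donors = np.arange(len(y_obs))
        out[i] = y_obs[int(rng.choice(donors))]
    return out


def mice_impute(trial: TrialDataset, config: ImputationConfig = ImputationConfig()
                ) -> ImputationResult:
    """Multiply impute the covariates of a trial dataset.

    Observed cells are preserved exactly; only originally missing cells
    change. Identical ``(trial, config)`` reproduce identical output.
    Raises if any covariate is 100% missing. A dataset without missing
    covariates is returned unchanged with an empty visit order.
    """
    schema = trial.schema
    X0 = trial.covariates.astype(float)
    miss = X0.isna()
    counts = {name: int(miss[name].sum()) for name in schema.names}

    if all(c == 0 for c in counts.values()):
        return ImputationResult([trial.with_df(trial.df)], counts, [])

    fully_missing = [n for n, c in counts.items() if c == len(X0)]
    if fully_missing:
        raise ValueError(f"covariate(s) 100% missing, cannot impute: {fully_missing}")
    if all(counts[n] > 0 for n in schema.names):
        raise ValueError("at least one fully observed covariate is required")

    visit = monotone_visit_sequence(counts, schema.names)
    binary = set(schema.binary)

    completed: list[TrialDataset] = []
    traces: list[dict[str, list[float]]] = []
    for m in range(config.n_imputations):
        rng = np.random.default_rng(derive_seed(config.seed, 0x31CE, m))
        work = X0.copy()
        for name in visit:  # initial fill: random draw from the observed marginal
            obs_vals = X0.loc[~miss[name], name].to_numpy()
            work.loc[miss[name], name] = rng.choice(obs_vals, size=counts[name], replace=True)

        trace: dict[str, list[float]] = {name: [] for name in visit}
        for sweep in range(config.n_iterations):
            for name in visit:
                obs = ~miss[name].to_numpy()
                others = [c for c in schema.names if c != name]
                P = work[others].to_numpy()
                y = work[name].to_numpy()
                rf_seed = derive_seed(config.seed, 0x31CE, m, sweep, schema.names.index(name))
                if name in binary:
                    clf = RandomForestClassifier(n_estimators=config.rf_trees,
                                                 random_state=rf_seed, n_jobs=1)
                    clf.fit(P[obs], y[obs].astype(int))
                    if len(clf.classes_) == 1:
                        draws = np.full((~obs).sum(), float(clf.classes_[0]))
                    else:
                        p1 = clf.predict_proba(P[~obs])[:, list(clf.classes_).index(1)]
                        draws = (rng.random((~obs).sum()) < p1).astype(float)
                else:
                    reg = RandomForestRegressor(n_estimators=config.rf_trees,
                                                random_state=rf_seed, n_jobs=1)
                    reg.fit(P[obs], y[obs])
                    draws = _draw_continuous(reg, P[obs], y[obs], P[~obs], rng)
                work.loc[~obs, name] = draws
                trace[name].append(float(np.mean(draws)))

        out = trial.df.copy()
        out[schema.names] = work
        completed.append(trial.with_df(out))
        traces.append(trace)

    return ImputationResult(completed, counts, visit, traces)
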