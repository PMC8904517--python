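"""End-to-end pipeline driver: simulate/ingest -> prepare -> impute ->
train -> transfer -> sweep -> report, with a JSON manifest of every
artifact written. Two runs from the same config and seed produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .dataset import OUTCOME, TrialDataset, read_trial_csv, write_trial_csv
from .hte import balance_table, contingency_test, group_summary, roc_cutoffs, sweep
from .imputation import ImputationConfig, mice_impute
from .learners import LearnerSpec, default_menu
from .preprocess import (
    ResponderRule,
    build_feature_matrix,
    dichotomize_outcome,
    filter_analysis_set,
)
from .schema import CovariateSchema, default_schema
from .superlearner import SuperLearnerFit, fit_superlearner, nested_cv_auc, sl_predict
from .trial_sim import TrialSimConfig, simulate_trial_pair

log = logging.getLogger(__name__)

#: trial characteristics used to balance allocation in the target trial;
#: entries absent from the shared covariate schema (e.g. prior
#: pharmacological treatment, statin use, carotid intima-media thickness)
#: are dropped with a warning at run time.
DEFAULT_ADJUSTMENT = [
    "prior_pharmacological_treatment", "statin_use",
    "age", "male", "sbp", "hba1c_baseline", "max_carotid_imt",
]


@dataclass
class RunConfig:
    source: dict = field(default_factory=dict)   # {"csv": path} or {"sim": overrides}
    target: dict = field(default_factory=dict)
    responder: ResponderRule = field(default_factory=ResponderRule)
    menu: list[LearnerSpec] | None = None        # None -> default 17-entry menu
    k: int = 5
    nested_cv: bool = False
    imputation: dict = field(default_factory=dict)
    adjustment: list[str] | None = None
    max_cutoffs: int | None = None
    figures: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "responder" in d and isinstance(d["responder"], dict):
            d["responder"] = ResponderRule(**d["responder"])
        if "menu" in d and isinstance(d["menu"], list):
            d["menu"] = [parse_menu_entry(e) for e in d["menu"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def parse_menu_entry(entry: dict) -> LearnerSpec:
    e = dict(entry)
    return LearnerSpec(
        name=e["name"], family=e["family"],
        hyperparameters=e.get("hyperparameters", {}),
        screen=bool(e.get("screen", False)),
        screen_k=int(e.get("screen_k", 6)),
    )


@dataclass
class ModelBundle:
    """Everything needed to score new patients: the fitted ensemble, the
    feature schema, the training out-of-fold scores (the source of the
    cut-off grid) and the responder rule. Round-trips through pickle with
    bit-identical predictions."""

    fit: SuperLearnerFit
    feature_columns: list[str]
    schema_names: list[str]
    responder: ResponderRule
    version: str = "1"

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh, protocol=4)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} is not a model bundle")
        return bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_trial(side: dict, label: str, schema: CovariateSchema,
                sim_pair: dict[str, TrialDataset]) -> TrialDataset:
    if "csv" in side:
        return read_trial_csv(side["csv"], schema, arm_map=side.get("arm_map"))
    if label in sim_pair:
        return sim_pair[label]
    raise ValueError(f"{label}: config must provide 'csv' or 'sim'")


def resolve_adjustment(requested: list[str] | None, available: list[str]) -> list[str]:
    req = DEFAULT_ADJUSTMENT if requested is None else list(requested)
    kept = [a for a in req if a in available]
    dropped = [a for a in req if a not in available]
    if dropped:
        log.warning("adjustment covariates absent from the shared schema, dropped: %s", dropped)
    return kept


def run_pipeline(config: RunConfig, outdir: str | Path,
                 schema: CovariateSchema | None = None) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``). Any
    stage failure aborts with a stage-named error; files already written
    are recorded next to a ``manifest.partial`` marker.
    """
    schema = schema or default_schema()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    marker = out / "manifest.partial"
    marker.write_text("run in progress\n")

    def emit_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs[name] = _sha256(path)

    stage = "simulate/ingest"
    try:
        sim_pair: dict[str, TrialDataset] = {}
        if "sim" in config.source or "sim" in config.target:
            src_cfg = TrialSimConfig(**{"seed": derive_seed(config.seed, 1),
                                        **config.source.get("sim", {})})
            tgt_cfg = TrialSimConfig(**{"seed": derive_seed(config.seed, 2),
                                        **config.target.get("sim", {})})
            s, t = simulate_trial_pair(src_cfg, tgt_cfg, schema)
            sim_pair = {"source": s, "target": t}
        source = _load_trial(config.source, "source", schema, sim_pair)
        target = _load_trial(config.target, "target", schema, sim_pair)
        for label, trial in (("source", source), ("target", target)):
            path = out / f"{label}.csv"
            write_trial_csv(trial, path)
            outputs[f"{label}.csv"] = _sha256(path)

        stage = "prepare"
        train_set, src_report = filter_analysis_set(source, arm_filter="treatment")
        target_set, tgt_report = filter_analysis_set(target)
        prep = {"source_treated": src_report, "target": tgt_report}
        (out / "prepare_report.json").write_text(json.dumps(prep, indent=2) + "\n")
        outputs["prepare_report.json"] = _sha256(out / "prepare_report.json")
        if train_set.missing_mask.any().any():
            raise ValueError("source training covariates contain missing values")

        stage = "impute"
        imp_cfg = ImputationConfig(**{"seed": derive_seed(config.seed, 3),
                                      **config.imputation})
        imp = mice_impute(target_set, imp_cfg)
        target_complete = imp.completed[0]
        emit_csv(target_complete.df, "target_imputed.csv")
        (out / "impute_report.json").write_text(json.dumps(
            {"missing_counts": imp.missing_counts, "visit_order": imp.visit_order,
             "n_imputations": len(imp.completed)}, indent=2) + "\n")
        outputs["impute_report.json"] = _sha256(out / "impute_report.json")

        stage = "train"
        menu = config.menu if config.menu is not None else default_menu()
        X_train = build_feature_matrix(train_set.df)
        y_train = dichotomize_outcome(train_set.outcome, config.responder)
        fit = fit_superlearner(menu, X_train, y_train, k=config.k,
                               seed=derive_seed(config.seed, 4))
        emit_csv(fit.report(), "learner_report.csv")
        train_info = {"n_train": len(X_train), "cv_auc": fit.cv_auc,
                      "dropped_learners": fit.dropped}
        if config.nested_cv:
            train_info["nested_cv_auc"] = nested_cv_auc(
                menu, X_train, y_train, k=config.k, seed=derive_seed(config.seed, 5))
        bundle = ModelBundle(fit, list(X_train.columns), schema.names, config.responder)
        bundle.save(out / "model_bundle.pkl")
        outputs["model_bundle.pkl"] = _sha256(out / "model_bundle.pkl")

        stage = "sweep"
        X_target = build_feature_matrix(target_complete.df)
        scores = sl_predict(fit, X_target)
        grid = roc_cutoffs(fit.oof_ensemble_scores, max_cutoffs=config.max_cutoffs)
        adjustment = resolve_adjustment(config.adjustment, list(target_complete.df.columns))
        result = sweep(target_complete, scores, grid, adjustment)
        emit_csv(result.to_frame(), "sweep.csv")

        stage = "report"
        responders = dichotomize_outcome(target_complete.outcome, config.responder)
        treated = target_complete.is_treated
        table = [[int(responders[~treated].sum()), int((~treated).sum() - responders[~treated].sum())],
                 [int(responders[treated].sum()), int(treated.sum() - responders[treated].sum())]]
        chi2, p = contingency_test(table)
        best_idx = select_best_rows(scores, result.best_cutoff)
        best_sub = target_complete.with_df(target_complete.df.iloc[best_idx])
        emit_csv(group_summary(best_sub), "subgroup_summary.csv")
        emit_csv(balance_table(best_sub), "subgroup_balance.csv")
        summary = {
            "responder_table": table,
            "responder_chi2": chi2, "responder_p": p,
            "best_cutoff": result.best_cutoff,
            "best_effect": result.best.effect,
            "best_ci": [result.best.ci_low, result.best.ci_high],
            "best_n": [result.best.n_treatment, result.best.n_control],
            "full_sample_effect": result.effects[0].effect,
            "adjustment_used": adjustment,
            **train_info,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        outputs["summary.json"] = _sha256(out / "summary.json")

        if config.figures:
            _make_figures(result, target_complete, scores, out, outputs)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": "1",
        "seed": config.seed,
        "config": _config_echo(config),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    marker.unlink()
    return manifest


def select_best_rows(scores, cutoff: float) -> np.ndarray:
    return np.flatnonzero(np.asarray(scores, float) >= cutoff)


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["responder"] = {"threshold": config.responder.threshold,
                      "inclusive": config.responder.inclusive}
    if config.menu is not None:
        d["menu"] = [{"name": s.name, "family": s.family, "screen": s.screen}
                     for s in config.menu]
    return d


def _make_figures(result, target: TrialDataset, scores, out: Path,
                  outputs: dict[str, str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.errorbar(frame["cutoff"], frame["effect"],
                yerr=[frame["effect"] - frame["ci_low"], frame["ci_high"] - frame["effect"]],
                fmt="o-", capsize=3)
    ax.axhline(0.0, color="grey", lw=0.8)
    for _, row in frame.iterrows():
        ax.annotate(str(int(row["n"])), (row["cutoff"], row["ci_low"]),
                    textcoords="offset points", xytext=(0, -12), ha="center", fontsize=7)
    ax.set_xlabel("responder-probability cut-off")
    ax.set_ylabel("adjusted treatment effect on ΔHbA1c (%)")
    fig.tight_layout()
    fig.savefig(out / "figure1.png", dpi=150)
    plt.close(fig)
    outputs["figure1.png"] = _sha256(out / "figure1.png")

    s = np.asarray(scores, float)
    cutoffs = [e.cutoff for e in result.effects]
    fig, axes = plt.subplots(len(cutoffs), 1, figsize=(7, 1.6 * len(cutoffs)),
                             sharex=True, squeeze=False)
    for ax, c in zip(axes[:, 0], cutoffs):
        sub = target.df[s >= c]
        for arm, color in (("control", "C0"), ("treatment", "C1")):
            vals = sub.loc[sub["arm"] == arm, OUTCOME].dropna()
            ax.hist(vals, bins=30, alpha=0.5, color=color, label=arm, density=True)
        ax.axvline(-0.5, color="red", ls="--", lw=0.8)
        ax.set_ylabel(f"≥{c:.2f}", fontsize=8)
    axes[0, 0].legend(fontsize=7)
    axes[-1, 0].set_xlabel("ΔHbA1c (%)")
    fig.tight_layout()
    fig.savefig(out / "figure2.png", dpi=150)
    plt.close(fig)
    outputs["figure2.png"] = _sha256(out / "figure2.png")
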