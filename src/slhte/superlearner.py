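"""Cross-validated stacking (Super Learner) with NNLS meta-weights.

Every candidate learner is trained on the same k-1 folds and its
out-of-fold predictions retained; per-learner risk is reported both as
mean squared error (the loss the meta-learner minimizes) and as 1-AUC
(the discrimination error). Non-negative least squares regresses the
observed outcome on the out-of-fold prediction matrix, the weights are
normalized to the simplex, and each surviving learner is refitted on the
full data. The resulting convex combination is asymptotically as
accurate as the best single candidate in the menu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls
from scipy.stats import rankdata

from ._seeds import derive_seed
from .learners import FittedLearner, LearnerSpec, fit_learner

log = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Area under the ROC curve as the probability of concordance.

    Each (positive, negative) pair contributes 1 if the positive scores
    higher, 0.5 on a tie; the total is divided by n_pos * n_neg.
    Computed via the rank (Mann-Whitney) identity.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc requires both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class CVFolds:
    k: int
    assignment: np.ndarray  # per-row fold index in [0, k)
    stratified: bool
    seed: int

    def split(self):
        for f in range(self.k):
            test = np.flatnonzero(self.assignment == f)
            train = np.flatnonzero(self.assignment != f)
            yield train, test


def make_folds(y, k: int = 5, seed: int = 0, stratified: bool = True) -> CVFolds:
    """Stratified fold assignment with maximally balanced sizes.

    Rows are dealt round-robin into folds, one outcome class at a time,
    with the dealing pointer carried across classes: both the per-class
    counts and the total fold sizes differ by at most 1 (e.g. 43 rows in
    5 folds always gives sizes {9,9,9,8,8}). The within-class order and
    the fold rotation are shuffled deterministically under the seed.
    """
    y = np.asarray(y, int)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(derive_seed(seed, 0xF01D))
    assignment = np.empty(n, int)
    fold_cycle = rng.permutation(k)
    ptr = int(rng.integers(k))
    if stratified:
        if len(np.unique(y)) < 2:
            raise ValueError("stratified folds require both classes present")
        class_groups = [np.flatnonzero(y == c) for c in (1, 0)]
    else:
        class_groups = [np.arange(n)]
    for idx in class_groups:
        idx = idx.copy()
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = fold_cycle[ptr % k]
            ptr += 1
    return CVFolds(k, assignment, stratified, seed)


@dataclass
class SuperLearnerFit:
    specs: list[LearnerSpec]              # surviving learners, in menu order
    weights: np.ndarray                   # simplex weights over survivors
    oof_matrix: np.ndarray                # n x L out-of-fold predictions
    cv_risk_mse: np.ndarray
    cv_risk_one_minus_auc: np.ndarray
    cv_auc: float                         # AUC of the out-of-fold ensemble Z @ w
    refitted: list[FittedLearner]
    folds: CVFolds
    dropped: list[str] = field(default_factory=list)
    y: np.ndarray | None = None

    @property
    def oof_ensemble_scores(self) -> np.ndarray:
        return self.oof_matrix @ self.weights

    def report(self) -> pd.DataFrame:
        """Per-learner risk/weight table plus the ensemble row."""
        rows = [
            {"algorithm": s.name, "screened": s.screen,
             "risk_mse": float(self.cv_risk_mse[i]),
             "risk_1mauc": float(self.cv_risk_one_minus_auc[i]),
             "weight": float(self.weights[i]),
             "note": "surrogate (non-faithful Bayesian sum-of-trees)"
                     if s.family == "bart_like" else ""}
            for i, s in enumerate(self.specs)
        ]
        rows.append({"algorithm": "super_learner", "screened": False,
                     "risk_mse": float(np.mean((self.oof_ensemble_scores - self.y) ** 2))
                     if self.y is not None else np.nan,
                     "risk_1mauc": 1.0 - self.cv_auc, "weight": np.nan, "note": ""})
        return pd.DataFrame(rows)


def cross_validate(specs: list[LearnerSpec], X: pd.DataFrame, y, folds: CVFolds,
                   seed: int = 0):
    """Out-of-fold prediction matrix and per-learner CV risks.

    Screening (when a spec asks for it) is refit inside each training
    fold. A learner that fails on any fold is dropped from the ensemble
    with a logged warning.

    Returns ``(surviving_specs, Z, risk_mse, risk_1mauc, dropped_names)``.
    """
    y = np.asarray(y, int)
    n = len(y)
    Z = np.full((n, len(specs)), np.nan)
    fold_mse = np.zeros((folds.k, len(specs)))
    failed: set[int] = set()
    for f, (train, test) in enumerate(folds.split()):
        for l, spec in enumerate(specs):
            if l in failed:
                continue
            try:
                fitted = fit_learner(spec, X.iloc[train], y[train],
                                     seed=derive_seed(seed, f))
                Z[test, l] = fitted.predict_proba(X.iloc[test])
                fold_mse[f, l] = float(np.mean((Z[test, l] - y[test]) ** 2))
            except Exception as exc:  # noqa: BLE001 - learner failure is data
                failed.add(l)
                log.warning("learner %s failed on fold %d and is dropped: %s",
                            spec.name, f, exc)
    keep = [l for l in range(len(specs)) if l not in failed]
    if not keep:
        raise RuntimeError("every learner failed cross-validation")
    dropped = [specs[l].name for l in sorted(failed)]
    Z = Z[:, keep]
    risk_mse = fold_mse[:, keep].mean(axis=0)
    risk_auc = np.array([1.0 - auc(Z[:, j], y) for j in range(Z.shape[1])])
    return [specs[l] for l in keep], Z, risk_mse, risk_auc, dropped


def nnls_weights(Z: np.ndarray, y) -> np.ndarray:
    """Simplex meta-weights: solve min ||y - Zw||^2 s.t. w >= 0, then
    normalize to sum 1. An all-zero solution falls back to uniform
    weights with a warning."""
    Z = np.asarray(Z, float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("Z must be n x L with at least one learner column")
    w, _ = _scipy_nnls(Z, np.asarray(y, float))
    total = w.sum()
    if total <= 0:
        log.warning("NNLS returned the zero vector; falling back to uniform weights")
        return np.full(Z.shape[1], 1.0 / Z.shape[1])
    return w / total


def fit_superlearner(specs: list[LearnerSpec], X: pd.DataFrame, y,
                     k: int = 5, seed: int = 0) -> SuperLearnerFit:
    """Full stacking pipeline: folds -> out-of-fold matrix -> NNLS weights
    -> refit survivors on all rows.

    ``cv_auc`` is the AUC of the out-of-fold ensemble combination Z @ w
    (internal CV; see :func:`nested_cv_auc` for the honest variant).
    """
    y = np.asarray(y, int)
    folds = make_folds(y, k=k, seed=seed)
    survivors, Z, risk_mse, risk_auc, dropped = cross_validate(specs, X, y, folds, seed=seed)
    w = nnls_weights(Z, y)
    refitted = [fit_learner(s, X, y, seed=derive_seed(seed, 0xF011)) for s in survivors]
    cv_auc = auc(Z @ w, y)
    return SuperLearnerFit(survivors, w, Z, risk_mse, risk_auc, cv_auc,
                           refitted, folds, dropped, y)


def sl_predict(fit: SuperLearnerFit, Xnew: pd.DataFrame) -> np.ndarray:
    """Ensemble probability: the weight-convex combination of the
    refitted learners' predictions (bounded row-wise by the component
    min/max)."""
    preds = np.column_stack([fl.predict_proba(Xnew) for fl in fit.refitted])
    return preds @ fit.weights


def nested_cv_auc(specs: list[LearnerSpec], X: pd.DataFrame, y,
                  k: int = 5, seed: int = 0) -> float:
    """Honest ensemble AUC: an outer k-fold loop refits the whole Super
    Learner on each outer-training set and scores the held-out fold."""
    y = np.asarray(y, int)
    outer = make_folds(y, k=k, seed=derive_seed(seed, 0x0E7E2))
    scores = np.full(len(y), np.nan)
    for train, test in outer.split():
        sub = fit_superlearner(specs, X.iloc[train], y[train], k=k,
                               seed=derive_seed(seed, 0x1E57, int(test[0])))
        scores[test] = sl_predict(sub, X.iloc[test])
    return auc(scores, y)
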