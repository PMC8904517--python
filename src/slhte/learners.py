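"""Base-learner registry with a uniform fit / predict-probability contract.

Each learner predicts the probability of treatment response from baseline
covariates. The menu mirrors the ensemble's candidate families — gradient
boosting, elastic-net and plain logistic regression, an intercept-only
("not adjusted") logistic model, adaptive regression splines, random
forest, a single regression tree, bagged trees, a kernel SVM with
calibrated probabilities, and a boosted surrogate for the sum-of-trees
Bayesian slot — each optionally wrapped in random-forest variable
screening. All stochastic learners are seeded for exact reproducibility.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._seeds import derive_seed

FAMILIES = (
    "gbm", "glm_logistic", "glm_logistic_unadjusted", "glmnet_elastic",
    "mars", "random_forest", "cart", "bagging", "svm_kernel", "bart_like",
)

#: boosting settings used throughout: 500 trees of depth 5, shrinkage 0.1
GBM_DEFAULTS = {"n_estimators": 500, "max_depth": 5, "learning_rate": 0.1}

DEFAULT_SCREEN_K = 6


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    family: str
    hyperparameters: Mapping = field(default_factory=dict)
    screen: bool = False
    screen_k: int = DEFAULT_SCREEN_K

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; known: {FAMILIES}")
        if self.screen_k < 1:
            raise ValueError("screen_k must be >= 1")


@dataclass
class FittedLearner:
    spec: LearnerSpec
    model: object
    columns: list[str]          # training schema (all columns, canonical order)
    selected: list[str]         # columns actually fed to the model
    n_train: int

    def predict_proba(self, Xnew: pd.DataFrame) -> np.ndarray:
        """One probability in [0,1] per row; columns are realigned to the
        training schema, so column order in ``Xnew`` is irrelevant."""
        present = list(Xnew.columns)
        missing = [c for c in self.columns if c not in present]
        extra = [c for c in present if c not in self.columns]
        if missing or extra:
            raise ValueError(f"schema mismatch: missing columns {missing}, extra columns {extra}")
        X = Xnew[self.selected].to_numpy(float)
        if np.isnan(X).any():
            raise ValueError("predict_proba: missing values in covariates")
        p = _proba(self.model, X)
        return np.clip(p, 0.0, 1.0)


def _proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    if proba.ndim == 1:
        return proba
    classes = list(getattr(model, "classes_", [0, 1]))
    return proba[:, classes.index(1)]


class _InterceptOnly:
    """The 'not adjusted' logistic model: ignores covariates, predicts the
    training prevalence for every row."""

    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict_proba(self, X):
        return np.full(len(X), self.p_)


class _Mars:
    """Adaptive piecewise-linear basis regression (hinge functions).

    Forward stepwise addition of mirrored hinge pairs h(x_j - t),
    h(t - x_j) — with interaction degree up to 2 via parent bases —
    followed by backward pruning on the generalized cross-validation
    score. Fitted by least squares on the 0/1 outcome; predictions are
    clipped to [0,1].
    """

    def __init__(self, max_terms: int = 11, max_degree: int = 2, penalty: float = 3.0):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.penalty = penalty

    @staticmethod
    def _hinge(x, t, sign):
        return np.maximum(sign * (x - t), 0.0)

    def _basis_matrix(self, X, terms):
        n = len(X)
        B = np.ones((n, len(terms) + 1))
        for i, term in enumerate(terms):
            col = np.ones(n)
            for (j, t, s) in term:
                col *= self._hinge(X[:, j], t, s)
            B[:, i + 1] = col
        return B

    def _gcv(self, sse, n, n_terms):
        c = n_terms + self.penalty * max(n_terms - 1, 0) / 2.0
        denom = (1.0 - min(c, n - 1) / n) ** 2
        return sse / n / denom

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        knots = [np.unique(np.quantile(X[:, j], [0.1, 0.3, 0.5, 0.7, 0.9]))
                 for j in range(p)]
        terms: list[tuple] = []

        def sse_of(term_list):
            B = self._basis_matrix(X, term_list)
            coef, res, rank, _ = np.linalg.lstsq(B, y, rcond=None)
            fitted = B @ coef
            return float(np.sum((y - fitted) ** 2)), coef

        best_sse, _ = sse_of(terms)
        while len(terms) + 2 <= self.max_terms:
            parents = [()] + [t for t in terms if len(t) < self.max_degree]
            cand_best = None
            for parent in parents:
                used = {j for (j, _, _) in parent}
                for j in range(p):
                    if j in used:
                        continue
                    for t in knots[j]:
                        pair = [tuple(list(parent) + [(j, t, +1)]),
                                tuple(list(parent) + [(j, t, -1)])]
                        sse, _ = sse_of(terms + pair)
                        if cand_best is None or sse < cand_best[0]:
                            cand_best = (sse, pair)
            if cand_best is None or cand_best[0] >= best_sse - 1e-12:
                break
            best_sse = cand_best[0]
            terms = terms + cand_best[1]

        # backward pruning on GCV
        best_terms = list(terms)
        best_gcv = self._gcv(best_sse, n, len(terms) + 1)
        current = list(terms)
        cur_sse = best_sse
        while current:
            drop_best = None
            for i in range(len(current)):
                trial = current[:i] + current[i + 1:]
                sse, _ = sse_of(trial)
                if drop_best is None or sse < drop_best[0]:
                    drop_best = (sse, trial)
            cur_sse, current = drop_best
            gcv = self._gcv(cur_sse, n, len(current) + 1)
            if gcv < best_gcv:
                best_gcv, best_terms = gcv, list(current)

        self.terms_ = best_terms
        B = self._basis_matrix(X, best_terms)
        self.coef_, *_ = np.linalg.lstsq(B, y, rcond=None)
        return self

    def predict_proba(self, X):
        B = self._basis_matrix(np.asarray(X, float), self.terms_)
        return np.clip(B @ self.coef_, 0.0, 1.0)


def _build_model(spec: LearnerSpec, seed: int):
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "gbm":
        params = {**GBM_DEFAULTS, **hp}
        return GradientBoostingClassifier(random_state=seed, **params)
    if fam == "glm_logistic":
        return LogisticRegression(penalty=None, max_iter=hp.pop("max_iter", 2000), **hp)
    if fam == "glm_logistic_unadjusted":
        return _InterceptOnly()
    if fam == "glmnet_elastic":
        params = dict(penalty="elasticnet", solver="saga", l1_ratio=0.5, C=1.0,
                      max_iter=10000, random_state=seed)
        params.update(hp)
        return Pipeline([("scale", StandardScaler()),
                         ("glm", LogisticRegression(**params))])
    if fam == "mars":
        return _Mars(**hp)
    if fam == "random_forest":
        params = dict(n_estimators=500, n_jobs=1)
        params.update(hp)
        return RandomForestClassifier(random_state=seed, **params)
    if fam == "cart":
        params = dict(min_samples_leaf=5)
        params.update(hp)
        return DecisionTreeClassifier(random_state=seed, **params)
    if fam == "bagging":
        params = dict(n_estimators=25)
        params.update(hp)
        return BaggingClassifier(estimator=DecisionTreeClassifier(), random_state=seed, **params)
    if fam == "svm_kernel":
        # probability=True fits a monotone (sigmoid) calibration on
        # internal training folds, mapping decision values to [0,1]
        params = dict(kernel="rbf", C=1.0, probability=True, random_state=seed)
        params.update(hp)
        return Pipeline([("scale", StandardScaler()), ("svm", SVC(**params))])
    if fam == "bart_like":
        # boosted surrogate for the Bayesian sum-of-trees slot; flagged
        # non-faithful in reports
        params = dict(n_estimators=200, max_depth=3, learning_rate=0.05, subsample=0.5)
        params.update(hp)
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {fam!r}")


def rf_screen(X: pd.DataFrame, y: np.ndarray, k: int, seed: int = 0,
              n_estimators: int = 200) -> list[str]:
    """Top-k covariates by random-forest impurity importance, in rank order.

    Deterministic under a fixed seed; with an uninformative outcome the
    importances are all ~0 and the (stable) ranking falls back to column
    order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available covariates")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(float), np.asarray(y, int))
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return [X.columns[i] for i in order[:k]]


def fit_learner(spec: LearnerSpec, X: pd.DataFrame, y, seed: int = 0) -> FittedLearner:
    """Fit one base learner, honouring its hyperparameters and optional
    variable screening (screening is refit on the data given here, i.e.
    inside each training fold during cross-validation)."""
    y = np.asarray(y, int)
    classes = set(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("y has a single class; cannot fit a classifier")
    if classes - {0, 1}:
        raise ValueError(f"y must be binary 0/1, got classes {sorted(classes)}")
    if X.isna().any().any():
        raise ValueError("missing values in covariates; impute first")

    columns = list(X.columns)
    if spec.screen:
        selected = rf_screen(X, y, spec.screen_k, seed=derive_seed(seed, 0x5C12EE))
    else:
        selected = columns
    model = _build_model(spec, derive_seed(seed, zlib.crc32(spec.name.encode())))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny folds
        model.fit(X[selected].to_numpy(float), y)
    return FittedLearner(spec, model, columns, selected, len(X))


def default_menu(screen_k: int = DEFAULT_SCREEN_K) -> list[LearnerSpec]:
    """The 17-entry candidate menu: eight families plain + screened, plus
    the screened-only elastic net."""
    menu: list[LearnerSpec] = []
    base = [
        ("bart_like", "sum_of_trees"),
        ("random_forest", "random_forest"),
        ("cart", "cart"),
        ("bagging", "bagging"),
        ("svm_kernel", "kernel_svm"),
        ("glm_logistic", "logistic"),
        ("glm_logistic_unadjusted", "logistic_unadjusted"),
        ("mars", "poly_mars"),
    ]
    for family, label in base:
        menu.append(LearnerSpec(label, family))
        menu.append(LearnerSpec(f"{label}_screen_rf", family, screen=True, screen_k=screen_k))
    menu.append(LearnerSpec("elastic_net_screen_rf", "glmnet_elastic",
                            screen=True, screen_k=screen_k))
    return menu
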