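"""Stacking: folds, out-of-fold risks, NNLS weights, ensemble AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_xy
from slhte import (
    LearnerSpec,
    auc,
    cross_validate,
    fit_superlearner,
    make_folds,
    nnls_weights,
    sl_predict,
)
from slhte.superlearner import SuperLearnerFit


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate every (positive, negative) pair."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------- auc

def test_auc_hand_enumerated_example():
    assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_perfect_and_uninformative():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5


def test_auc_single_class_errors():
    with pytest.raises(ValueError, match="both classes"):
        auc([0.1, 0.2], [1, 1])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_auc_matches_brute_force_with_ties(data):
    n = data.draw(st.integers(3, 30))
    y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)
                  .filter(lambda v: 0 < sum(v) < len(v)))
    # coarse score grid to generate plenty of ties
    s = data.draw(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                           min_size=n, max_size=n))
    assert auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)


def test_auc_values_on_granularity_grid():
    # attainable AUC values are multiples of 1/(2 p q)
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.integers(0, 2, 12)
        if y.sum() in (0, 12):
            continue
        s = rng.choice([0.2, 0.5, 0.8], size=12)
        p, q = int(y.sum()), int(12 - y.sum())
        val = auc(s, y) * 2 * p * q
        assert val == pytest.approx(round(val), abs=1e-9)


# ---------------------------------------------------------------- folds

def test_folds_43_rows_sizes_9_9_9_8_8():
    y = np.array([1] * 30 + [0] * 13)
    folds = make_folds(y, k=5, seed=0)
    sizes = sorted(np.bincount(folds.assignment, minlength=5), reverse=True)
    assert sizes == [9, 9, 9, 8, 8]


def test_folds_per_class_balance():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 57)
    while len(np.unique(y)) < 2:
        y = rng.integers(0, 2, 57)
    folds = make_folds(y, k=5, seed=3)
    for cls in (0, 1):
        counts = np.bincount(folds.assignment[y == cls], minlength=5)
        assert counts.max() - counts.min() <= 1


def test_folds_perfect_stratification_small():
    y = np.array([1, 0] * 5)
    folds = make_folds(y, k=5, seed=2)
    for f in range(5):
        fold_y = y[folds.assignment == f]
        assert sorted(fold_y) == [0, 1]


def test_folds_deterministic_and_errors():
    y = np.array([0, 1] * 10)
    a = make_folds(y, k=4, seed=9).assignment
    b = make_folds(y, k=4, seed=9).assignment
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="exceeds"):
        make_folds(np.array([0, 1]), k=5)


# ---------------------------------------------------------------- cross_validate

def oracle_data(n=60, seed=0):
    """x0 equals y exactly: a deep tree reproduces y out of fold."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame({"x0": y.astype(float), "x1": rng.normal(size=n)})
    return X, y


def test_oracle_learner_zero_risk():
    X, y = oracle_data()
    specs = [LearnerSpec("oracle", "cart", {"min_samples_leaf": 1})]
    folds = make_folds(y, k=5, seed=0)
    _, Z, mse, one_m_auc, dropped = cross_validate(specs, X, y, folds)
    assert mse[0] == pytest.approx(0.0)
    assert one_m_auc[0] == pytest.approx(0.0)
    assert dropped == []


def test_constant_learner_has_half_auc_risk():
    X, y = oracle_data()
    specs = [LearnerSpec("const", "glm_logistic_unadjusted")]
    folds = make_folds(y, k=5, seed=0)
    _, Z, _, one_m_auc, _ = cross_validate(specs, X, y, folds)
    assert one_m_auc[0] == pytest.approx(0.5)


def test_signal_learner_beats_noise_learner_in_mse():
    X, y = make_xy(500, 4, seed=5, signal=2.0)
    Xdf = pd.DataFrame(X, columns=["x0", "x1", "x2", "x3"])
    specs = [LearnerSpec("signal", "glm_logistic"),
             LearnerSpec("noise", "glm_logistic_unadjusted")]
    folds = make_folds(y, k=5, seed=1)
    _, _, mse, _, _ = cross_validate(specs, Xdf, y, folds)
    assert mse[0] < mse[1]


# ---------------------------------------------------------------- nnls

def test_nnls_single_perfect_column():
    y = np.array([0, 1, 1, 0, 1], float)
    w = nnls_weights(y.reshape(-1, 1), y)
    np.testing.assert_allclose(w, [1.0])


def test_nnls_identical_columns_degenerate_contract():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 50).astype(float)
    z = np.clip(y * 0.8 + 0.1, 0, 1)
    Z = np.column_stack([z, z])
    w = nnls_weights(Z, y)
    assert w.sum() == pytest.approx(1.0)
    assert np.all(w >= 0)
    np.testing.assert_allclose(Z @ w, z)  # prediction invariant to the split


def test_nnls_concentrates_on_informative_column():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 200).astype(float)
    noise = rng.random(200)
    Z = np.column_stack([y, noise])
    w = nnls_weights(Z, y)
    assert w[0] > 0.9
    # brute-force simplex grid confirms the optimum sits near (1, 0)
    grid = np.linspace(0, 1, 201)
    sse = [np.sum((y - (g * Z[:, 0] + (1 - g) * Z[:, 1])) ** 2) for g in grid]
    assert grid[int(np.argmin(sse))] > 0.9


def test_nnls_zero_solution_falls_back_to_uniform():
    y = np.ones(10)
    Z = -np.ones((10, 3))  # NNLS optimum is w = 0
    w = nnls_weights(Z, y)
    np.testing.assert_allclose(w, [1 / 3] * 3)


def test_nnls_empty_errors():
    with pytest.raises(ValueError):
        nnls_weights(np.empty((5, 0)), np.zeros(5))


# ---------------------------------------------------------------- fit / predict

def test_superlearner_oracle_plus_constant_is_perfect():
    X, y = oracle_data(n=40, seed=4)
    menu = [LearnerSpec("oracle", "cart", {"min_samples_leaf": 1}),
            LearnerSpec("const", "glm_logistic_unadjusted")]
    fit = fit_superlearner(menu, X, y, k=5, seed=0)
    assert fit.cv_auc == pytest.approx(1.0)
    assert fit.weights.sum() == pytest.approx(1.0)


def test_all_constant_learners_cv_auc_half():
    X, y = oracle_data(n=40, seed=5)
    menu = [LearnerSpec("c1", "glm_logistic_unadjusted"),
            LearnerSpec("c2", "glm_logistic_unadjusted")]
    fit = fit_superlearner(menu, X, y, k=5, seed=0)
    assert fit.cv_auc == pytest.approx(0.5)


class _Stub:
    def __init__(self, preds):
        self.preds = np.asarray(preds, float)

    def predict_proba(self, Xnew):
        return self.preds


def _stub_fit(weights, cols):
    preds = np.column_stack(cols)
    return SuperLearnerFit(
        specs=[], weights=np.asarray(weights, float), oof_matrix=preds,
        cv_risk_mse=np.zeros(len(weights)), cv_risk_one_minus_auc=np.zeros(len(weights)),
        cv_auc=np.nan, refitted=[_Stub(c) for c in cols],
        folds=None)


def test_sl_predict_hand_computed_combination():
    fit = _stub_fit([0.25, 0.75], [[0.2, 0.8, 0.6], [0.4, 0.0, 1.0]])
    np.testing.assert_allclose(sl_predict(fit, pd.DataFrame(index=range(3))),
                               [0.35, 0.2, 0.9])


def test_sl_predict_convexity_bounds():
    rng = np.random.default_rng(6)
    cols = [rng.random(20) for _ in range(3)]
    w = np.array([0.2, 0.5, 0.3])
    fit = _stub_fit(w, cols)
    p = sl_predict(fit, pd.DataFrame(index=range(20)))
    stack = np.column_stack(cols)
    assert np.all(p >= stack.min(axis=1) - 1e-12)
    assert np.all(p <= stack.max(axis=1) + 1e-12)


def test_weights_concentrated_on_one_learner_reproduces_it():
    cols = [np.linspace(0, 1, 7), np.linspace(1, 0, 7)]
    fit = _stub_fit([1.0, 0.0], cols)
    np.testing.assert_allclose(sl_predict(fit, pd.DataFrame(index=range(7))), cols[0])


def test_failed_learner_is_dropped_with_survivors_kept():
    X, y = oracle_data(n=40, seed=7)
    # elastic net with absurd hyperparameter fails; cart survives
    menu = [LearnerSpec("bad", "glmnet_elastic", {"l1_ratio": 42.0}),
            LearnerSpec("good", "cart", {"min_samples_leaf": 1})]
    fit = fit_superlearner(menu, X, y, k=5, seed=0)
    assert fit.dropped == ["bad"]
    assert [s.name for s in fit.specs] == ["good"]
    report = fit.report()
    assert list(report["algorithm"]) == ["good", "super_learner"]
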