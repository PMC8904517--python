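"""Threshold sweep, subgroup effects, contingency and summary reports."""

import numpy as np
import pandas as pd
import pytest

from slhte import (
    ThresholdGrid,
    TrialSimConfig,
    contingency_test,
    estimate_effect,
    group_summary,
    roc_cutoffs,
    select_subgroup,
    simulate_trial,
    sweep,
)
from slhte.hte import balance_table


# ---------------------------------------------------------------- grid

def test_roc_cutoffs_dedupe_and_prepend_zero():
    grid = roc_cutoffs([0.2, 0.2, 0.7])
    assert tuple(grid) == (0.0, 0.2, 0.7)


def test_roc_cutoffs_all_identical():
    assert tuple(roc_cutoffs([0.4, 0.4, 0.4])) == (0.0, 0.4)


def test_roc_cutoffs_distinct_scores_counting():
    rng = np.random.default_rng(0)
    scores = rng.uniform(0.01, 0.99, 43)
    assert len(np.unique(scores)) == 43
    assert len(roc_cutoffs(scores)) == 44


def test_roc_cutoffs_empty_errors_and_thinning():
    with pytest.raises(ValueError, match="empty"):
        roc_cutoffs([])
    rng = np.random.default_rng(1)
    grid = roc_cutoffs(rng.uniform(0.01, 0.99, 200), max_cutoffs=20)
    assert len(grid) <= 21
    assert tuple(grid)[0] == 0.0


def test_threshold_grid_invariants():
    with pytest.raises(ValueError):
        ThresholdGrid((0.1, 0.2))       # must start at 0
    with pytest.raises(ValueError):
        ThresholdGrid((0.0, 0.2, 0.2))  # strictly ascending


# ---------------------------------------------------------------- selection

def test_select_subgroup_boundaries():
    scores = [0.1, 0.5, 0.9]
    np.testing.assert_array_equal(select_subgroup(scores, 0.0), [0, 1, 2])
    np.testing.assert_array_equal(select_subgroup(scores, 0.5), [1, 2])  # inclusive
    assert select_subgroup(scores, 0.95).size == 0


# ---------------------------------------------------------------- effects

def _arm_df(n_t, n_c, delta_t, delta_c, seed=0, **extra):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "arm": ["treatment"] * n_t + ["control"] * n_c,
        "delta_hba1c": np.concatenate([delta_t, delta_c]),
    })
    for k, v in extra.items():
        df[k] = v
    return df


def test_unadjusted_effect_equals_difference_in_arm_means():
    rng = np.random.default_rng(2)
    dt, dc = rng.normal(-0.6, 0.4, 40), rng.normal(-0.2, 0.4, 35)
    eff = estimate_effect(_arm_df(40, 35, dt, dc))
    assert eff.effect == pytest.approx(dt.mean() - dc.mean(), abs=1e-12)
    assert eff.ci_low <= eff.effect <= eff.ci_high


def test_effect_ci_covers_truth_fixed_seed():
    trial = simulate_trial(TrialSimConfig(n_patients=5000, tau=-0.4, seed=3))
    eff = estimate_effect(trial.df)
    assert eff.ci_low <= -0.4 <= eff.ci_high


def test_degenerate_zero_outcome_handled():
    eff = estimate_effect(_arm_df(10, 10, np.zeros(10), np.zeros(10)))
    assert eff.effect == pytest.approx(0.0)
    assert eff.estimable


def test_adjuster_aliased_with_arm_is_dropped():
    rng = np.random.default_rng(4)
    df = _arm_df(20, 20, rng.normal(size=20), rng.normal(size=20))
    df["copy_of_arm"] = (df["arm"] == "treatment").astype(float)
    eff = estimate_effect(df, ["copy_of_arm"])
    assert eff.estimable
    assert eff.dropped_covariates == ["copy_of_arm"]
    unadj = estimate_effect(df.drop(columns="copy_of_arm"))
    assert eff.effect == pytest.approx(unadj.effect)


def test_one_arm_empty_flagged_non_estimable():
    rng = np.random.default_rng(5)
    df = _arm_df(15, 0, rng.normal(size=15), np.array([]))
    eff = estimate_effect(df)
    assert not eff.estimable


def test_adjusted_effect_uses_covariates():
    trial = simulate_trial(TrialSimConfig(n_patients=2000, tau=-0.4, seed=6))
    adj = estimate_effect(trial.df, ["age", "hba1c_baseline"])
    assert adj.ci_low <= -0.4 <= adj.ci_high
    # adjusting for the strong outcome covariate tightens the interval
    unadj = estimate_effect(trial.df)
    assert (adj.ci_high - adj.ci_low) < (unadj.ci_high - unadj.ci_low)


# ---------------------------------------------------------------- sweep

def test_sweep_single_zero_cutoff_equals_full_sample():
    trial = simulate_trial(TrialSimConfig(n_patients=400, seed=7))
    scores = np.random.default_rng(8).uniform(0, 1, 400)
    result = sweep(trial, scores, ThresholdGrid((0.0,)))
    full = estimate_effect(trial.df)
    assert len(result.effects) == 1
    assert result.effects[0].effect == pytest.approx(full.effect)
    assert result.nested


def test_sweep_nested_sizes_monotone_and_truncation():
    trial = simulate_trial(TrialSimConfig(n_patients=300, seed=9))
    rng = np.random.default_rng(10)
    scores = rng.uniform(0, 1, 300)
    grid = roc_cutoffs(scores, max_cutoffs=25)
    result = sweep(trial, scores, grid)
    ns = [e.n for e in result.effects]
    assert all(a >= b for a, b in zip(ns, ns[1:]))
    assert result.nested
    # high cutoffs exhaust an arm: the sweep stops before the grid ends
    assert len(result.effects) < len(grid)


def test_sweep_best_cutoff_is_most_beneficial():
    trial = simulate_trial(TrialSimConfig(n_patients=500, seed=11))
    scores = np.random.default_rng(12).uniform(0, 1, 500)
    result = sweep(trial, scores, roc_cutoffs(scores, max_cutoffs=10))
    assert result.best.effect == min(e.effect for e in result.effects)


# ---------------------------------------------------------------- contingency

def test_published_responder_tables_reproduced():
    # target trial: 57/193 conventional vs 81/192 treated responders
    stat, p = contingency_test([[57, 136], [81, 111]])
    assert round(p, 3) == pytest.approx(0.010, abs=1e-9)
    # source trial: 34/49 vs 30/43
    stat, p = contingency_test([[34, 15], [30, 13]])
    assert abs(p - 0.969) <= 5e-4


def test_identical_proportions_statistic_zero():
    stat, p = contingency_test([[10, 10], [10, 10]])
    assert stat == 0.0 and p == 1.0


def test_contingency_zero_margin_errors():
    with pytest.raises(ValueError, match="margin"):
        contingency_test([[0, 0], [5, 5]])


def test_contingency_agrees_with_permutation_null():
    table = np.array([[40, 60], [55, 45]])  # large enough for the
    # asymptotic chi-squared tail to match the discrete permutation null
    stat, p = contingency_test(table)
    # permutation of group labels, conditioning on the margins
    rng = np.random.default_rng(13)
    n1, n2 = table.sum(axis=1)
    pool = np.concatenate([np.repeat(1, table[0, 0] + table[1, 0]),
                           np.repeat(0, table[0, 1] + table[1, 1])])
    reps = 4000
    exceed = 0
    for _ in range(reps):
        rng.shuffle(pool)
        a = pool[:n1].sum()
        t = np.array([[a, n1 - a], [pool[n1:].sum(), n2 - pool[n1:].sum()]])
        if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
            s, _ = contingency_test(t)
            exceed += s >= stat - 1e-12
    mc_p = exceed / reps
    assert abs(mc_p - p) < 4 * np.sqrt(p * (1 - p) / reps) + 0.01


def test_yates_correction_flag():
    stat_plain, _ = contingency_test([[8, 12], [14, 6]])
    stat_yates, _ = contingency_test([[8, 12], [14, 6]], yates=True)
    assert stat_yates < stat_plain


# ---------------------------------------------------------------- summaries

def test_group_summary_quartiles_and_binary():
    trial = simulate_trial(TrialSimConfig(n_patients=40, seed=14))
    df = trial.df.copy()
    vals = np.arange(1.0, 6.0)  # 1..5 in each arm
    df = df.iloc[:10].copy()
    df["arm"] = ["treatment"] * 5 + ["control"] * 5
    df["age"] = np.concatenate([vals, vals])
    df["male"] = 1.0
    df["delta_hba1c"] = np.concatenate([vals, vals])
    summary = group_summary(trial.with_df(df))
    age_row = summary[summary["variable"] == "age"].iloc[0]
    assert age_row["treatment"] == "2.00/3.00/4.00"  # type-7 quartiles of 1..5
    male_row = summary[summary["variable"] == "male"].iloc[0]
    assert male_row["treatment"] == "100% (5)"
    out_row = summary[summary["variable"] == "delta_hba1c"].iloc[0]
    assert out_row["p_value"] > 0.99  # identical distributions


def test_balance_table_smd_near_zero_in_rct():
    trial = simulate_trial(TrialSimConfig(n_patients=3000, seed=15))
    tbl = balance_table(trial)
    assert set(tbl["variable"]) == set(trial.schema.names)
    assert np.all(np.abs(tbl["smd"]) < 0.15)
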