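"""ROC cutoffs, association tests, regression models and risk scores."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hncpipe import outcome_analysis as oa
from hncpipe import synthetic_data as sd


# ---------------------------------------------------------------------------
# ROC cutoff


def test_perfect_separation_reaches_j_one():
    x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    r = oa.roc_cutoff(x, y)
    assert r.youden_j == pytest.approx(1.0)
    assert 3.0 < r.cutoff < 10.0
    assert r.direction == "above"


def test_enumeration_example_cutoff_between_two_and_three():
    r = oa.roc_cutoff(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]))
    assert r.cutoff == pytest.approx(2.5)
    assert r.youden_j == pytest.approx(1.0)
    assert r.sensitivity == 1.0 and r.specificity == 1.0


def test_cutoff_equals_exhaustive_search_oracle():
    rng = np.random.default_rng(12)
    x = rng.normal(size=60)
    y = rng.random(60) < 0.4
    r = oa.roc_cutoff(x, y)
    # oracle: brute force over all midpoints and both directions
    best_j = -np.inf
    u = np.sort(np.unique(x))
    for c in (u[:-1] + u[1:]) / 2:
        for pred in (x > c, x < c):
            j = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
            best_j = max(best_j, j)
    assert r.youden_j == pytest.approx(best_j, abs=1e-12)


def test_label_permutation_null_j_small():
    rng = np.random.default_rng(77)
    x = rng.normal(size=100)
    y = np.repeat([True, False], 50)
    js = []
    for _ in range(200):
        perm = rng.permutation(y)
        js.append(oa.roc_cutoff(x, perm).youden_j)
    # optimally chosen cutoffs overfit, but the null J stays far from 1
    assert 0 < np.mean(js) < 0.35


def test_degenerate_outcome_rejected():
    with pytest.raises(ValueError):
        oa.roc_cutoff(np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# chi-square association


def test_independence_gives_zero_statistic():
    a = np.repeat([True, True, False, False], 10)
    b = np.tile(np.repeat([True, False], 10), 2)
    res = oa.association_test(a, b)
    assert res["chi2"] == pytest.approx(0.0)
    assert res["p_value"] == pytest.approx(1.0)


def test_perfect_association_closed_form():
    a = np.repeat([True, False], 20)
    res = oa.association_test(a, a)
    assert res["chi2"] == pytest.approx(40.0)


def test_matches_manual_pearson_on_random_tables():
    rng = np.random.default_rng(3)
    a = rng.random(200) < 0.5
    b = rng.random(200) < (0.3 + 0.3 * a)
    res = oa.association_test(a, b)
    obs = res["observed"].astype(float)
    rowsum = obs.sum(1, keepdims=True)
    colsum = obs.sum(0, keepdims=True)
    exp = rowsum * colsum / obs.sum()
    manual = ((obs - exp) ** 2 / exp).sum()
    assert res["chi2"] == pytest.approx(manual, rel=1e-12)
    assert np.allclose(res["expected"], exp)


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        oa.association_test(np.zeros(10, bool), np.repeat([True, False], 5))


# ---------------------------------------------------------------------------
# logistic response model


def _planted_cohort(n, beta, seed, hazard=0.0):
    preds = tuple(
        dataclasses.replace(p, response_log_odds=beta,
                            survival_log_hazard=hazard,
                            dichotomize_at=100.0)
        if p.name == "tlg" else p
        for p in sd.DEFAULT_PREDICTORS
    )
    spec = sd.CohortSpec(n_patients=n, predictors=preds, rng_seed=seed)
    return sd.generate_cohort(spec)[0]


TLG_RULE = oa.CutoffRule("tlg", 100.0, "above", 1.0, 1.0)


def test_single_predictor_fit_equals_table_odds_ratio():
    df = _planted_cohort(500, 1.5, seed=4)
    fit = oa.response_model(df, [TLG_RULE])
    hi = TLG_RULE.apply(df["tlg"])
    pos = (df["response"] == "non_complete").to_numpy()
    tab = np.array([
        [(hi & pos).sum(), (hi & ~pos).sum()],
        [(~hi & pos).sum(), (~hi & ~pos).sum()],
    ], dtype=float)
    or_table = (tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])
    assert fit.iloc[0]["odds_ratio"] == pytest.approx(or_table, rel=1e-6)


def test_perfect_separation_flagged_and_penalized():
    df = pd.DataFrame({
        "tlg": np.concatenate([np.full(20, 200.0), np.full(20, 50.0)]),
        "response": ["non_complete"] * 20 + ["complete"] * 20,
    })
    fit = oa.response_model(df, [TLG_RULE])
    assert bool(fit.iloc[0]["penalized"])
    assert np.isfinite(fit.iloc[0]["odds_ratio"])


# ---------------------------------------------------------------------------
# survival models


def test_km_on_uncensored_data_equals_empirical_survivor():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    km = oa.kaplan_meier(times, np.ones(5, bool))
    for t, frac in [(1.0, 0.8), (3.0, 0.4), (5.0, 0.0)]:
        row = km[km["time"] == t].iloc[0]
        assert row["survival"] == pytest.approx(frac)
    surv = km["survival"].to_numpy()
    assert surv[0] == 1.0
    assert np.all(np.diff(surv) <= 1e-12)


def test_logrank_identical_strata_zero():
    from lifelines.statistics import logrank_test
    t = np.array([2.0, 4.0, 6.0, 8.0])
    e = np.ones(4, bool)
    lr = logrank_test(t, t, e, e)
    assert lr.test_statistic == pytest.approx(0.0, abs=1e-12)


def test_cox_recovers_planted_hazard_uncensored():
    preds = tuple(
        dataclasses.replace(p, survival_log_hazard=0.8, dichotomize_at=100.0)
        if p.name == "tlg" else p
        for p in sd.DEFAULT_PREDICTORS
    )
    df, _ = sd.generate_cohort(
        sd.CohortSpec(n_patients=1000, predictors=preds, censoring_rate=0.0,
                      rng_seed=9)
    )
    res = oa.survival_models(df, [TLG_RULE], "os_months", "death")
    row = res["univariate"].iloc[0]
    assert row["ci_low"] < np.exp(0.8) < row["ci_high"]
    assert row["log_hazard"] == pytest.approx(0.8, abs=0.25)


def test_screen_then_adjust_retains_significant_rules():
    df = _planted_cohort(800, 0.0, seed=6, hazard=1.0)
    null_rule = oa.CutoffRule("adc_mm2_per_s", 1.0e-3, "above", 0.5, 0.5)
    res = oa.survival_models(df, [TLG_RULE, null_rule], "os_months", "death")
    assert "tlg" in res["retained"]
    assert res["multivariable"] is not None


# ---------------------------------------------------------------------------
# risk scores


def test_score_counts_satisfied_rules():
    df = pd.DataFrame({
        "tlg": [150.0, 150.0, 50.0],
        "entropy_bits": [7.5, 6.5, 6.5],
        "response": ["non_complete", "complete", "complete"],
    })
    rules = [
        oa.CutoffRule("tlg", 100.0, "above", 1, 1),
        oa.CutoffRule("entropy_bits", 7.0, "above", 1, 1),
    ]
    res = oa.build_score(df, rules)
    assert list(res["score"].scores) == [2, 1, 0]
    assert res["score"].max_score == 2
    # permutation invariance of rule order
    res_rev = oa.build_score(df, rules[::-1])
    assert list(res_rev["score"].scores) == [2, 1, 0]


def test_four_rule_survival_score_max_four():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({f"p{i}": rng.normal(size=30) for i in range(4)})
    df["os_months"] = rng.exponential(20, 30)
    df["death"] = True
    rules = [oa.CutoffRule(f"p{i}", 0.0, "above", 1, 1) for i in range(4)]
    res = oa.build_score(df, rules, response_col=None,
                         time_col="os_months", event_col="death")
    assert res["score"].max_score == 4
    assert res["score"].scores.max() <= 4


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), n_rules=st.integers(1, 5))
def test_score_equals_rule_count_and_is_order_invariant(seed, n_rules):
    """Score is the count of satisfied rules, regardless of rule order."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"p{i}": rng.normal(size=20) for i in range(n_rules)})
    rules = [oa.CutoffRule(f"p{i}", float(rng.normal()), "above", 1, 1)
             for i in range(n_rules)]
    scores = oa.build_score(df, rules, response_col=None)["score"].scores
    direct = sum((df[f"p{i}"] > rules[i].cutoff).to_numpy().astype(int)
                 for i in range(n_rules))
    assert np.array_equal(scores, direct)
    perm = list(rng.permutation(n_rules))
    shuffled = oa.build_score(df, [rules[i] for i in perm],
                              response_col=None)["score"].scores
    assert np.array_equal(scores, shuffled)
    assert scores.max() <= n_rules and scores.min() >= 0


def test_missing_parameter_value_excludes_patient():
    df = pd.DataFrame({
        "tlg": [150.0, np.nan, 50.0],
        "response": ["non_complete", "complete", "complete"],
    })
    res = oa.build_score(df, [TLG_RULE])
    assert res["n_excluded"] == 1
    assert len(res["score"].scores) == 2


def test_missing_parameter_column_rejected():
    df = pd.DataFrame({"response": ["complete"]})
    with pytest.raises(ValueError, match="missing"):
        oa.build_score(df, [TLG_RULE])
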