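"""Response and survival statistics with additive risk-factor scoring.

The analysis layer mirrors common practice in imaging-biomarker studies:

1. continuous imaging parameters are dichotomized at the ROC cutoff
   maximizing Youden's J (sensitivity + specificity - 1) against a binary
   endpoint;
2. dichotomized parameters are screened by Pearson chi-square and entered
   into a multivariable logistic model of treatment response (odds ratios
   reported; such coefficients are sometimes labeled "hazard ratios" in the
   clinical literature, but they are odds ratios);
3. survival endpoints (overall survival, recurrence-free survival) are
   modeled by Kaplan–Meier estimation, log-rank tests and Cox proportional
   hazards with Efron tie handling, using a univariate screen
   (default p < .05) followed by a multivariable fit;
4. an additive risk score counts, per patient, how many independent adverse
   factors are present (1 point each); outcomes are then stratified by score.

No multiple-testing correction is applied by default (two-sided p < .05
convention); Benjamini–Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

__all__ = [
    "CutoffRule",
    "RiskScore",
    "roc_cutoff",
    "association_test",
    "response_model",
    "survival_models",
    "build_score",
    "kaplan_meier",
]


@dataclass(frozen=True)
class CutoffRule:
    """A dichotomization rule: ``parameter`` is high-risk on ``direction`` side."""

    parameter: str
    cutoff: float
    direction: str  # "above" | "below": side counted as high-risk/test-positive
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def apply(self, values) -> np.ndarray:
        """Boolean high-risk indicator for an array of parameter values."""
        x = np.asarray(values, dtype=float)
        return x > self.cutoff if self.direction == "above" else x < self.cutoff


@dataclass(frozen=True)
class RiskScore:
    """Integer per-patient count of satisfied high-risk rules."""

    rules: tuple[CutoffRule, ...]
    scores: np.ndarray
    max_score: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.size and (s.min() < 0 or s.max() > self.max_score):
            raise ValueError("scores out of range")


def roc_cutoff(values, binary_outcome) -> CutoffRule:
    """Youden-optimal dichotomization cutoff against a binary endpoint.

    All midpoints between consecutive sorted unique values are examined in
    both orientations ("above" and "below" as the test-positive side); ties
    in J are broken toward higher sensitivity, then toward the smaller
    cutoff.  The positive class of ``binary_outcome`` is 1/True.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(binary_outcome).astype(bool)
    if x.size != y.size:
        raise ValueError("values and outcome must align")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("need at least two distinct values")

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(y.sum())
    n_neg = y.size - n_pos

    best: tuple | None = None
    name = getattr(values, "name", "") or "parameter"
    for c in mids:
        for direction in ("above", "below"):
            pred = x > c if direction == "above" else x < c
            sens = float((pred & y).sum()) / n_pos
            spec = float((~pred & ~y).sum()) / n_neg
            j = sens + spec - 1.0
            key = (j, sens, -c)
            if best is None or key > best[0]:
                best = (key, CutoffRule(name, float(c), direction, sens, spec))
    assert best is not None
    return best[1]


def association_test(high_risk, positive_outcome) -> dict:
    """Pearson chi-square on the 2×2 table of risk indicator vs outcome.

    No continuity correction (plain Pearson statistic).  Returns the
    statistic, p-value, the observed table and the expected counts.
    """
    a = np.asarray(high_risk).astype(bool)
    b = np.asarray(positive_outcome).astype(bool)
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return {
        "chi2": float(res.statistic),
        "p_value": float(res.pvalue),
        "dof": int(res.dof),
        "observed": table,
        "expected": np.asarray(res.expected_freq),
    }


def response_model(
    cohort: pd.DataFrame,
    rules: list[CutoffRule],
    response_col: str = "response",
    positive_label: str = "non_complete",
) -> pd.DataFrame:
    """Multivariable logistic model of response on dichotomized predictors.

    One row per rule with the exponentiated coefficient (odds ratio), its
    95% CI and p-value.  With fewer than 5 events or non-events per fitted
    parameter a low-information warning flag is set.  Perfect separation
    triggers an L2-penalized refit, flagged in the output.
    """
    import statsmodels.api as sm

    if not rules:
        raise ValueError("no rules supplied")
    y = (cohort[response_col] == positive_label).astype(float).to_numpy()
    X = pd.DataFrame(
        {r.parameter: r.apply(cohort[r.parameter]).astype(float) for r in rules}
    )
    Xc = sm.add_constant(X, has_constant="add")

    n_events = int(y.sum())
    n_nonevents = int(y.size - n_events)
    low_info = min(n_events, n_nonevents) < 5 * len(rules)

    penalized = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 15):
            raise np.linalg.LinAlgError("separation suspected")
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except Exception:
        # ridge-penalized IRLS: always well-posed, flagged as penalized
        penalized = True
        Xa = Xc.to_numpy()
        lam = 1.0
        beta = np.zeros(Xa.shape[1])
        for _ in range(100):
            eta = np.clip(Xa @ beta, -30, 30)
            p_hat = 1 / (1 + np.exp(-eta))
            W = np.clip(p_hat * (1 - p_hat), 1e-10, None)
            grad = Xa.T @ (y - p_hat) - lam * beta
            info = (Xa.T * W) @ Xa + lam * np.eye(Xa.shape[1])
            step = np.linalg.solve(info, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        cov = np.linalg.inv(info)
        params = pd.Series(beta, index=Xc.columns)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=Xc.columns)
        zs = beta / np.asarray(bse)
        pvals = pd.Series(2 * stats.norm.sf(np.abs(zs)), index=Xc.columns)

    rows = []
    params = pd.Series(np.asarray(params), index=Xc.columns)
    bse = pd.Series(np.asarray(bse), index=Xc.columns)
    pvals = pd.Series(np.asarray(pvals), index=Xc.columns)
    for r in rules:
        beta = float(params[r.parameter])
        se = float(bse[r.parameter])
        rows.append(
            {
                "parameter": r.parameter,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p_value": float(pvals[r.parameter]),
                "log_odds": beta,
                "se": se,
                "penalized": penalized,
                "low_information": low_info,
            }
        )
    return pd.DataFrame(rows)


def kaplan_meier(times, events) -> pd.DataFrame:
    """Kaplan–Meier survival estimate with Greenwood confidence band."""
    km = KaplanMeierFitter()
    km.fit(np.asarray(times, float), np.asarray(events, bool))
    out = km.survival_function_.copy()
    out.columns = ["survival"]
    ci = km.confidence_interval_
    out["ci_low"] = ci.iloc[:, 0].to_numpy()
    out["ci_high"] = ci.iloc[:, 1].to_numpy()
    return out.reset_index().rename(columns={"timeline": "time"})


def survival_models(
    cohort: pd.DataFrame,
    rules: list[CutoffRule],
    time_col: str,
    event_col: str,
    univariate_alpha: float = 0.05,
) -> dict:
    """Screen-then-adjust Cox modeling plus per-rule Kaplan–Meier strata.

    Each dichotomized rule is first fitted in a univariate Cox model (Efron
    ties); rules reaching ``univariate_alpha`` enter a multivariable model.
    Returns univariate and multivariable summaries, the retained rule names
    and per-rule log-rank tests between high/low strata.
    """
    if not rules:
        raise ValueError("no rules supplied")
    times = cohort[time_col].to_numpy(dtype=float)
    events = cohort[event_col].to_numpy(dtype=bool)
    if not events.any():
        raise ValueError("no events in cohort")

    uni_rows, logrank_rows = [], []
    for r in rules:
        ind = r.apply(cohort[r.parameter]).astype(float)
        df = pd.DataFrame({"T": times, "E": events.astype(int), r.parameter: ind})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        s = cph.summary.loc[r.parameter]
        uni_rows.append(
            {
                "parameter": r.parameter,
                "hazard_ratio": float(s["exp(coef)"]),
                "ci_low": float(s["exp(coef) lower 95%"]),
                "ci_high": float(s["exp(coef) upper 95%"]),
                "p_value": float(s["p"]),
                "log_hazard": float(s["coef"]),
            }
        )
        hi = np.asarray(ind, dtype=bool)
        if hi.any() and (~hi).any() and events[hi].any() and events[~hi].any():
            lr = logrank_test(times[hi], times[~hi], events[hi], events[~hi])
            logrank_rows.append(
                {"parameter": r.parameter, "statistic": float(lr.test_statistic),
                 "p_value": float(lr.p_value)}
            )
    univariate = pd.DataFrame(uni_rows)

    retained = univariate.loc[
        univariate["p_value"] < univariate_alpha, "parameter"
    ].tolist()
    multivariable = None
    if retained:
        cols = {r.parameter: r.apply(cohort[r.parameter]).astype(float)
                for r in rules if r.parameter in retained}
        df = pd.DataFrame({"T": times, "E": events.astype(int), **cols})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        multivariable = cph.summary.reset_index().rename(
            columns={
                "covariate": "parameter",
                "exp(coef)": "hazard_ratio",
                "exp(coef) lower 95%": "ci_low",
                "exp(coef) upper 95%": "ci_high",
                "p": "p_value",
                "coef": "log_hazard",
            }
        )[["parameter", "hazard_ratio", "ci_low", "ci_high", "p_value", "log_hazard"]]

    return {
        "univariate": univariate,
        "retained": retained,
        "multivariable": multivariable,
        "logrank": pd.DataFrame(logrank_rows),
    }


def build_score(
    cohort: pd.DataFrame,
    rules: list[CutoffRule],
    response_col: str | None = "response",
    positive_label: str = "non_complete",
    time_col: str | None = None,
    event_col: str | None = None,
) -> dict:
    """Additive risk score (one point per satisfied rule) and stratified outcomes.

    Patients missing any rule's parameter are excluded and counted.  When a
    response column is given, complete-response rates per score level and a
    chi-square across levels are reported; when a survival endpoint is
    given, per-level Kaplan–Meier estimates and the multi-stratum log-rank
    test are reported.
    """
    if not rules:
        raise ValueError("no rules supplied")
    for r in rules:
        if r.parameter not in cohort.columns:
            raise ValueError(f"parameter {r.parameter!r} missing from cohort")

    complete = cohort.dropna(subset=[r.parameter for r in rules])
    n_excluded = len(cohort) - len(complete)
    score = np.zeros(len(complete), dtype=int)
    for r in rules:
        score += r.apply(complete[r.parameter]).astype(int)
    risk = RiskScore(rules=tuple(rules), scores=score, max_score=len(rules),
                     n_excluded=n_excluded)

    out: dict = {"score": risk, "n_excluded": n_excluded}

    if response_col is not None and response_col in complete.columns:
        resp = (complete[response_col] == positive_label).to_numpy()
        levels = np.arange(len(rules) + 1)
        rows = []
        for s in levels:
            sel = score == s
            n = int(sel.sum())
            rows.append(
                {
                    "score": int(s),
                    "n": n,
                    "complete_response_rate": float((~resp[sel]).mean()) if n else np.nan,
                }
            )
        table = pd.DataFrame(rows)
        occupied = table["n"] > 0
        ct = np.array(
            [
                [int((~resp[score == s]).sum()), int(resp[score == s].sum())]
                for s in levels[occupied.to_numpy()]
            ]
        )
        chi2 = stats.chi2_contingency(ct, correction=False) if ct.shape[0] > 1 else None
        out["response_by_score"] = table
        out["response_chi2"] = None if chi2 is None else {
            "chi2": float(chi2.statistic), "p_value": float(chi2.pvalue)
        }

    if time_col is not None and event_col is not None:
        times = complete[time_col].to_numpy(dtype=float)
        events = complete[event_col].to_numpy(dtype=bool)
        km_by_level = {}
        for s in np.unique(score):
            sel = score == s
            km_by_level[int(s)] = kaplan_meier(times[sel], events[sel])
        lr = multivariate_logrank_test(times, score, events.astype(int))
        out["km_by_score"] = km_by_level
        out["survival_logrank"] = {
            "statistic": float(lr.test_statistic),
            "p_value": float(lr.p_value),
        }

    return out
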