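"""Lifespan summaries: Kaplan-Meier medians, maximum lifespan, log-rank tests.

The median lifespan of an arm is the Kaplan-Meier median — the smallest time
at which the product-limit survivor estimate drops to <= 0.5 — which on
fully observed data reduces to the empirical (lower) median of death times.
Maximum lifespan is the longest *observed* death time; censored follow-up
times are excluded.  Arm comparisons use the standard unweighted log-rank
(Mantel-Cox) test with hypergeometric tie variance, plus an optional exact
label-permutation p-value for very small arms.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "km_median",
    "max_lifespan",
    "lifespan_change",
    "logrank",
    "km_curve",
    "summarize_survival",
]

_COLUMNS = ("arm", "time_months", "event")


def _arm(data: pd.DataFrame, arm: str) -> pd.DataFrame:
    missing = set(_COLUMNS).difference(data.columns)
    if missing:
        raise ValueError(f"survival data lacks column(s): {sorted(missing)}")
    sub = data.loc[data["arm"] == arm]
    if sub.empty:
        raise ValueError(f"arm '{arm}' absent from survival data")
    if (sub["time_months"] <= 0).any():
        raise ValueError(f"arm '{arm}' has non-positive times")
    return sub


def km_median(data: pd.DataFrame, arm: str) -> float:
    """KM median lifespan of one arm; NaN when the curve never reaches 0.5.

    The median is the smallest time with survivor estimate <= 0.5 (lower
    median on fully observed even-n data).  The boundary comparison carries
    a 1e-9 tolerance so a product-limit value of exactly one half is not
    missed to floating-point round-off in the cumulative product.
    """
    sub = _arm(data, arm)
    kmf = KaplanMeierFitter().fit(sub["time_months"], sub["event"])
    surv = kmf.survival_function_.iloc[:, 0]
    hit = surv[surv <= 0.5 + 1e-9]
    return float(hit.index[0]) if len(hit) else float("nan")


def max_lifespan(data: pd.DataFrame, arm: str) -> float:
    """Longest observed death time in an arm; NaN when no death was observed."""
    sub = _arm(data, arm)
    deaths = sub.loc[sub["event"].astype(bool), "time_months"]
    return float(deaths.max()) if len(deaths) else float("nan")


def top_decile_mean_lifespan(data: pd.DataFrame, arm: str) -> float:
    """Mean of the top 10% of observed death times (robust maximum-lifespan variant)."""
    sub = _arm(data, arm)
    deaths = np.sort(sub.loc[sub["event"].astype(bool), "time_months"].to_numpy())
    if deaths.size == 0:
        return float("nan")
    k = max(1, int(np.ceil(0.1 * deaths.size)))
    return float(deaths[-k:].mean())


def lifespan_change(reference_months: float, treated_months: float) -> tuple[float, float]:
    """Absolute and percent lifespan change of treated vs reference.

    Returns (delta_months, pct) at full precision; display rounding (two
    decimals for months, one for percent) is left to the caller.
    """
    if not reference_months > 0:
        raise ValueError(f"reference lifespan must be > 0, got {reference_months}")
    delta = treated_months - reference_months
    return delta, 100.0 * delta / reference_months


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_b: np.ndarray) -> float:
    """Unweighted log-rank chi-square with hypergeometric tie variance."""
    order = np.argsort(times, kind="stable")
    times, events, in_b = times[order], events[order], in_b[order]
    n = times.size
    obs_minus_exp = 0.0
    var = 0.0
    i = 0
    at_risk_total = n
    at_risk_b = int(in_b.sum())
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d = int(events[i:j].sum())
        d_b = int(events[i:j][in_b[i:j]].sum())
        if d > 0 and at_risk_total > 1:
            e_b = d * at_risk_b / at_risk_total
            v = (
                d
                * (at_risk_b / at_risk_total)
                * (1 - at_risk_b / at_risk_total)
                * (at_risk_total - d)
                / (at_risk_total - 1)
            )
            obs_minus_exp += d_b - e_b
            var += v
        at_risk_total -= j - i
        at_risk_b -= int(in_b[i:j].sum())
        i = j
    if var == 0:
        return 0.0
    return obs_minus_exp**2 / var


def logrank(
    data: pd.DataFrame,
    arm_a: str,
    arm_b: str,
    exact_permutation: bool = False,
    max_exact: int = 200_000,
) -> tuple[float, float]:
    """Two-arm log-rank (Mantel-Cox) test: (chi-square statistic, p-value).

    With ``exact_permutation=True`` the p-value is instead the fraction of
    all arm-label reassignments (preserving arm sizes) whose chi-square
    statistic is at least the observed one — feasible only while the number
    of assignments C(n, n_a) stays below ``max_exact``.
    """
    a, b = _arm(data, arm_a), _arm(data, arm_b)
    if int(a["event"].sum() + b["event"].sum()) < 1:
        raise ValueError("log-rank needs at least one event across the two arms")
    if not exact_permutation:
        res = _ll_logrank(
            a["time_months"], b["time_months"], a["event"], b["event"]
        )
        return float(res.test_statistic), float(res.p_value)

    times = np.concatenate([a["time_months"].to_numpy(float), b["time_months"].to_numpy(float)])
    events = np.concatenate(
        [a["event"].to_numpy(int).astype(bool), b["event"].to_numpy(int).astype(bool)]
    )
    n, nb = times.size, len(b)
    if comb(n, nb) > max_exact:
        raise ValueError(
            f"exact permutation infeasible: C({n}, {nb}) > {max_exact} assignments"
        )
    in_b_obs = np.zeros(n, dtype=bool)
    in_b_obs[len(a):] = True
    stat_obs = _logrank_chi2(times, events, in_b_obs)
    hits = total = 0
    for idx in combinations(range(n), nb):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        total += 1
        if _logrank_chi2(times, events, mask) >= stat_obs - 1e-12:
            hits += 1
    return float(stat_obs), hits / total


def km_curve(data: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Product-limit curve of one arm: time, number at risk, survival estimate."""
    sub = _arm(data, arm)
    kmf = KaplanMeierFitter().fit(sub["time_months"], sub["event"])
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time_months": surv.index, "at_risk": at_risk.to_numpy(), "survival": surv.to_numpy()}
    ).reset_index(drop=True)


def summarize_survival(
    data: pd.DataFrame,
    reference_arm: str,
    comparison_arm: str,
    exact_permutation: bool = False,
) -> dict:
    """Per-arm medians/maxima and the reference-vs-comparison deltas and test.

    Percent changes are 100 * delta / reference.  Display-rounded fields
    (months to two decimals, percent to one) accompany the full-precision
    values.
    """
    arms = {}
    for arm in (reference_arm, comparison_arm):
        arms[arm] = {
            "n": int((data["arm"] == arm).sum()),
            "n_events": int(data.loc[data["arm"] == arm, "event"].sum()),
            "km_median_months": km_median(data, arm),
            "max_lifespan_months": max_lifespan(data, arm),
        }
    ref, cmp_ = arms[reference_arm], arms[comparison_arm]
    d_med, p_med = lifespan_change(ref["km_median_months"], cmp_["km_median_months"])
    d_max, p_max = lifespan_change(ref["max_lifespan_months"], cmp_["max_lifespan_months"])
    stat, p = logrank(data, reference_arm, comparison_arm, exact_permutation=exact_permutation)
    return {
        "arms": arms,
        "comparison": {
            "reference": reference_arm,
            "comparison": comparison_arm,
            "delta_median_months": round(d_med, 2),
            "pct_median": round(p_med, 1),
            "delta_max_months": round(d_max, 2),
            "pct_max": round(p_max, 1),
            "logrank_statistic": stat,
            "logrank_p": p,
            "exact_permutation": exact_permutation,
        },
    }
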