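"""Median-split Kaplan-Meier survival analysis.

A per-sample heterogeneity score is dichotomized at the cohort median
(ties to the low group), the two groups' Kaplan-Meier curves are compared
with a log-rank test, and follow-up is capped at a 4-year horizon (1460
days): later events and censorings are re-censored at the horizon.

Beyond the p-value, the direction of effect is summarized by the signed,
horizon-normalized integral of the gap between the two step survival
curves,

    (1/T_max) * integral_0^T_max [S_high(t) - S_low(t)] dt,

a number in [-1, 1]: negative when the high-score group fares worse.
Multiple testing over a (cohort x caller) grid of tests uses the
Benjamini-Hochberg step-up procedure.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .io_core import ClinicalRecord

__all__ = [
    "SurvivalCurve",
    "SplitTestResult",
    "HORIZON_DAYS",
    "censor_at_horizon",
    "km_curve",
    "median_split",
    "logrank_median_split",
    "survival_difference",
    "bh_correct",
]

#: 4-year follow-up horizon in days.
HORIZON_DAYS = 1460.0


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function S(t), S(0) = 1.

    ``event_times`` are the ascending times where the curve drops;
    ``survival_probs[i]`` is the value of S on [event_times[i],
    event_times[i+1]).  ``censor_marks`` lists censoring times.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    censor_marks: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival_probs = np.asarray(self.survival_probs, dtype=float)
        self.censor_marks = np.asarray(self.censor_marks, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly ascending")
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise ValueError("survival_probs must be non-increasing")
        if np.any((self.survival_probs < 0) | (self.survival_probs > 1)):
            raise ValueError("survival_probs must lie in [0, 1]")

    def at(self, t: float) -> float:
        """S(t): right-continuous step evaluation; 1 before the first drop."""
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival_probs[i])


@dataclass
class SplitTestResult:
    """Log-rank outcome of one median-split test in the cohort x caller grid."""

    cohort: str
    caller: str
    score_name: str
    logrank_p: float
    survival_difference: float
    n_high: int
    n_low: int
    significant_raw: bool = False
    significant_bh: bool = False


def censor_at_horizon(
    records: list[ClinicalRecord], t_max_days: float = HORIZON_DAYS
) -> list[ClinicalRecord]:
    """Cap follow-up: anything beyond t_max becomes a censoring at t_max.

    A record exactly at the horizon is kept unchanged (boundary
    inclusive).
    """
    out = []
    for r in records:
        if r.time_days > t_max_days:
            out.append(
                ClinicalRecord(
                    sample_id=r.sample_id,
                    time_days=t_max_days,
                    event=False,
                    covariates=r.covariates,
                )
            )
        else:
            out.append(r)
    return out


def km_curve(records: list[ClinicalRecord]) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function."""
    if not records:
        raise ValueError("cannot fit a survival curve to zero records")
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    # lifelines includes t=0 (S=1); keep only actual drop points
    drops = np.flatnonzero(np.diff(np.concatenate([[1.0], s])) < 0)
    return SurvivalCurve(
        event_times=t[drops],
        survival_probs=s[drops],
        censor_marks=np.sort(times[~events]),
    )


def median_split(scores: dict) -> tuple[set, set]:
    """Split sample ids at the median score: high = strictly above, ties low."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    values = np.array(list(scores.values()), dtype=float)
    med = float(np.median(values))
    high = {sid for sid, v in scores.items() if v > med}
    low = {sid for sid, v in scores.items() if v <= med}
    if not high:
        raise ValueError("all scores identical; no median split exists")
    return high, low


def logrank_median_split(
    scores: dict,
    records: list[ClinicalRecord],
    t_max: float = HORIZON_DAYS,
    cohort: str = "",
    caller: str = "",
    score_name: str = "",
) -> SplitTestResult:
    """Median-split log-rank test on horizon-censored survival data.

    Joins scores and clinical records on sample id, applies the horizon,
    and compares the two groups' survival with the chi-square log-rank
    test.  Also reports the signed survival-difference integral.
    """
    by_id = {r.sample_id: r for r in censor_at_horizon(records, t_max)}
    scores = {sid: v for sid, v in scores.items() if sid in by_id}
    high, low = median_split(scores)
    high_recs = [by_id[s] for s in high]
    low_recs = [by_id[s] for s in low]
    if not high_recs or not low_recs:
        raise ValueError("a group is empty after joining scores with records")
    res = logrank_test(
        [r.time_days for r in high_recs],
        [r.time_days for r in low_recs],
        event_observed_A=[r.event for r in high_recs],
        event_observed_B=[r.event for r in low_recs],
    )
    diff = survival_difference(km_curve(high_recs), km_curve(low_recs), t_max)
    return SplitTestResult(
        cohort=cohort,
        caller=caller,
        score_name=score_name,
        logrank_p=float(res.p_value),
        survival_difference=diff,
        n_high=len(high_recs),
        n_low=len(low_recs),
    )


def survival_difference(
    s_high: SurvivalCurve, s_low: SurvivalCurve, t_max: float = HORIZON_DAYS
) -> float:
    """Signed normalized integral (1/T) int_0^T [S_high - S_low] dt.

    Computed exactly by interval decomposition over the union of both
    curves' drop points (no quadrature).  Lies in [-1, 1]; antisymmetric
    in the two groups; negative when the high group has worse survival.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    knots = np.concatenate(
        [[0.0], s_high.event_times, s_low.event_times, [t_max]]
    )
    knots = np.unique(knots[knots <= t_max])
    total = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        total += (s_high.at(a) - s_low.at(a)) * (b - a)
    return total / t_max


def bh_correct(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level alpha."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject
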