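"""Endpoint construction and survival statistics.

Endpoints follow the conventions of retrospective re-irradiation series:

* post-recurrence survival (PRS) — from the first day of re-irradiation to
  death or last follow-up;
* progression-free survival (PFS) — from the first day of re-irradiation to
  progression, death or last follow-up;
* overall survival (OS) — from the start of the initial radiotherapy;
* treatment interval — first to second irradiation, a candidate covariate.

Durations are day counts by calendar difference; months are reported at a
fixed 30 days/month, rounded to one decimal.

Estimation and testing are delegated to lifelines (Kaplan-Meier
product-limit estimator, log-rank test, Cox proportional hazards with Efron
tie handling — appropriate for the heavy ties of day-resolution data) and
scipy (Mann-Whitney U, paired Wilcoxon, Fisher's exact).  All p-values are
two-sided.  The median-survival convention is the smallest time at which the
survival curve drops to 0.5 or below; a curve that never does has its median
"not reached" (returned as ``math.inf``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .errors import DataError, ValidationError

DAYS_PER_MONTH = 30.0


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up for a single endpoint."""

    patient_id: str
    time_days: float
    event: int

    def __post_init__(self):
        if self.time_days < 0:
            raise ValidationError(f"negative follow-up time for {self.patient_id}")
        if self.event not in (0, 1):
            raise ValidationError("event flag must be 0 (censored) or 1")


@dataclass(frozen=True)
class EndpointSet:
    """All endpoint durations (days) and event flags for one patient."""

    patient_id: str
    prs_days: float
    prs_event: int
    pfs_days: float
    pfs_event: int
    os_days: float
    os_event: int
    interval_days: float


def compute_endpoints(
    patient_id: str,
    rt1_start: date,
    rert_start: date,
    last_contact: date,
    death: date | None = None,
    progression: date | None = None,
) -> EndpointSet:
    """Derive PRS / PFS / OS durations and event flags from calendar dates.

    ``last_contact`` is the date of death when the patient died, otherwise
    the last follow-up.  Progression before re-irradiation start is part of
    the indication, not the outcome, and is rejected.
    """
    if rert_start < rt1_start:
        raise DataError(f"{patient_id}: re-irradiation precedes initial radiotherapy")
    if death is not None and death < rert_start:
        raise DataError(f"{patient_id}: death precedes re-irradiation start")
    if progression is not None and progression < rert_start:
        raise DataError(f"{patient_id}: progression precedes re-irradiation start")
    end = death if death is not None else last_contact
    prs = (end - rert_start).days
    prs_event = 1 if death is not None else 0
    if progression is not None:
        pfs, pfs_event = (progression - rert_start).days, 1
    else:
        pfs, pfs_event = prs, prs_event
    os_days = (end - rt1_start).days
    interval = (rert_start - rt1_start).days
    if prs < 0:
        raise DataError(f"{patient_id}: follow-up ends before re-irradiation start")
    return EndpointSet(
        patient_id=patient_id,
        prs_days=float(prs),
        prs_event=prs_event,
        pfs_days=float(pfs),
        pfs_event=pfs_event,
        os_days=float(os_days),
        os_event=prs_event,
        interval_days=float(interval),
    )


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier curve: timeline, survival probabilities and median."""

    timeline: np.ndarray
    survival: np.ndarray
    median_days: float  # math.inf when the median is not reached

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median_days)

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step curve)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_arrays(records: Sequence[SurvivalRecord] | pd.DataFrame):
    if isinstance(records, pd.DataFrame):
        return records["time_days"].to_numpy(float), records["event"].to_numpy(int)
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord] | pd.DataFrame) -> KMResult:
    """Product-limit survival estimate with median survival time."""
    times, events = _as_arrays(records)
    if times.size == 0:
        raise DataError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    below = np.flatnonzero(surv <= 0.5)
    median = float(timeline[below[0]]) if below.size else math.inf
    return KMResult(timeline=timeline, survival=surv, median_days=median)


def logrank(
    group_a: Sequence[SurvivalRecord] | pd.DataFrame,
    group_b: Sequence[SurvivalRecord] | pd.DataFrame,
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi-square, p)."""
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    if ta.size == 0 or tb.size == 0:
        raise DataError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox proportional-hazards fit for one covariate."""

    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int


def cox_univariate(df: pd.DataFrame, covariate: str,
                   time_col: str = "time_days", event_col: str = "event") -> CoxResult:
    """Univariate Cox regression (partial likelihood, Efron ties).

    Returns the hazard ratio per unit of ``covariate`` with its Wald 95%
    confidence interval and two-sided p-value.  A covariate that does not
    vary, or that separates the data completely, cannot be fitted and raises
    :class:`DataError`.
    """
    data = df[[time_col, event_col, covariate]].dropna()
    if data[covariate].nunique() < 2:
        raise DataError(f"covariate {covariate!r} is constant; cannot fit Cox model")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except ConvergenceError as exc:
        raise DataError(f"Cox fit for {covariate!r} did not converge: {exc}") from exc
    s = cph.summary.loc[covariate]
    return CoxResult(
        covariate=covariate,
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
    )


def two_sample_tests(x, y=None, method: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided two-sample tests used for cohort comparisons.

    method = "mann_whitney"     — independent samples (U statistic);
    method = "wilcoxon_paired"  — paired samples of equal length (identical
                                  pairs give the degenerate statistic 0, p=1);
    method = "fisher_exact"     — ``x`` is a 2x2 table of counts, ``y`` unused.
    """
    from scipy import stats

    if method == "fisher_exact":
        table = np.asarray(x, dtype=float)
        if table.shape != (2, 2):
            raise ValidationError("fisher_exact needs a 2x2 table of counts")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("samples must be non-empty")
    if method == "mann_whitney":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(stat), float(p)
    if method == "wilcoxon_paired":
        if x.size != y.size:
            raise ValidationError("paired test needs equal-length samples")
        if np.all(x == y):
            return 0.0, 1.0
        stat, p = stats.wilcoxon(x, y, alternative="two-sided")
        return float(stat), float(p)
    raise ValidationError(f"unknown test method {method!r}")
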