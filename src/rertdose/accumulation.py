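"""Conservative cumulative-dose estimation across two radiation courses.

When a structure is irradiated in two sequential courses the sum of the two
per-course EUDs is an upper bound on the EUD of the accumulated dose
distribution, because hot spots of the two plans rarely coincide (for the
power-law gEUD the bound is Minkowski's inequality; for mean dose it is
exact).  A recovery factor ``r`` in [0, 1] applied to the FIRST course's
value models repair of normal CNS tissue in the interval between courses:

    corrected_sum = r * value_course1 + value_course2

Both the uncorrected upper bound and the corrected sum are reported.
Cohort-level tables are built patient-wise: each patient's two course values
are summed first, then the cohort median/maximum of those sums is taken
(median of sums, not sum of medians).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

COURSE_PRIMARY = "RT1"
COURSE_REIRRADIATION = "ReRT"

#: long-format per-course metric table columns expected by the cohort tables
METRIC_COLUMNS = ["patient_id", "course", "structure", "metric", "value"]


@dataclass(frozen=True)
class CumulativeDoseEstimate:
    """Two-course accumulation of one scalar dose metric for one structure."""

    metric_name: str
    course1_value: float
    course2_value: float
    sum_upper_bound: float
    corrected_sum: float
    recovery_r: float


def cumulative_estimate(
    v1: float, v2: float, r: float = 0.5, metric_name: str = "EUD"
) -> CumulativeDoseEstimate:
    """Accumulate a per-course dose metric with a recovery correction.

    ``v1`` is the first-course value (Gy), ``v2`` the re-irradiation value.
    The uncorrected sum is a conservative upper bound on the true cumulative
    value; the corrected sum discounts the first course by the recovery
    factor ``r`` (r = 1 disables the correction, r = 0 ignores the first
    course entirely).
    """
    if v1 < 0 or v2 < 0:
        raise DataError(f"dose values must be non-negative, got ({v1}, {v2})")
    if not 0.0 <= r <= 1.0:
        raise ParameterError(f"recovery factor must lie in [0, 1], got {r}")
    return CumulativeDoseEstimate(
        metric_name=metric_name,
        course1_value=float(v1),
        course2_value=float(v2),
        sum_upper_bound=float(v1 + v2),
        corrected_sum=float(r * v1 + v2),
        recovery_r=float(r),
    )


def _check_metric_frame(metrics: pd.DataFrame) -> pd.DataFrame:
    if metrics.empty:
        raise DataError("empty cohort: no per-course metrics supplied")
    missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
    if missing:
        raise DataError(f"metric table lacks columns: {', '.join(missing)}")
    return metrics


def per_course_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-structure, per-metric summary of each course separately.

    Returns one row per (structure, metric) with N / median / maximum for
    the primary course and for re-irradiation, mirroring how treatment
    parameters are tabulated per course.  N counts patients with available
    data; patients missing a structure in a course simply do not contribute
    to that column.
    """
    metrics = _check_metric_frame(metrics)
    rows = []
    for (structure, metric), grp in metrics.groupby(["structure", "metric"], sort=False):
        row: dict = {"structure": structure, "metric": metric}
        for course, tag in ((COURSE_PRIMARY, "rt1"), (COURSE_REIRRADIATION, "rert")):
            vals = grp.loc[grp["course"] == course, "value"].to_numpy(dtype=float)
            row[f"n_{tag}"] = int(vals.size)
            row[f"median_{tag}"] = float(np.median(vals)) if vals.size else np.nan
            row[f"maximum_{tag}"] = float(vals.max()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_dose_table(
    metrics: pd.DataFrame,
    recovery_r: float = 0.5,
    exclude_patients: Iterable[str] = (),
) -> pd.DataFrame:
    """Cumulative two-course summary table for a cohort.

    For every (structure, metric), patients with values in BOTH courses are
    accumulated patient-wise with :func:`cumulative_estimate`; the table
    then reports the cohort N, median and maximum of the uncorrected sums
    and of the recovery-corrected sums.  Patients lacking either course's
    value for a structure are excluded from that row (variable N per row).

    ``exclude_patients`` drops patients entirely (e.g. interstitial
    brachytherapy between the courses whose dose cannot be accumulated).
    """
    metrics = _check_metric_frame(metrics)
    excl = set(exclude_patients)
    if excl:
        metrics = metrics[~metrics["patient_id"].isin(excl)]
        if metrics.empty:
            raise DataError("empty cohort after exclusions")
    wide = metrics.pivot_table(
        index=["structure", "metric", "patient_id"],
        columns="course",
        values="value",
        aggfunc="first",
    )
    for col in (COURSE_PRIMARY, COURSE_REIRRADIATION):
        if col not in wide.columns:
            wide[col] = np.nan
    paired = wide.dropna(subset=[COURSE_PRIMARY, COURSE_REIRRADIATION])
    rows = []
    for (structure, metric), grp in paired.groupby(["structure", "metric"], sort=False):
        sums = (grp[COURSE_PRIMARY] + grp[COURSE_REIRRADIATION]).to_numpy(dtype=float)
        corrected = (
            recovery_r * grp[COURSE_PRIMARY] + grp[COURSE_REIRRADIATION]
        ).to_numpy(dtype=float)
        rows.append(
            {
                "structure": structure,
                "metric": metric,
                "N": int(sums.size),
                "median": float(np.median(sums)),
                "maximum": float(sums.max()),
                "corrected_median": float(np.median(corrected)),
                "corrected_maximum": float(corrected.max()),
            }
        )
    if not rows:
        raise DataError("no structure has data in both courses for any patient")
    return pd.DataFrame(rows)
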