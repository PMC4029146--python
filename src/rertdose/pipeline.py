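"""End-to-end analysis orchestration.

Takes a cohort (synthetic or from the DVH + metadata CSVs), computes
per-course dose metrics (EUD, maximum, mean dose, target volumes and
equivalent-sphere radii), accumulates them across the two courses with the
recovery correction, builds the survival endpoints and runs the univariate
analyses, and renders everything as TSV tables plus a machine-readable run
manifest.  The whole run is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accumulation import cohort_dose_table, per_course_table
from .cohort import (
    CohortConfig,
    PatientRecord,
    SurvivalModel,
    cohort_metadata,
    generate_cohort,
    iter_dvhs,
)
from .dvh import DoseVolumeHistogram, dose_summary, read_dvh_csv, write_dvh_csv
from .errors import DataError, ValidationError
from .eud import EUDParameters, StructureClass, classify_structure, eud_for_structure
from .geometry import sphere_radius, sphere_volume, volume_dichotomy
from .survival import compute_endpoints, cox_univariate, km_estimate, logrank
from .utils import days_to_months, round_half_up

log = logging.getLogger("rertdose")


@dataclass
class RunConfig:
    """Configuration for one analysis run.

    Exactly one input source is active: either ``dvh_csv``/``cohort_csv``
    paths, or the synthetic cohort config.
    """

    dvh_csv: str | None = None
    cohort_csv: str | None = None
    synthetic: CohortConfig | None = None
    eud_params: EUDParameters = field(default_factory=EUDParameters)
    dichotomy_radii_cm: tuple[float, ...] = (2.0,)
    rng_seed: int = 0

    def validate(self):
        has_files = self.dvh_csv is not None and self.cohort_csv is not None
        if has_files == (self.synthetic is not None):
            raise ValidationError(
                "exactly one of (dvh_csv + cohort_csv) or synthetic config must be set"
            )
        if any(r <= 0 for r in self.dichotomy_radii_cm):
            raise ValidationError("dichotomy radii must be positive")


def _parse_date(s: str) -> date | None:
    return date.fromisoformat(s) if s else None


def compute_course_metrics(
    dvhs: list[DoseVolumeHistogram], params: EUDParameters
) -> pd.DataFrame:
    """Long-format per-patient, per-course, per-structure dose metrics."""
    rows = []
    for dvh in dvhs:
        try:
            cls = classify_structure(dvh.structure_name)
        except ValidationError:
            log.warning("skipping unknown structure %s", dvh.structure_name)
            continue
        summ = dose_summary(dvh)
        eud = eud_for_structure(dvh, cls, params)
        base = {
            "patient_id": dvh.patient_id,
            "course": dvh.course,
            "structure": dvh.structure_name,
        }
        rows.append({**base, "metric": "EUD", "value": eud})
        rows.append({**base, "metric": "d_max", "value": summ.d_max})
        if dvh.structure_name == "brain":
            rows.append({**base, "metric": "d_mean", "value": summ.d_mean})
        if cls is StructureClass.TARGET and dvh.absolute_volume_cc is not None:
            rows.append({**base, "metric": "volume_cc", "value": dvh.absolute_volume_cc})
            rows.append(
                {**base, "metric": "spherical_radius_cm",
                 "value": sphere_radius(dvh.absolute_volume_cc)}
            )
    return pd.DataFrame(rows)


def patient_characteristics(meta: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics table (counts and percentages)."""
    n = len(meta)
    if n == 0:
        raise DataError("empty cohort")
    rows = [("N", n, "")]

    def frac(label, count):
        rows.append((label, count, f"{round_half_up(100.0 * count / n, 1)}%"))

    frac("sex: male", int((meta["sex"] == "male").sum()))
    frac("sex: female", int((meta["sex"] == "female").sum()))
    rows.append(("age: median (range)",
                 f"{meta['age'].median():.0f}",
                 f"{meta['age'].min():.0f}-{meta['age'].max():.0f}"))
    for cat in ("methylated", "unmethylated", "unknown"):
        frac(f"mgmt: {cat}", int((meta["mgmt"] == cat).sum()))
    frac("surgery: yes", int((meta["surgery"] == 1).sum()))
    for grade in ("III", "IV"):
        frac(f"who_grade: {grade}", int((meta["who_grade"] == grade).sum()))
    frac("kps >= 70", int((meta["kps"] >= 70).sum()))
    frac("kps < 70", int((meta["kps"] < 70).sum()))
    return pd.DataFrame(rows, columns=["characteristic", "value", "detail"])


def build_endpoints(meta: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in meta.iterrows():
        ep = compute_endpoints(
            patient_id=r["patient_id"],
            rt1_start=date.fromisoformat(r["rt1_start"]),
            rert_start=date.fromisoformat(r["rert_start"]),
            last_contact=date.fromisoformat(r["last_contact"]),
            death=_parse_date(r.get("death", "")),
            progression=_parse_date(r.get("progression", "")),
        )
        rows.append(asdict(ep))
    return pd.DataFrame(rows)


def univariate_table(
    meta: pd.DataFrame, endpoints: pd.DataFrame, radii_cm=(2.0,)
) -> pd.DataFrame:
    """Univariate survival analyses over the standard covariate set.

    KPS (dichotomised at 70) is tested with the log-rank test on
    post-recurrence survival and PFS; continuous and binary covariates are
    additionally fitted with univariate Cox models per endpoint.
    """
    df = meta.merge(endpoints, on="patient_id")
    df["kps_ge70"] = (df["kps"] >= 70).astype(int)
    df["grade_iv"] = (df["who_grade"] == "IV").astype(int)
    df["male"] = (df["sex"] == "male").astype(int)
    df["mgmt_methylated"] = (df["mgmt"] == "methylated").astype(float)
    df.loc[df["mgmt"] == "unknown", "mgmt_methylated"] = np.nan
    df["rert_radius_cm"] = [
        sphere_radius(v) if np.isfinite(v) else np.nan for v in df["gtv_volume_rert_cc"]
    ]

    rows = []
    endpoints_map = {
        "PRS": ("prs_days", "prs_event"),
        "PFS": ("pfs_days", "pfs_event"),
        "OS": ("os_days", "os_event"),
    }
    covariates = [
        "age", "kps_ge70", "grade_iv", "male", "surgery",
        "mgmt_methylated", "interval_days", "rert_radius_cm",
    ]
    for ep_name, (tcol, ecol) in endpoints_map.items():
        for cov in covariates:
            sub = df[[tcol, ecol, cov]].dropna().rename(
                columns={tcol: "time_days", ecol: "event"}
            )
            try:
                res = cox_univariate(sub, cov)
            except DataError as exc:
                log.warning("univariate %s/%s skipped: %s", cov, ep_name, exc)
                continue
            rows.append(
                {
                    "variable": cov,
                    "endpoint": ep_name,
                    "test": "cox",
                    "n": res.n,
                    "statistic": math.nan,
                    "hr": res.hazard_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p_value,
                }
            )
        # log-rank for the KPS dichotomy, the study's principal grouping
        grp_a = df.loc[df["kps_ge70"] == 1, [tcol, ecol]].rename(
            columns={tcol: "time_days", ecol: "event"}
        )
        grp_b = df.loc[df["kps_ge70"] == 0, [tcol, ecol]].rename(
            columns={tcol: "time_days", ecol: "event"}
        )
        if len(grp_a) and len(grp_b):
            chi2, p = logrank(grp_a, grp_b)
            rows.append(
                {
                    "variable": "kps_ge70",
                    "endpoint": ep_name,
                    "test": "logrank",
                    "n": len(grp_a) + len(grp_b),
                    "statistic": chi2,
                    "hr": math.nan,
                    "ci_low": math.nan,
                    "ci_high": math.nan,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def km_tables(meta: pd.DataFrame, endpoints: pd.DataFrame, radii_cm=(2.0,)):
    """Kaplan-Meier curves (PRS) for the KPS and tumour-size groupings."""
    df = meta.merge(endpoints, on="patient_id")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}

    def add_curve(name, sub):
        if sub.empty:
            return
        res = km_estimate(
            sub.rename(columns={"prs_days": "time_days", "prs_event": "event"})
        )
        curves[name] = pd.DataFrame({"time_days": res.timeline, "survival": res.survival})
        medians[name] = res.median_days

    add_curve("kps_ge70", df[df["kps"] >= 70][["prs_days", "prs_event"]])
    add_curve("kps_lt70", df[df["kps"] < 70][["prs_days", "prs_event"]])
    for r_cut in radii_cm:
        vols = {
            r["patient_id"]: (None if not np.isfinite(r["gtv_volume_rert_cc"])
                              else r["gtv_volume_rert_cc"])
            for _, r in df.iterrows()
        }
        excl = set(df.loc[df["distant_lesions"] == 1, "patient_id"]) | {
            pid for pid, v in vols.items() if v is None
        }
        small, large = volume_dichotomy(vols, r_cut, exclusions=excl)
        tag = f"r{r_cut:g}cm"
        add_curve(f"gtv_small_{tag}", df[df["patient_id"].isin(small)][["prs_days", "prs_event"]])
        add_curve(f"gtv_large_{tag}", df[df["patient_id"].isin(large)][["prs_days", "prs_event"]])
    return curves, medians


def _fmt(x, nd=1) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "NR"
    if isinstance(x, float):
        return f"{round_half_up(x, nd):.{nd}f}"
    return str(x)


def render_tables(results: dict, out_dir: Path) -> None:
    """Write the report bundle as TSV files with display rounding.

    Dose and radius columns are rounded half-up to one decimal; medians that
    are not reached render as ``NR``.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    num_cols = ("median", "maximum", "corrected_median", "corrected_maximum",
                "median_rt1", "maximum_rt1", "median_rert", "maximum_rert",
                "hr", "ci_low", "ci_high", "statistic")
    for name in ("patient_characteristics", "course_doses", "cumulative_doses",
                 "univariate"):
        table = results[name].copy()
        for col in table.columns:
            if col in num_cols:
                table[col] = [_fmt(v, 3 if name == "univariate" else 1) for v in table[col]]
            elif col == "p":
                table[col] = [_fmt(v, 4) for v in table[col]]
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    for name, curve in results["km_curves"].items():
        curve.to_csv(out_dir / f"km_{name}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"group": k, "median_days": _fmt(v, 0)} for k, v in results["km_medians"].items()]
    ).to_csv(out_dir / "km_medians.tsv", sep="\t", index=False)


def _config_digest(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_analysis(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    config.validate()
    out_dir = Path(out_dir)
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        meta = cohort_metadata(cohort)
        dvhs = list(iter_dvhs(cohort))
    else:
        dvhs = read_dvh_csv(config.dvh_csv)
        meta = pd.read_csv(config.cohort_csv, dtype={"patient_id": str},
                           keep_default_na=False)
        for col in ("gtv_volume_rt1_cc", "gtv_volume_rert_cc"):
            if col in meta.columns:
                meta[col] = pd.to_numeric(meta[col], errors="coerce")
    if meta.empty:
        raise DataError("empty cohort")

    metrics = compute_course_metrics(dvhs, config.eud_params)
    endpoints = build_endpoints(meta)
    results = {
        "patient_characteristics": patient_characteristics(meta),
        "course_doses": per_course_table(metrics),
        "cumulative_doses": cohort_dose_table(
            metrics[metrics["metric"].isin(["EUD", "d_max", "d_mean"])],
            recovery_r=config.eud_params.recovery_r,
        ),
        "univariate": univariate_table(meta, endpoints, config.dichotomy_radii_cm),
    }
    curves, medians = km_tables(meta, endpoints, config.dichotomy_radii_cm)
    results["km_curves"] = curves
    results["km_medians"] = medians

    render_tables(results, out_dir)
    # serialized intermediates so `report` can re-render without recomputation
    metrics.to_csv(out_dir / "course_metrics.csv", index=False)
    endpoints.to_csv(out_dir / "endpoints.csv", index=False)
    manifest = {
        "package": "rertdose",
        "version": __version__,
        "seed": config.rng_seed,
        "config_sha256": _config_digest(config),
        "n_patients": int(len(meta)),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    results["metrics"] = metrics
    results["endpoints"] = endpoints
    return results


def simulate_to_files(config: CohortConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate a synthetic cohort and write its DVH and metadata CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    dvh_path = out_dir / "dvhs.csv"
    meta_path = out_dir / "cohort.csv"
    write_dvh_csv(list(iter_dvhs(cohort)), dvh_path)
    cohort_metadata(cohort).to_csv(meta_path, index=False)
    return dvh_path, meta_path
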