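"""Synthetic re-irradiation cohort generator.

Emulates the statistical structure of a retrospective malignant-glioma
re-irradiation series: two percutaneous radiation courses per patient
(a ~60 Gy primary course and a 36 Gy re-irradiation, both in 2 Gy
fractions), per-structure DVHs for the cranial organs at risk (optic
chiasm, brainstem, both optic nerves, whole brain) and the targets
(GTV, PTV), cohort demographics, and survival with a Karnofsky
performance-status (KPS) effect and right censoring.

DVH shapes use a three-parameter logistic family for the cumulative curve,

    v(D) = (1 - spared_fraction) * logistic((d50 - D) / spread),   D > 0,
    v(0) = 1,

where ``d50`` is the dose received by half of the non-spared volume,
``spread`` controls the fall-off width and ``spared_fraction`` the part of
the structure receiving essentially no dose.  The family is illustrative —
chosen for plausibility and interpretability, not fitted to any plan data.

Survival is Weibull proportional hazards: patients with KPS >= 70 follow the
baseline; KPS < 70 multiplies the hazard.  Default shape 1.2 and scale 418
days put the good-KPS median near 308 days, and the default hazard ratio
1.96 puts the poor-KPS median near 176 days.  A hardcopy-digitisation
emulator subsamples a DVH curve with jitter, mimicking raw data recovered
from printed plan documents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterator

import numpy as np
import pandas as pd

from .dvh import (
    CUMULATIVE,
    DEFAULT_BIN_GY,
    DoseVolumeHistogram,
    default_grid,
)
from .errors import ParameterError, ValidationError

STRUCTURES = (
    "optic_chiasm",
    "brainstem",
    "optic_nerve_left",
    "optic_nerve_right",
    "brain",
    "gtv",
    "ptv",
)

OAR_STRUCTURES = STRUCTURES[:5]


@dataclass(frozen=True)
class DVHShape:
    """Logistic cumulative-DVH shape parameters for one structure.

    ``d_max_gy`` is a hard cap: no voxel receives more than this dose.
    Planned dose distributions end steeply near the plan maximum, so the
    logistic tail is truncated there rather than decaying forever.
    """

    d50_gy: float
    spread_gy: float
    spared_fraction: float = 0.0
    d_max_gy: float | None = None

    def __post_init__(self):
        if self.d50_gy < 0:
            raise ParameterError("d50 must be non-negative")
        if self.spread_gy <= 0:
            raise ParameterError("spread must be positive")
        if not 0.0 <= self.spared_fraction < 1.0:
            raise ParameterError("spared_fraction must lie in [0, 1)")
        if self.d_max_gy is not None and self.d_max_gy <= 0:
            raise ParameterError("d_max_gy must be positive when given")


# Illustrative per-structure shapes: OAR doses fall well below the target
# prescription at re-irradiation (conformal re-treatment of a recurrence),
# while primary-course OAR exposure is substantially higher.  Caps keep
# every structure below ~105% of the course prescription.
_RT1_SHAPES = {
    "optic_chiasm": DVHShape(40.0, 4.0, 0.10, 50.0),
    "brainstem": DVHShape(40.0, 4.5, 0.10, 54.0),
    "optic_nerve_left": DVHShape(17.0, 6.0, 0.30, 26.0),
    "optic_nerve_right": DVHShape(16.0, 6.0, 0.30, 25.0),
    "brain": DVHShape(22.0, 11.0, 0.05, 62.0),
    "gtv": DVHShape(60.0, 0.8, 0.0, 62.5),
    "ptv": DVHShape(59.3, 1.3, 0.0, 62.5),
}
_RERT_SHAPES = {
    "optic_chiasm": DVHShape(7.0, 1.5, 0.25, 10.0),
    "brainstem": DVHShape(15.0, 3.0, 0.20, 23.0),
    "optic_nerve_left": DVHShape(2.0, 0.8, 0.40, 3.5),
    "optic_nerve_right": DVHShape(3.0, 0.8, 0.40, 4.5),
    "brain": DVHShape(10.0, 7.0, 0.10, 37.8),
    "gtv": DVHShape(36.0, 0.8, 0.0, 37.8),
    "ptv": DVHShape(34.5, 1.5, 0.0, 37.8),
}

# Fraction of patients whose primary-course DVH is unavailable for each
# structure (plans from outside institutions, uncontoured organs, hardcopies
# only); re-irradiation data are always present.
_RT1_MISSING = {
    "optic_chiasm": 0.57,
    "brainstem": 0.53,
    "optic_nerve_left": 0.55,
    "optic_nerve_right": 0.60,
    "brain": 0.79,
    "gtv": 0.64,
    "ptv": 0.62,
}


@dataclass
class SurvivalModel:
    """Weibull proportional-hazards survival generator settings."""

    weibull_shape: float = 1.2
    weibull_scale_days: float = 418.0  # good-KPS median ~ 308 days
    kps_low_hazard_ratio: float = 1.96  # poor-KPS median ~ 176 days
    censoring_rate: float = 0.2
    baseline: str = "weibull"  # or "exponential" (shape fixed at 1)


@dataclass
class CohortConfig:
    """All distributions and effect sizes for cohort generation."""

    n_patients: int = 58
    p_male: float = 0.621
    age_median: float = 52.0
    age_range: tuple[float, float] = (18.0, 68.0)
    p_mgmt: tuple[float, float, float] = (0.345, 0.483, 0.172)  # meth/unmeth/unknown
    p_surgery: float = 0.81
    p_grade_iv: float = 0.793
    p_kps_ge70: float = 0.759
    rt1_dose_gy: float = 60.0
    rert_dose_gy: float = 36.0
    fraction_gy: float = 2.0
    interval_min_days: float = 173.0
    interval_median_days: float = 642.0
    interval_log_sigma: float = 0.8
    dvh_bin_gy: float = DEFAULT_BIN_GY
    d50_log_jitter: float = 0.15
    target_d50_log_jitter: float = 0.03
    spread_log_jitter: float = 0.10
    spared_jitter: float = 0.05
    rt1_shapes: dict = field(default_factory=lambda: dict(_RT1_SHAPES))
    rert_shapes: dict = field(default_factory=lambda: dict(_RERT_SHAPES))
    rt1_missing: dict = field(default_factory=lambda: dict(_RT1_MISSING))
    n_distant_lesions: int = 2
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    rng_seed: int = 0

    def validate(self) -> None:
        probs = [self.p_male, self.p_surgery, self.p_grade_iv, self.p_kps_ge70,
                 *self.p_mgmt, self.survival.censoring_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")
        if abs(sum(self.p_mgmt) - 1.0) > 1e-9:
            raise ParameterError("MGMT category probabilities must sum to 1")
        if self.n_patients < 2:
            raise ParameterError("need at least 2 patients")
        if self.rt1_dose_gy <= 0 or self.rert_dose_gy <= 0:
            raise ParameterError("prescription doses must be positive")


@dataclass
class PatientRecord:
    """One synthetic patient with demographics, dates and two courses."""

    patient_id: str
    sex: str
    age: int
    kps: int
    who_grade: str
    mgmt: str
    surgery: bool
    distant_lesions: bool
    rt1_start: date
    rert_start: date
    last_contact: date
    death: date | None
    progression: date | None
    gtv_volume_rt1_cc: float
    gtv_volume_rert_cc: float
    ptv_volume_rt1_cc: float
    ptv_volume_rert_cc: float
    dvhs: dict = field(default_factory=dict)  # (course, structure) -> DVH

    @property
    def kps_ge70(self) -> bool:
        return self.kps >= 70


def synth_dvh(
    structure_name: str,
    d50_gy: float,
    spread_gy: float,
    spared_fraction: float = 0.0,
    d_max_gy: float | None = None,
    grid: np.ndarray | None = None,
    bin_gy: float = DEFAULT_BIN_GY,
) -> DoseVolumeHistogram:
    """Cumulative DVH from the logistic shape family.

    ``v(D) = (1 - spared_fraction) / (1 + exp((D - d50)/spread))`` for D > 0,
    with ``v(0)`` pinned to 1 so the spared fraction sits in the first bin,
    truncated to zero above ``d_max_gy`` when a cap is given.  The grid
    defaults to 0.1 Gy bins out to where the curve has decayed (or to one
    bin past the cap).
    """
    shape = DVHShape(d50_gy, spread_gy, spared_fraction, d_max_gy)  # validates
    if grid is None:
        top = d_max_gy if d_max_gy is not None else d50_gy + 12.0 * spread_gy
        grid = default_grid(top, bin_gy)
    grid = np.asarray(grid, dtype=float)
    with np.errstate(over="ignore"):
        v = (1.0 - shape.spared_fraction) / (1.0 + np.exp((grid - shape.d50_gy) / shape.spread_gy))
    if shape.d_max_gy is not None:
        v[grid >= shape.d_max_gy] = 0.0
    v[0] = 1.0
    v = np.minimum.accumulate(np.clip(v, 0.0, 1.0))
    v[v < 1e-12] = 0.0
    return DoseVolumeHistogram(structure_name, CUMULATIVE, grid, v)


def emulate_hardcopy(
    dvh: DoseVolumeHistogram,
    n_points: int = 30,
    dose_jitter_gy: float = 0.3,
    volume_jitter: float = 0.005,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Sample a printed-curve digitisation of a cumulative DVH.

    Returns ``n_points`` (dose, volume) pairs read off the curve at evenly
    spaced doses across its support, with additive Gaussian jitter on both
    axes — the kind of noise manual digitisation of a plan hardcopy
    introduces.  Deterministic for a fixed seed.
    """
    if dvh.mode != CUMULATIVE:
        raise ValidationError("hardcopy emulation expects a cumulative DVH")
    if n_points < 5:
        raise ValidationError("need at least 5 digitisation points")
    rng = np.random.default_rng(seed)
    doses = np.linspace(0.0, float(dvh.dose_edges[-1]), n_points)
    vols = np.interp(doses, dvh.dose_edges, dvh.volume)
    doses = doses + rng.normal(0.0, dose_jitter_gy, n_points)
    doses[0] = 0.0  # the origin of the printed axes is unambiguous
    vols = vols + rng.normal(0.0, volume_jitter, n_points)
    return list(zip(np.abs(doses).tolist(), vols.tolist()))


def _jittered_shape(
    shape: DVHShape, cfg: CohortConfig, rng: np.random.Generator, is_target: bool = False
) -> DVHShape:
    # target coverage follows the prescription closely; OAR exposure varies
    # with anatomy, so it gets the wider patient-to-patient jitter.  Targets
    # never acquire a spared (zero-dose) fraction: they are covered by design.
    sigma = cfg.target_d50_log_jitter if is_target else cfg.d50_log_jitter
    factor = float(rng.lognormal(0.0, sigma))
    d50 = shape.d50_gy * factor
    spread = shape.spread_gy * float(rng.lognormal(0.0, cfg.spread_log_jitter))
    if is_target or shape.spared_fraction == 0.0:
        spared = shape.spared_fraction
    else:
        spared = float(
            np.clip(shape.spared_fraction + rng.normal(0.0, cfg.spared_jitter), 0.0, 0.95)
        )
    cap = None if shape.d_max_gy is None else shape.d_max_gy * factor
    return DVHShape(d50, spread, spared, cap)


def _sample_survival_days(kps_ge70: bool, model: SurvivalModel, rng: np.random.Generator) -> float:
    shape = 1.0 if model.baseline == "exponential" else model.weibull_shape
    hr = 1.0 if kps_ge70 else model.kps_low_hazard_ratio
    u = rng.uniform()
    return model.weibull_scale_days * (-math.log(u) / hr) ** (1.0 / shape)


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Draw a full synthetic cohort; deterministic for a fixed ``rng_seed``."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_patients
    lo, hi = cfg.age_range
    # triangular mode placed so the distribution median matches the
    # configured one (median = lo + sqrt((hi-lo)(mode-lo)/2) when mode is
    # above the median)
    mode = float(np.clip(lo + 2.0 * (cfg.age_median - lo) ** 2 / (hi - lo), lo, hi))

    # mean event time of the KPS mixture, used to calibrate the independent
    # exponential censoring so P(censored) ~= censoring_rate
    sm = cfg.survival
    w_shape = 1.0 if sm.baseline == "exponential" else sm.weibull_shape
    mean_t = (
        sm.weibull_scale_days
        * math.gamma(1.0 + 1.0 / w_shape)
        * (cfg.p_kps_ge70 + (1.0 - cfg.p_kps_ge70) * sm.kps_low_hazard_ratio ** (-1.0 / w_shape))
    )
    p_c = sm.censoring_rate
    censor_scale = mean_t * (1.0 - p_c) / p_c if p_c > 0 else 0.0

    distant = set(rng.choice(n, size=min(cfg.n_distant_lesions, n), replace=False).tolist())
    patients: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        sex = "male" if rng.uniform() < cfg.p_male else "female"
        age = int(round(rng.triangular(lo, mode, hi)))
        kps_good = rng.uniform() < cfg.p_kps_ge70
        kps = int(rng.choice([70, 80, 90, 100])) if kps_good else int(rng.choice([40, 50, 60]))
        mgmt = ["methylated", "unmethylated", "unknown"][
            int(rng.choice(3, p=list(cfg.p_mgmt)))
        ]
        grade = "IV" if rng.uniform() < cfg.p_grade_iv else "III"
        surgery = bool(rng.uniform() < cfg.p_surgery)

        rt1_start = date(2007, 1, 1) + timedelta(days=int(rng.integers(0, 1200)))
        interval = max(
            cfg.interval_min_days,
            float(rng.lognormal(math.log(cfg.interval_median_days), cfg.interval_log_sigma)),
        )
        rert_start = rt1_start + timedelta(days=int(round(interval)))

        t_death = max(1.0, _sample_survival_days(kps_good, cfg.survival, rng))
        t_prog = t_death * float(rng.beta(2.0, 1.0))
        # independent exponential loss-to-follow-up, calibrated so roughly
        # `censoring_rate` of patients are censored (KM stays unbiased only
        # when censoring is independent of the event time)
        t_censor = rng.exponential(censor_scale) if censor_scale else math.inf
        if t_censor < t_death:
            t_follow = max(1.0, t_censor)
            death = None
            last_contact = rert_start + timedelta(days=int(round(t_follow)))
            progression = (
                rert_start + timedelta(days=int(round(t_prog))) if t_prog < t_follow else None
            )
        else:
            death = rert_start + timedelta(days=int(round(t_death)))
            last_contact = death
            progression = rert_start + timedelta(days=max(1, int(round(t_prog))))

        dvhs: dict[tuple[str, str], DoseVolumeHistogram] = {}
        volumes: dict[tuple[str, str], float] = {}
        for course, shapes, scale in (
            ("RT1", cfg.rt1_shapes, cfg.rt1_dose_gy / 60.0),
            ("ReRT", cfg.rert_shapes, cfg.rert_dose_gy / 36.0),
        ):
            for structure in STRUCTURES:
                base = shapes[structure]
                cap = None if base.d_max_gy is None else base.d_max_gy * scale
                shp = _jittered_shape(
                    DVHShape(base.d50_gy * scale, base.spread_gy, base.spared_fraction, cap),
                    cfg,
                    rng,
                    is_target=structure in ("gtv", "ptv"),
                )
                if course == "RT1" and rng.uniform() < cfg.rt1_missing.get(structure, 0.0):
                    continue
                dvh = synth_dvh(
                    structure, shp.d50_gy, shp.spread_gy, shp.spared_fraction,
                    d_max_gy=shp.d_max_gy, bin_gy=cfg.dvh_bin_gy,
                )
                if structure in ("gtv", "ptv"):
                    # lognormal absolute volumes: GTV median ~35 cc, PTV larger
                    med = 35.0 if structure == "gtv" else (290.0 if course == "RT1" else 120.0)
                    volumes[(course, structure)] = float(rng.lognormal(math.log(med), 0.7))
                dvhs[(course, structure)] = DoseVolumeHistogram(
                    structure, dvh.mode, dvh.dose_edges, dvh.volume,
                    absolute_volume_cc=volumes.get((course, structure)),
                    patient_id=pid, course=course,
                )

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age=age,
                kps=kps,
                who_grade=grade,
                mgmt=mgmt,
                surgery=surgery,
                distant_lesions=i in distant,
                rt1_start=rt1_start,
                rert_start=rert_start,
                last_contact=last_contact,
                death=death,
                progression=progression,
                gtv_volume_rt1_cc=volumes.get(("RT1", "gtv"), float("nan")),
                gtv_volume_rert_cc=volumes.get(("ReRT", "gtv"), float("nan")),
                ptv_volume_rt1_cc=volumes.get(("RT1", "ptv"), float("nan")),
                ptv_volume_rert_cc=volumes.get(("ReRT", "ptv"), float("nan")),
                dvhs=dvhs,
            )
        )
    return patients


def cohort_metadata(patients: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient demographics/dates into the cohort metadata table."""
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "age": p.age,
                "kps": p.kps,
                "who_grade": p.who_grade,
                "mgmt": p.mgmt,
                "surgery": int(p.surgery),
                "distant_lesions": int(p.distant_lesions),
                "rt1_start": p.rt1_start.isoformat(),
                "rert_start": p.rert_start.isoformat(),
                "last_contact": p.last_contact.isoformat(),
                "death": p.death.isoformat() if p.death else "",
                "progression": p.progression.isoformat() if p.progression else "",
                "gtv_volume_rt1_cc": p.gtv_volume_rt1_cc,
                "gtv_volume_rert_cc": p.gtv_volume_rert_cc,
                "ptv_volume_rt1_cc": p.ptv_volume_rt1_cc,
                "ptv_volume_rert_cc": p.ptv_volume_rert_cc,
            }
        )
    return pd.DataFrame(rows)


def iter_dvhs(patients: list[PatientRecord]) -> Iterator[DoseVolumeHistogram]:
    for p in patients:
        for dvh in p.dvhs.values():
            yield dvh
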