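"""Synthetic cohort generator: marginals, DVH validity, determinism,
hardcopy digitisation emulation, survival-model parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from rertdose import (
    CohortConfig,
    SurvivalModel,
    days_to_months,
    dose_summary,
    emulate_hardcopy,
    eud_for_structure,
    generate_cohort,
    geud,
    ingest_digitized_points,
    km_estimate,
    synth_dvh,
)
from rertdose.cohort import STRUCTURES, cohort_metadata, iter_dvhs
from rertdose.errors import ParameterError, ValidationError
from rertdose.pipeline import build_endpoints


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=58, rng_seed=7))


@pytest.fixture(scope="module")
def big_metadata():
    pats = generate_cohort(CohortConfig(n_patients=1000, rng_seed=11))
    return cohort_metadata(pats), pats


class TestConfig:
    def test_bad_probability_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(CohortConfig(p_male=1.5))

    def test_mgmt_probs_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            generate_cohort(CohortConfig(p_mgmt=(0.5, 0.5, 0.5)))

    def test_too_few_patients_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(CohortConfig(n_patients=1))


class TestSynthDvh:
    def test_near_step_limit_all_euds_agree(self):
        dvh = synth_dvh("gtv", d50_gy=60.0, spread_gy=1e-3, spared_fraction=0.0)
        s = dose_summary(dvh)
        for val in (
            s.d_mean,
            eud_for_structure(dvh, "gtv"),
            geud(dvh, 12),
        ):
            assert val == pytest.approx(60.0, abs=0.2)

    def test_spared_fraction_halves_mean(self):
        full = dose_summary(synth_dvh("brain", 30.0, 4.0, 0.0)).d_mean
        half = dose_summary(synth_dvh("brain", 30.0, 4.0, 0.5)).d_mean
        assert half == pytest.approx(0.5 * full, rel=0.05)

    def test_dose_cap_truncates(self):
        dvh = synth_dvh("optic_chiasm", 40.0, 4.0, 0.1, d_max_gy=50.0)
        assert dose_summary(dvh).d_max <= 50.0 + 0.1

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            synth_dvh("brain", 30.0, -1.0)
        with pytest.raises(ParameterError):
            synth_dvh("brain", 30.0, 1.0, spared_fraction=1.0)

    @pytest.mark.parametrize("d50,spread,spared", [(7, 1.5, 0.25), (60, 0.8, 0.0), (22, 11, 0.05)])
    def test_output_is_valid_cumulative(self, d50, spread, spared):
        dvh = synth_dvh("brainstem", d50, spread, spared)
        assert dvh.mode == "cumulative"  # constructor enforced the invariants


class TestCohortStructure:
    def test_determinism(self):
        cfg = CohortConfig(n_patients=20, rng_seed=123)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        ma, mb = cohort_metadata(a), cohort_metadata(b)
        pd.testing.assert_frame_equal(ma, mb)
        for pa, pb in zip(a, b):
            assert pa.dvhs.keys() == pb.dvhs.keys()
            for key in pa.dvhs:
                np.testing.assert_array_equal(pa.dvhs[key].volume, pb.dvhs[key].volume)

    def test_all_structures_present_at_rert(self, small_cohort):
        for p in small_cohort:
            for s in STRUCTURES:
                assert ("ReRT", s) in p.dvhs

    def test_some_rt1_dvhs_missing(self, small_cohort):
        n_chiasm = sum(("RT1", "optic_chiasm") in p.dvhs for p in small_cohort)
        assert 0 < n_chiasm < len(small_cohort)

    def test_two_patients_flagged_distant(self, small_cohort):
        assert sum(p.distant_lesions for p in small_cohort) == 2

    def test_generated_dvhs_valid(self, small_cohort):
        for dvh in iter_dvhs(small_cohort[:10]):
            assert dvh.volume[0] == 1.0
            assert np.all(np.diff(dvh.volume) <= 1e-12)

    def test_interval_above_minimum(self, small_cohort):
        meta = cohort_metadata(small_cohort)
        ep = build_endpoints(meta)
        assert (ep["interval_days"] >= 173).all()
        assert days_to_months(ep["interval_days"].min()) >= 5.8

    def test_rert_target_eud_below_prescription(self, small_cohort):
        euds = [
            eud_for_structure(p.dvhs[("ReRT", "gtv")], "gtv") for p in small_cohort
        ]
        assert np.median(euds) < 36.0


class TestMarginals:
    def test_male_fraction(self, big_metadata):
        meta, _ = big_metadata
        assert (meta.sex == "male").mean() == pytest.approx(0.621, abs=0.03)

    def test_grade_iv_fraction(self, big_metadata):
        meta, _ = big_metadata
        assert (meta.who_grade == "IV").mean() == pytest.approx(0.793, abs=0.03)

    def test_kps_and_surgery_fractions(self, big_metadata):
        meta, _ = big_metadata
        assert (meta.kps >= 70).mean() == pytest.approx(0.759, abs=0.03)
        assert meta.surgery.mean() == pytest.approx(0.81, abs=0.03)

    def test_age_median_and_range(self, big_metadata):
        meta, _ = big_metadata
        assert meta.age.median() == pytest.approx(52, abs=2)
        assert meta.age.min() >= 18 and meta.age.max() <= 68


class TestSurvivalParameterRecovery:
    def test_km_medians_recover_configured_targets(self):
        """Closing the loop: configured 308 / 176 day medians come back out
        of the Kaplan-Meier estimate at large n within 10%."""
        pats = generate_cohort(CohortConfig(n_patients=3000, rng_seed=5))
        meta = cohort_metadata(pats)
        ep = build_endpoints(meta)
        df = meta.merge(ep, on="patient_id")
        good = df[df.kps >= 70].rename(columns={"prs_days": "time_days", "prs_event": "event"})
        poor = df[df.kps < 70].rename(columns={"prs_days": "time_days", "prs_event": "event"})
        m_good = km_estimate(good[["time_days", "event"]]).median_days
        m_poor = km_estimate(poor[["time_days", "event"]]).median_days
        assert m_good == pytest.approx(308, rel=0.10)
        assert m_poor == pytest.approx(176, rel=0.10)
        assert m_good > m_poor  # better performance status -> longer survival


class TestHardcopyEmulation:
    def test_zero_jitter_round_trip(self):
        dvh = synth_dvh("optic_chiasm", 40.0, 4.0, 0.1, d_max_gy=50.0)
        pts = emulate_hardcopy(dvh, n_points=40, dose_jitter_gy=0.0, volume_jitter=0.0, seed=3)
        rebuilt = ingest_digitized_points(pts)
        expected = np.interp(rebuilt.dose_edges, dvh.dose_edges, dvh.volume)
        np.testing.assert_allclose(rebuilt.volume, expected, atol=1e-9)

    def test_fixed_seed_is_deterministic(self):
        dvh = synth_dvh("brainstem", 42.0, 5.0, 0.1)
        a = emulate_hardcopy(dvh, seed=9)
        b = emulate_hardcopy(dvh, seed=9)
        assert a == b

    def test_too_few_points_rejected(self):
        dvh = synth_dvh("brainstem", 42.0, 5.0, 0.1)
        with pytest.raises(ValidationError):
            emulate_hardcopy(dvh, n_points=4)

    def test_low_jitter_recovers_geud(self):
        """30-point digitisations with realistic jitter recover gEUD(k=12)
        within 2% in at least 95% of seeds."""
        dvh = synth_dvh("optic_chiasm", 40.0, 4.0, 0.1, d_max_gy=50.0)
        truth = geud(dvh, 12)
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            pts = emulate_hardcopy(
                dvh, n_points=30, dose_jitter_gy=0.3, volume_jitter=0.005, seed=seed
            )
            rec = geud(ingest_digitized_points(pts), 12)
            ok += abs(rec - truth) / truth <= 0.02
        assert ok >= 95
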