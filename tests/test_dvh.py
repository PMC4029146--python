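"""DVH model, conversions, resampling, digitised-point ingestion, CSV I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rertdose import (
    DoseVolumeHistogram,
    dose_summary,
    ingest_digitized_points,
    read_dvh_csv,
    resample_cumulative,
    to_cumulative,
    to_differential,
    write_dvh_csv,
)
from rertdose.errors import ParseError, ValidationError

from conftest import random_cumulative_dvh


class TestValidation:
    def test_cumulative_must_start_at_one(self):
        with pytest.raises(ValidationError):
            DoseVolumeHistogram("brain", "cumulative", [0, 10], [0.9, 0.5])

    def test_cumulative_must_be_non_increasing(self):
        with pytest.raises(ValidationError, match="non-increasing"):
            DoseVolumeHistogram("brain", "cumulative", [0, 10, 20], [1.0, 0.4, 0.6])

    def test_edges_strictly_increasing_with_index(self):
        with pytest.raises(ValidationError, match="index 2"):
            DoseVolumeHistogram("brain", "cumulative", [0, 10, 10], [1.0, 0.5, 0.2])

    def test_differential_fractions_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            DoseVolumeHistogram("brain", "differential", [0, 10, 20], [0.5, 0.4])

    def test_negative_bin_fraction_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            DoseVolumeHistogram("brain", "differential", [0, 10, 20], [1.2, -0.2])


class TestConversions:
    def test_finite_difference(self, step_cumulative):
        diff = to_differential(step_cumulative)
        np.testing.assert_allclose(diff.volume, [0.0, 0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(diff.bin_midpoints, [10.0, 30.0, 50.0])

    def test_uniform_dose_single_bin(self):
        eps = 1e-3
        dvh = DoseVolumeHistogram("gtv", "cumulative", [0.0, 50.0, 50.0 + eps], [1.0, 1.0, 0.0])
        diff = to_differential(dvh)
        assert diff.volume[-1] == pytest.approx(1.0)
        assert diff.bin_midpoints[-1] == pytest.approx(50.0, abs=eps)

    def test_round_trip_identity(self, step_cumulative):
        back = to_cumulative(to_differential(step_cumulative))
        np.testing.assert_allclose(back.volume, step_cumulative.volume, atol=1e-9)
        np.testing.assert_array_equal(back.dose_edges, step_cumulative.dose_edges)

    def test_single_bin_step(self):
        diff = DoseVolumeHistogram("gtv", "differential", [0.0, 50.0], [1.0])
        cum = to_cumulative(diff)
        np.testing.assert_allclose(cum.volume, [1.0, 0.0])

    def test_wrong_mode_rejected(self, step_cumulative, two_bin_diff):
        with pytest.raises(ValidationError):
            to_differential(two_bin_diff)
        with pytest.raises(ValidationError):
            to_cumulative(step_cumulative)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_random(self, seed):
        dvh = random_cumulative_dvh(np.random.default_rng(seed))
        back = to_cumulative(to_differential(dvh))
        np.testing.assert_allclose(back.volume[1:], dvh.volume[1:], atol=1e-9)


class TestResample:
    def test_identity_on_own_grid(self, step_cumulative):
        out = resample_cumulative(step_cumulative, step_cumulative.dose_edges)
        np.testing.assert_allclose(out.volume, step_cumulative.volume)

    def test_linear_interpolation(self):
        dvh = DoseVolumeHistogram("brain", "cumulative", [0.0, 60.0], [1.0, 0.0])
        out = resample_cumulative(dvh, [0.0, 30.0, 60.0])
        assert out.volume[1] == pytest.approx(0.5)

    def test_zero_beyond_support(self, step_cumulative):
        out = resample_cumulative(step_cumulative, [0.0, 50.0, 100.0])
        assert out.volume[-1] == 0.0

    def test_empty_grid_rejected(self, step_cumulative):
        with pytest.raises(ValidationError):
            resample_cumulative(step_cumulative, [])

    def test_refinement_preserves_mean(self, step_cumulative):
        fine = np.union1d(step_cumulative.dose_edges, np.arange(0, 60.5, 0.5))
        out = resample_cumulative(step_cumulative, fine)
        m0 = dose_summary(step_cumulative).d_mean
        m1 = dose_summary(out).d_mean
        assert m1 == pytest.approx(m0, abs=1e-9)


class TestDigitizedPoints:
    def test_sorting_only(self):
        dvh = ingest_digitized_points([(40, 0.5), (0, 1.0), (20, 0.98)])
        np.testing.assert_allclose(dvh.volume, [1.0, 0.98, 0.5])
        np.testing.assert_allclose(dvh.dose_edges, [0.0, 20.0, 40.0])

    def test_running_minimum_removes_bumps(self):
        dvh = ingest_digitized_points([(0, 1.0), (20, 0.60), (25, 0.62), (40, 0.3)])
        np.testing.assert_allclose(dvh.volume, [1.0, 0.60, 0.60, 0.3])

    def test_clipping_and_prepend(self):
        dvh = ingest_digitized_points([(10, 1.2), (60, -0.1)])
        np.testing.assert_allclose(dvh.dose_edges, [0.0, 10.0, 60.0])
        np.testing.assert_allclose(dvh.volume, [1.0, 1.0, 0.0])

    @pytest.mark.parametrize(
        "points", [[(10, 0.5)], [(5, 1.0), (5, 0.7), (5, 0.2)]],
        ids=["too-few", "all-equal-doses"],
    )
    def test_bad_inputs_rejected(self, points):
        with pytest.raises(ValidationError):
            ingest_digitized_points(points)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 80.0, allow_nan=False),
                st.floats(-0.5, 1.5, allow_nan=False),
            ),
            min_size=2,
            max_size=50,
        )
    )
    def test_always_yields_valid_cumulative(self, points):
        doses = [p[0] for p in points]
        if len(set(doses)) < 2:
            return
        dvh = ingest_digitized_points(points)  # validation runs in constructor
        assert dvh.mode == "cumulative"
        assert dvh.volume[0] == 1.0
        assert np.all(np.diff(dvh.volume) <= 1e-12)


class TestDoseSummary:
    def test_two_bin_example(self):
        dvh = DoseVolumeHistogram(
            "brainstem", "differential", [0, 20, 40, 60], [0.0, 0.5, 0.5]
        )
        s = dose_summary(dvh)
        assert (s.d_min, s.d_mean, s.d_max) == (20.0, 40.0, 60.0)

    def test_uniform_dose(self):
        eps = 1e-9
        dvh = DoseVolumeHistogram("gtv", "cumulative", [0, 50 - eps, 50 + eps], [1, 1, 0])
        s = dose_summary(dvh)
        assert s.d_min == pytest.approx(50.0, abs=1e-6)
        assert s.d_mean == pytest.approx(50.0, abs=1e-6)
        assert s.d_max == pytest.approx(50.0, abs=1e-6)

    def test_zero_dose_structure(self):
        dvh = DoseVolumeHistogram("nerve", "cumulative", [0.0, 1e-9], [1.0, 0.0])
        s = dose_summary(dvh)
        assert s.d_max <= 1e-8

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ordering_invariant(self, seed):
        dvh = random_cumulative_dvh(np.random.default_rng(seed))
        s = dose_summary(dvh)
        assert s.d_min <= s.d_mean <= s.d_max


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path, step_cumulative, two_bin_diff):
        path = tmp_path / "dvh.csv"
        a = step_cumulative.with_labels(patient_id="P1", course="RT1")
        b = two_bin_diff.with_labels(patient_id="P1", course="ReRT")
        write_dvh_csv([a, b], path)
        out = read_dvh_csv(path)
        assert len(out) == 2
        for orig, back in zip([a, b], out):
            assert back.mode == orig.mode
            assert back.structure_name == orig.structure_name
            np.testing.assert_allclose(back.dose_edges, orig.dose_edges, atol=1e-6)
            np.testing.assert_allclose(back.volume, orig.volume, atol=1e-6)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("patient_id,structure\nP1,brain\n")
        with pytest.raises(ParseError, match="missing required columns"):
            read_dvh_csv(p)

    def test_unknown_mode_token(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "patient_id,course,structure,mode,dose_gy,volume_fraction,absolute_volume_cc\n"
            "P1,RT1,brain,absolute,0,1.0,\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_dvh_csv(p)

    def test_non_numeric_cell_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "patient_id,course,structure,mode,dose_gy,volume_fraction,absolute_volume_cc\n"
            "P1,RT1,brain,cumulative,0,1.0,\n"
            "P1,RT1,brain,cumulative,ten,0.5,\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_dvh_csv(p)

    def test_increasing_cumulative_rejected_on_read(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "patient_id,course,structure,mode,dose_gy,volume_fraction,absolute_volume_cc\n"
            "P1,RT1,brain,cumulative,0,1.0,\n"
            "P1,RT1,brain,cumulative,10,0.4,\n"
            "P1,RT1,brain,cumulative,20,0.6,\n"
        )
        with pytest.raises(ValidationError, match="non-increasing"):
            read_dvh_csv(p)
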