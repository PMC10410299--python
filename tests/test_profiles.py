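"""Trajectory model: oscillation, dampening, calibration, cold kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldclock.profiles import (
    ClockGeneProfile,
    ColdResponseSpec,
    calibrate_amplitude,
    calibrate_dampening,
    diurnal_mean,
)


def make_profile(amplitude=1.0, phase=2.5, cold=None, baseline=100.0):
    return ClockGeneProfile("g", baseline, amplitude=amplitude, phase=phase,
                            cold=cold or ColdResponseSpec())


class TestCalibrateAmplitude:
    def test_closed_form(self):
        # a = ln(10) / (1 - cos(pi/4)), evaluated independently
        expected = math.log(10.0) / (1.0 - math.cos(math.pi / 4.0))
        assert calibrate_amplitude(10.0, 2.5, 5.5, 2.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.8615, abs=1e-4)

    def test_unit_fold_needs_no_oscillation(self):
        assert calibrate_amplitude(1.0, 2.5, 5.5, 2.5) == 0.0

    def test_degenerate_times_raise(self):
        # t0 and t1 symmetric about the peak -> equal cosines
        with pytest.raises(ValueError, match="unidentifiable"):
            calibrate_amplitude(2.0, 1.5, 3.5, 2.5)

    @pytest.mark.parametrize("fold,phase", [(10.0, 2.5), (3.0, 14.5), (1.7, 20.0)])
    def test_round_trip(self, fold, phase):
        a = calibrate_amplitude(fold, 2.5, 5.5, phase)
        prof = ClockGeneProfile("g", 50.0, amplitude=abs(a), phase=phase)
        realized = diurnal_mean(prof, 2.5) / diurnal_mean(prof, 5.5)
        assert realized == pytest.approx(fold if a > 0 else 1.0 / fold, rel=1e-12)


class TestAmbientTrajectory:
    def test_maximum_at_phase(self):
        prof = make_profile(amplitude=2.0, phase=7.0)
        grid = np.linspace(0, 24, 2401)
        values = diurnal_mean(prof, grid)
        assert diurnal_mean(prof, 7.0) == pytest.approx(prof.baseline * math.exp(2.0))
        assert values.max() <= diurnal_mean(prof, 7.0) + 1e-9

    @settings(max_examples=50, deadline=None)
    @given(t=st.floats(0, 96), a=st.floats(0, 5), phase=st.floats(0, 23.999))
    def test_periodicity(self, t, a, phase):
        prof = make_profile(amplitude=a, phase=phase)
        m1 = diurnal_mean(prof, t)
        m2 = diurnal_mean(prof, t + prof.period)
        assert m2 == pytest.approx(m1, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            diurnal_mean(make_profile(), -1.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            diurnal_mean(make_profile(), 3.0, condition="tepid")


class TestColdTrajectory:
    def test_full_dampening_is_flat(self):
        cold = ColdResponseSpec(category="static", dampening=0.0)
        prof = make_profile(amplitude=3.0, cold=cold)
        level = diurnal_mean(prof, 2.5)
        for t in (3.0, 5.5, 12.0, 26.0):
            assert diurnal_mean(prof, t, "cold") == pytest.approx(level, rel=1e-12)

    def test_no_dampening_equals_ambient(self):
        cold = ColdResponseSpec(category="static", dampening=1.0)
        prof = make_profile(amplitude=3.0, cold=cold)
        t = np.linspace(0, 48, 97)
        np.testing.assert_allclose(diurnal_mean(prof, t, "cold"),
                                   diurnal_mean(prof, t), rtol=1e-12)

    def test_before_treatment_cold_equals_ambient(self):
        cold = ColdResponseSpec(category="induced", fold=5.0)
        prof = make_profile(amplitude=0.5, cold=cold)
        assert diurnal_mean(prof, 1.0, "cold") == pytest.approx(diurnal_mean(prof, 1.0))

    @pytest.mark.parametrize("category,fold", [("induced", 8.0), ("repressed", 4.0)])
    def test_monotone_cold_kinetics(self, category, fold):
        cold = ColdResponseSpec(category=category, fold=fold, rate=0.7)
        prof = make_profile(amplitude=0.0, cold=cold)
        t = np.linspace(2.5, 26.5, 200)
        values = diurnal_mean(prof, t, "cold")
        diffs = np.diff(values)
        assert np.all(diffs > 0) if category == "induced" else np.all(diffs < 0)
        # saturates at the declared fold
        target = fold if category == "induced" else 1.0 / fold
        assert values[-1] / values[0] == pytest.approx(target, rel=1e-6)

    def test_resumption_restores_oscillation(self):
        cold = ColdResponseSpec(category="static", dampening=0.0, resume_peak_delay=3.0)
        prof = make_profile(amplitude=2.0, phase=2.5, cold=cold)
        t_release = 8.5
        t = np.linspace(t_release, t_release + 24, 2401)
        values = diurnal_mean(prof, t, "cold", t_release=t_release)
        assert float(t[np.argmax(values)]) == pytest.approx(t_release + 3.0, abs=0.02)


class TestPanelCalibration:
    def test_cca1_shoot_ambient_tenfold_drop(self, shoot_panel):
        cca1 = shoot_panel["CCA1"]
        assert diurnal_mean(cca1, 2.5) / diurnal_mean(cca1, 5.5) == pytest.approx(10.0, rel=1e-9)

    def test_cca1_shoot_cold_thirty_percent_drop(self, shoot_panel):
        cca1 = shoot_panel["CCA1"]
        ratio = diurnal_mean(cca1, 5.5, "cold") / diurnal_mean(cca1, 2.5, "cold")
        assert ratio == pytest.approx(0.7, rel=1e-9)

    def test_gi_shoot_eightfold_induction(self, shoot_panel):
        gi = shoot_panel["GI"]
        assert diurnal_mean(gi, 5.5) / diurnal_mean(gi, 2.5) == pytest.approx(8.0, rel=1e-9)

    def test_cbf3_strong_cold_induction(self, shoot_panel, root_panel):
        for panel, fold in ((shoot_panel, 400.0), (root_panel, 155.0)):
            cbf3 = panel["CBF3"]
            ratio = diurnal_mean(cbf3, 5.5, "cold") / diurnal_mean(cbf3, 5.5)
            assert ratio == pytest.approx(fold, rel=0.01)

    def test_reference_gene_constant(self, shoot_panel):
        ef1a = shoot_panel["EF1a"]
        t = np.linspace(0, 24, 49)
        np.testing.assert_allclose(diurnal_mean(ef1a, t, "cold"),
                                   diurnal_mean(ef1a, 0.0), rtol=1e-12)


class TestValidation:
    def test_dampening_bounds(self):
        with pytest.raises(ValueError):
            ColdResponseSpec(category="static", dampening=1.5)

    def test_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            ColdResponseSpec(category="induced", fold=0.5)

    def test_unknown_category(self):
        with pytest.raises(ValueError):
            ColdResponseSpec(category="mystery")

    def test_calibrate_dampening(self):
        assert calibrate_dampening(0.1, 0.7) == pytest.approx(1.0 / 3.0)
        assert calibrate_dampening(0.1, 1.0) == 0.0
        with pytest.raises(ValueError):
            calibrate_dampening(1.0, 0.7)
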