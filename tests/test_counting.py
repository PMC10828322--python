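"""Counting statistics: sensitivity, MDA, dead time, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fiberaif import (
    CountRateSeries,
    MDAInputs,
    calibrate,
    correct_dead_time,
    efficiency_curve,
    fit_dead_time,
    get_isotope,
    mda,
    sensitivity,
    subtended_source_volume_ml,
)
from fiberaif.counting import observed_rate
from fiberaif.geometry import build_validation_tube_scene
from fiberaif.synthetic import SyntheticSeriesSpec, generate_decaying_series, spectrum_fixture


class TestSensitivity:
    def test_unit_check(self):
        r = sensitivity(1.0, 0.001, 1.0, includes_branching=True)
        assert r.s == pytest.approx(1.0)

    def test_tube_consistency(self, tube_f18):
        """s from the tube simulation is exactly eff x 70 uL x f x 1000."""
        scene = build_validation_tube_scene("F18")
        v = subtended_source_volume_ml(scene)
        f = get_isotope("F18").branching_fraction
        eff = tube_f18.efficiency(100.0)
        r = sensitivity(eff, v, f, includes_branching=True, threshold_kev=100.0)
        assert r.s == pytest.approx(eff * v * 1000.0 * f, rel=1e-12)

    def test_branching_flag(self):
        with_f = sensitivity(0.1, 0.07, 0.9673, includes_branching=True).s
        without = sensitivity(0.1, 0.07, 0.9673, includes_branching=False).s
        assert with_f == pytest.approx(without * 0.9673)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            sensitivity(0.1, 0.0, 1.0)


class TestMda:
    def test_closed_form_zero_background(self):
        assert mda(MDAInputs(0.0, 1.0, 1.0, 1.0)) == pytest.approx(
            4.65 * math.sqrt(2.71))

    def test_closed_form_round_number(self):
        assert mda(MDAInputs(97.29, 1.0, 1.0, 1.0)) == pytest.approx(46.5)

    def test_zero_sensitivity_is_infinite(self):
        assert mda(MDAInputs(10.0, 0.9, 1.0, 0.0)) == math.inf

    @given(
        nb=st.floats(0.0, 1e6),
        f=st.floats(0.01, 1.0),
        t=st.floats(0.01, 100.0),
        s=st.floats(1e-6, 1e3),
        bump=st.floats(1e-3, 10.0),
    )
    def test_monotonicity(self, nb, f, t, s, bump):
        base = mda(MDAInputs(nb, f, t, s))
        assert mda(MDAInputs(nb + bump, f, t, s)) > base
        assert mda(MDAInputs(nb, min(f * (1 + bump), 1.0), t, s)) <= base
        assert mda(MDAInputs(nb, f, t * (1 + bump), s)) < base
        assert mda(MDAInputs(nb, f, t, s * (1 + bump))) < base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            MDAInputs(-1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            MDAInputs(0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            MDAInputs(0.0, 1.5, 1.0, 1.0)


class TestEfficiencyCurve:
    def test_canned_fixture_values(self):
        spec = spectrum_fixture("uniform_0_600")
        curve = dict(efficiency_curve(spec, [0.0, 300.0, 600.0], "source_artery"))
        assert curve[0.0] == pytest.approx(1.0)
        assert curve[300.0] == pytest.approx(0.5)
        assert curve[600.0] == 0.0

    def test_non_increasing_on_simulation(self, mouse_f18):
        curve = efficiency_curve(mouse_f18.spectrum(),
                                 list(np.arange(0.0, 650.0, 50.0)),
                                 "source_artery")
        eff = [e for _, e in curve]
        assert np.all(np.diff(eff) <= 1e-12)

    def test_unsorted_thresholds_rejected(self, mouse_f18):
        with pytest.raises(ValueError):
            efficiency_curve(mouse_f18.spectrum(), [100.0, 0.0], "source_artery")


class TestDeadTime:
    def test_zero_tau_noiseless(self):
        series = generate_decaying_series(SyntheticSeriesSpec(
            n0_cps=1e4, lambda_=1.7e-4, tau_s=0.0, bin_duration_s=10.0,
            total_duration_s=8000.0, noise="none"))
        fit = fit_dead_time(series, 1.7e-4)
        assert fit.tau_us == pytest.approx(0.0, abs=1e-9)
        assert fit.n0_cps == pytest.approx(1e4, rel=1e-9)

    @pytest.mark.parametrize("n0,tau", [(5e4, 2e-6), (2e5, 5e-7), (1e3, 1e-5)])
    def test_noiseless_exact_recovery(self, n0, tau):
        lam = get_isotope("Ga68").decay_constant
        series = generate_decaying_series(SyntheticSeriesSpec(
            n0_cps=n0, lambda_=lam, tau_s=tau, bin_duration_s=10.0,
            total_duration_s=3 * 4062.6, noise="none"))
        fit = fit_dead_time(series, lam)
        assert fit.tau_us == pytest.approx(tau * 1e6, rel=1e-6)
        assert fit.n0_cps == pytest.approx(n0, rel=1e-6)
        assert fit.residual_rms < 1e-6 * n0

    def test_poisson_recovery_within_5_percent(self):
        """Parameter recovery over 100 replicate noisy acquisitions."""
        lam = get_isotope("Ga68").decay_constant
        tau = 2e-6
        errs = []
        for seed in range(100):
            series = generate_decaying_series(SyntheticSeriesSpec(
                n0_cps=5e4, lambda_=lam, tau_s=tau, bin_duration_s=1.0,
                total_duration_s=3 * 4062.6, noise="poisson", seed=seed))
            fit = fit_dead_time(series, lam)
            errs.append(fit.tau_us / (tau * 1e6) - 1.0)
        errs = np.array(errs)
        assert np.all(np.abs(errs) < 0.05)
        assert abs(errs.mean()) < 0.01  # no systematic bias

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            fit_dead_time(CountRateSeries([0.0, 1.0], 1.0, [10.0, 9.0]), 1e-4)


class TestDeadTimeCorrection:
    def test_zero_tau_identity(self):
        assert correct_dead_time(1234.5, 0.0) == 1234.5

    def test_reference_value(self):
        # closed form with the bench-scale dead time 2.3664 us
        assert correct_dead_time(1000.0, 2.3664e-6) == pytest.approx(1002.372, abs=1e-2)

    @given(n=st.floats(1.0, 1e5), tau=st.floats(0.0, 5e-6))
    def test_roundtrip_with_forward_map(self, n, tau):
        assert correct_dead_time(observed_rate(n, tau), tau) == pytest.approx(
            n, rel=1e-12)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            correct_dead_time(1e6, 1e-5)


class TestCalibration:
    def test_reference_point_maps_to_itself(self):
        assert calibrate(500.0, 123.0, 500.0) == pytest.approx(123.0)

    def test_zero_rate(self):
        assert calibrate(0.0, 123.0, 500.0) == 0.0

    @given(rate=st.floats(0.0, 1e6))
    def test_linearity(self, rate):
        one = calibrate(rate, 10.0, 100.0)
        two = calibrate(2.0 * rate, 10.0, 100.0)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            calibrate(10.0, 1.0, 0.0)
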