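"""Reduced-order ejection model: waveforms, integration, calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mplv
from mplv.constants import MMHG_TO_PA
from mplv.ejection import (
    _batch_cardiac_output,
    ejection_time_model,
)
from mplv.errors import CalibrationError, DomainError, ValidationError


class TestWaveforms:
    def test_subject_rest_record_shape(self):
        """Ventricular peak at mid-ejection, aortic minimum at the ends."""
        bc = mplv.build_waveforms(152, 68, 0.30, 98)
        assert bc.ventricular_pressure(0.15) == pytest.approx(152, rel=1e-12)
        assert bc.aortic_pressure(0.0) == pytest.approx(68, rel=1e-12)
        assert bc.aortic_pressure(0.30) == pytest.approx(68, abs=1e-9)
        t = np.linspace(0, 0.30, 201)  # includes mid-ejection
        p_lv = np.array([bc.ventricular_pressure(ti) for ti in t])
        assert p_lv.max() == pytest.approx(152, rel=1e-6)
        assert p_lv.min() == pytest.approx(68, abs=1e-9)

    def test_gradient_vanishes_at_onset(self):
        bc = mplv.build_waveforms(180, 70, 0.25, 140)
        assert bc.ventricular_pressure(0.0) == bc.aortic_pressure(0.0)

    def test_gradient_nonnegative_throughout(self):
        bc = mplv.build_waveforms(170, 65, 0.22, 130)
        t = np.linspace(0, 0.22, 500)
        dp = [bc.ventricular_pressure(ti) - bc.aortic_pressure(ti) for ti in t]
        assert min(dp) >= -1e-12

    def test_degenerate_pressures_rejected(self):
        with pytest.raises(DomainError):
            mplv.build_waveforms(100, 100, 0.3, 60)


class TestEjectionTimeModel:
    def test_linear_region(self):
        assert ejection_time_model(98.0) == pytest.approx(0.413 - 0.0017 * 98)

    def test_clamped_at_high_heart_rate(self):
        assert ejection_time_model(169.0) == 0.15


class TestSimulate:
    def test_null_forcing_gives_zero_flow(self):
        bc = mplv.EjectionBC(
            ejection_time=0.3,
            heart_rate=60,
            ventricular_pressure=lambda t: 100.0,
            aortic_pressure=lambda t: 100.0,
        )
        res = mplv.simulate_ejection(bc, mplv.SurrogateParams(), dt=1e-3)
        assert np.all(res.flow == 0.0)
        assert res.cardiac_output == 0.0

    def test_orifice_limit_closed_form(self):
        """Pinned-open valve under constant load reaches Q = A sqrt(2 dP/rho)."""
        params = mplv.SurrogateParams(
            k_open=1e-3,
            effective_length=0.01,
            area_max=2e-4,
            area_min_fraction=0.05,
            blood_density=1056.0,
        )
        bc = mplv.EjectionBC(
            ejection_time=0.3,
            heart_rate=60,
            ventricular_pressure=lambda t: 110.0,
            aortic_pressure=lambda t: 100.0,
        )
        res = mplv.simulate_ejection(bc, params, dt=1e-4, initial_opening=1.0)
        q_expected = 2e-4 * math.sqrt(2 * 10 * MMHG_TO_PA / 1056.0)
        assert res.flow[-1] == pytest.approx(q_expected, rel=5e-3)
        assert res.flow[-1] == pytest.approx(3.178e-4, rel=5e-3)

    def test_coarse_dt_rejected(self):
        bc = mplv.build_waveforms(152, 68, 0.30, 98)
        with pytest.raises(DomainError, match="too coarse"):
            mplv.simulate_ejection(bc, mplv.SurrogateParams(), dt=0.30 / 100)

    def test_grid_convergence(self):
        """Halving dt changes cardiac output by well under 0.1%."""
        params, et_coeffs = mplv.packaged_calibration()
        et = ejection_time_model(98.0, *et_coeffs)
        bc = mplv.build_waveforms(152, 68, et, 98)
        co1 = mplv.simulate_ejection(bc, params, dt=et / 400).cardiac_output
        co2 = mplv.simulate_ejection(bc, params, dt=et / 800).cardiac_output
        assert abs(co2 - co1) / co2 < 1e-3

    def test_monotone_in_systolic_pressure(self):
        """All else fixed, higher VSP drives strictly more cardiac output."""
        params, _ = mplv.packaged_calibration()
        cos = []
        for vsp in (140.0, 155.0, 170.0, 185.0):
            bc = mplv.build_waveforms(vsp, 68, 0.25, 100)
            cos.append(mplv.simulate_ejection(bc, params, dt=0.25 / 400).cardiac_output)
        assert np.all(np.diff(cos) > 0)

    def test_monotone_in_ejection_time(self):
        """Longer ejection at fixed heart rate ejects strictly more volume."""
        params, _ = mplv.packaged_calibration()
        svs = []
        for et in (0.18, 0.22, 0.26, 0.30):
            bc = mplv.build_waveforms(160, 65, et, 100)
            svs.append(mplv.simulate_ejection(bc, params, dt=et / 400).stroke_volume)
        assert np.all(np.diff(svs) > 0)

    @given(
        vsp=st.floats(120, 220),
        adp=st.floats(50, 90),
        et=st.floats(0.15, 0.40),
        k_open=st.floats(1e-5, 1e-2),
    )
    @settings(max_examples=30, deadline=None)
    def test_opening_state_stays_in_unit_interval(self, vsp, adp, et, k_open):
        params = replace(mplv.SurrogateParams(), k_open=k_open)
        bc = mplv.build_waveforms(vsp, adp, et, 100)
        res = mplv.simulate_ejection(bc, params, dt=et / 400)
        assert np.all(res.opening >= 0.0)
        assert np.all(res.opening <= 1.0)

    def test_consistency_with_doppler_route(self):
        """CO from the flow integral equals the VTI x area route to < 0.5%."""
        params, et_coeffs = mplv.packaged_calibration()
        et = ejection_time_model(114.0, *et_coeffs)
        bc = mplv.build_waveforms(165, 63, et, 114)
        res = mplv.simulate_ejection(bc, params, dt=et / 500)
        velocity = np.maximum(res.flow, 0.0) / params.area_max
        trace = mplv.VelocityTrace(res.times, velocity)
        vti = mplv.velocity_time_integral(trace)
        sv_doppler = mplv.stroke_volume(vti, params.area_max)
        co_doppler = mplv.cardiac_output(sv_doppler, 114)
        assert co_doppler == pytest.approx(res.cardiac_output, rel=5e-3)

    def test_batch_matches_scalar_path(self):
        params, _ = mplv.packaged_calibration()
        pulse, et, hr = np.array([84.0]), np.array([0.2]), np.array([98.0])
        batch_co = _batch_cardiac_output(pulse, et, hr, params, 0.35, 400)[0]
        bc = mplv.build_waveforms(68 + 84, 68, 0.2, 98)
        scalar_co = mplv.simulate_ejection(bc, params, dt=0.2 / 400).cardiac_output
        assert batch_co == pytest.approx(scalar_co, rel=1e-9)


class TestCalibration:
    def test_fidelity_against_subject_numerical_co(self, calibration, subject_series):
        """Calibrated model reproduces the subject's numerical CO per record."""
        assert calibration.max_abs_relative_residual <= 0.05
        assert len(calibration.residuals) == len(subject_series)

    def test_calibration_deterministic_for_fixed_seed(self, calibration):
        assert calibration.seed == 1729
        assert calibration.n_starts == 8

    def test_parameter_recovery_noise_free(self):
        """Calibration recovers known parameters from surrogate-made data."""
        series, _ = mplv.generate_series(
            mplv.SynthConfig(seed=7, noise_sd_co=0.0, noise_sd_pressure=0.0)
        )
        truth = mplv.SurrogateParams(
            k_open=8e-4, effective_length=0.02, area_min_fraction=0.02
        )
        co = mplv.predict_numerical_co(series, truth)
        series = series.with_numerical_co(co)
        result = mplv.calibrate(
            series, fit_ejection_time=False, n_starts=4, n_steps=300
        )
        for name in ("k_open", "effective_length", "area_min_fraction"):
            fitted = getattr(result.params, name)
            expected = getattr(truth, name)
            assert fitted == pytest.approx(expected, rel=0.02)

    def test_series_without_numerical_co_rejected(self):
        series, _ = mplv.generate_series(mplv.SynthConfig(seed=3))
        bare = mplv.SubjectSeries(
            tuple(replace(r, numerical_co=None) for r in series.records)
        )
        with pytest.raises(CalibrationError, match=">= 4 records"):
            mplv.calibrate(bare)

    def test_save_calibration_json(self, calibration, tmp_path):
        import json

        path = tmp_path / "cal.json"
        mplv.ejection.save_calibration(calibration, path)
        raw = json.loads(path.read_text())
        assert raw["seed"] == 1729
        assert raw["k_open_per_pa_s"] == pytest.approx(calibration.params.k_open)
        assert len(raw["relative_residuals"]) == 9
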