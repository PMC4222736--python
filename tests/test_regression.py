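"""Regression chain: quadratic fits, inter-method transforms, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mplv
from mplv.errors import DomainError
from mplv.regression import (
    DEFAULT_MAPS,
    FICK_MAP,
    THERMODILUTION_MAP,
    ExtrapolationWarning,
)


class TestFitQuadratic:
    def test_exact_recovery(self):
        x = np.linspace(-3, 6, 10)
        y = 2 * x**2 - 3 * x + 1
        fit = mplv.fit_quadratic(x, y)
        assert fit.coefficients == pytest.approx((2, -3, 1), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError, match=">= 4"):
            mplv.fit_quadratic([1, 2, 3], [1, 2, 3])

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(DomainError, match="rank deficient"):
            mplv.fit_quadratic([2, 2, 2, 2], [1, 2, 3, 4])

    def test_r_squared_matches_statsmodels(self, subject_series):
        """Independent check of R^2 against an OLS fit."""
        import statsmodels.api as sm

        co = np.array(subject_series.column("numerical_co"), float)
        vsp = np.array(subject_series.column("ventricular_systolic"), float)
        fit = mplv.fit_quadratic(co, vsp)
        ols = sm.OLS(vsp, np.column_stack([co**2, co, np.ones_like(co)])).fit()
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)
        assert fit.coefficients == pytest.approx(tuple(ols.params), rel=1e-6)

    def test_extrapolation_warns(self, subject_fits):
        with pytest.warns(ExtrapolationWarning):
            subject_fits["vsp"](30000.0)


class TestSubjectFits:
    """Re-estimated fits validated against the published goodness-of-fit."""

    def test_vsp_fit_r_squared(self, subject_fits):
        assert round(subject_fits["vsp"].r_squared, 4) == 0.9977

    def test_adp_fit_r_squared(self, subject_fits):
        assert round(subject_fits["adp"].r_squared, 4) == 0.9674

    def test_cod_fit_r_squared(self, subject_fits):
        assert round(subject_fits["cod"].r_squared, 4) == 0.9934

    def test_vsp_fit_predicts_measured_pressures(self, subject_series, subject_fits):
        """Fitted VSP(CO) tracks the measured column within 5 mmHg."""
        co = np.array(subject_series.column("numerical_co"), float)
        vsp = np.array(subject_series.column("ventricular_systolic"), float)
        assert np.all(np.abs(subject_fits["vsp"](co) - vsp) < 5.0)

    def test_cod_fit_predicts_doppler_co(self, subject_series, subject_fits):
        """Fitted COD(HR) tracks the Doppler column within 500 ml/min."""
        hr = np.array(subject_series.heart_rates)
        cod = np.array(subject_series.column("doppler_co"), float)
        assert np.all(np.abs(subject_fits["cod"](hr) - cod) < 500.0)

    def test_doppler_numerical_correlation(self, subject_series):
        assert mplv.doppler_numerical_correlation(subject_series) >= 0.998


class TestChristieTransforms:
    def test_thermodilution_at_rest(self):
        assert mplv.christie_transform(11356, THERMODILUTION_MAP) == pytest.approx(
            13617.96, abs=0.01
        )

    def test_fick_at_peak_exercise(self):
        assert mplv.christie_transform(18849, FICK_MAP) == pytest.approx(
            21579.47, abs=0.01
        )

    def test_identity_map(self):
        identity = mplv.LinearMap(1.0, 0.0, "doppler")
        assert mplv.christie_transform(5000.0, identity) == 5000.0

    def test_out_of_validity_range_rejected(self):
        with pytest.raises(DomainError):
            mplv.christie_transform(1000.0, THERMODILUTION_MAP)  # negative output


class TestComposition:
    def test_fick_co_vs_hr_coefficients(self, subject_fits):
        """Composed Fick CO(HR) curve matches the published coefficients."""
        fick = mplv.compose_co_vs_hr(subject_fits["cod"], FICK_MAP)
        assert fick.c2 == pytest.approx(-0.776, rel=0.01)
        assert fick.c1 == pytest.approx(309.0, rel=0.03)

    def test_composed_fit_keeps_r_squared(self, subject_fits):
        composed = mplv.compose_co_vs_hr(subject_fits["cod"], THERMODILUTION_MAP)
        assert round(composed.r_squared, 4) == 0.9934
        assert composed.r_squared == subject_fits["cod"].r_squared

    def test_identity_map_leaves_fit_unchanged(self, subject_fits):
        identity = mplv.LinearMap(1.0, 0.0, "doppler")
        composed = mplv.compose_co_vs_hr(subject_fits["cod"], identity)
        assert composed.coefficients == subject_fits["cod"].coefficients

    @given(
        slope=st.floats(0.1, 3.0),
        intercept=st.floats(-3000, 3000),
        hr=st.floats(98, 169),
    )
    @settings(max_examples=100, deadline=None)
    def test_composition_equals_pointwise_transform(
        self, subject_fits, slope, intercept, hr
    ):
        """compose(f, m)(hr) = m(f(hr)) at machine precision."""
        lin = mplv.LinearMap(slope, intercept, "test")
        composed = mplv.compose_co_vs_hr(subject_fits["cod"], lin)
        direct = slope * subject_fits["cod"](hr) + intercept
        assert composed(hr) == pytest.approx(direct, rel=1e-12, abs=1e-9)

    @given(
        slope=st.floats(0.05, 5.0),
        intercept=st.floats(-5000, 5000),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_r_squared_invariant_under_linear_maps(self, slope, intercept, seed):
        """R^2 of y -> a y + b refit equals the original at machine precision."""
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 10, 12))
        y = rng.normal(2 + x - 0.3 * x**2, 0.5)
        base = mplv.fit_quadratic(x, y)
        mapped = mplv.fit_quadratic(x, slope * y + intercept)
        assert mapped.r_squared == pytest.approx(base.r_squared, abs=1e-9)


class TestPressureCurves:
    def test_thermodilution_vsp_at_rest(self, subject_series, subject_fits):
        """VSP at the thermodilution-transformed rest CO is about 162 mmHg."""
        co_t = mplv.christie_transform(
            subject_series[0].doppler_co, THERMODILUTION_MAP
        )
        assert subject_fits["vsp"](co_t) == pytest.approx(162.0, abs=1.0)

    def test_constant_fit_gives_constant_curve(self, subject_fits):
        flat = mplv.QuadraticFit(0.0, 0.0, 120.0, 1.0)
        curve = mplv.predict_pressure_curve(
            flat, subject_fits["cod"], np.linspace(98, 169, 10)
        )
        np.testing.assert_allclose(curve, 120.0)

    def test_doppler_chain_tracks_measured_vsp(self, subject_series, subject_fits):
        """VSP fit at the measured Doppler CO stays within 5 mmHg of measured VSP."""
        cod = np.array(subject_series.column("doppler_co"), float)
        vsp = np.array(subject_series.column("ventricular_systolic"), float)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            curve = subject_fits["vsp"](cod)
        assert np.all(np.abs(curve - vsp) < 5.0)

    def test_empty_grid_rejected(self, subject_fits):
        with pytest.raises(DomainError):
            mplv.predict_pressure_curve(subject_fits["vsp"], subject_fits["cod"], [])


class TestExerciseSummary:
    def test_doppler_vsp_changes(self, subject_series, subject_fits):
        entry = mplv.exercise_summary(subject_series, subject_fits).get(
            "doppler", "vsp"
        )
        assert entry.absolute_change == 34.0
        assert round(entry.percent_change) == 22
        assert round(entry.endpoint_gradient, 2) == 0.48

    def test_thermodilution_adp_changes(self, subject_series, subject_fits):
        entry = mplv.exercise_summary(subject_series, subject_fits).get(
            "thermodilution", "adp"
        )
        assert round(entry.percent_change, 1) == 31.3
        assert entry.absolute_change == pytest.approx(19.9, rel=0.01)

    def test_gradient_is_endpoint_difference_quotient(
        self, subject_series, subject_fits
    ):
        summary = mplv.exercise_summary(subject_series, subject_fits)
        for entry in summary.entries:
            assert entry.endpoint_gradient == pytest.approx(
                entry.absolute_change / (summary.hr_high - summary.hr_low),
                rel=1e-12,
            )

    def test_single_heart_rate_rejected(self, subject_series, subject_fits):
        short = mplv.SubjectSeries((subject_series[0],))
        with pytest.raises(DomainError):
            mplv.exercise_summary(short, subject_fits)

    def test_format_summary_mentions_rounding(self, subject_series, subject_fits):
        text = mplv.format_summary(
            mplv.exercise_summary(subject_series, subject_fits)
        )
        assert "rounding" in text
        assert "thermodilution" in text
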