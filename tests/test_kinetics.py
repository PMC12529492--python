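"""Tracer-kinetic estimators against closed-form and forward-model oracles."""

import numpy as np
import pytest

from metaclamp.errors import ConfigurationError, DataError, EstimationError
from metaclamp.kinetics import (
    endogenous_glucose_production,
    m_value,
    patlak_ki,
    patlak_ki_true,
    plasma_auc_with_tail,
    rate_of_disappearance,
    solve_irreversible_2tc,
    tissue_glucose_uptake,
)
from metaclamp.cohort import DEFAULT_SAMPLING_TIMES, feng_shape_auc_inf
from metaclamp.records import ClampRecord, TimeActivityCurve

from conftest import make_feng_plasma

STD_PARAMS = (0.1, 0.15, 0.05)  # K1, k2, k3 with Ki = 0.025


def _sample(plasma: TimeActivityCurve, times) -> TimeActivityCurve:
    return TimeActivityCurve(
        np.asarray(times),
        np.interp(times, plasma.times, plasma.activities),
        label="plasma",
    )


class TestPatlak:
    def test_pure_distribution_gives_zero_slope(self, feng_plasma):
        """Ct proportional to Cp means no trapping: Ki = 0, intercept = c."""
        times = np.asarray(DEFAULT_SAMPLING_TIMES)
        plasma = _sample(feng_plasma, times)
        tissue = TimeActivityCurve(times, 0.37 * plasma.activities, label="t")
        fit = patlak_ki(tissue, plasma, t_star=20.0)
        assert fit.ki == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.37, abs=1e-12)

    def test_exact_line_recovered(self):
        """Synthetic data lying exactly on y = 0.01 x + 0.5."""
        times = np.arange(1.0, 61.0, 1.0)
        plasma = TimeActivityCurve(times, np.full_like(times, 10.0))
        # constant Cp: running integral is 10 (t - 1) plus the 0..1 rise
        # triangle (5), i.e. 10 t - 5; build Ct so y = 0.01 x + 0.5 exactly
        x = (10.0 * times - 5.0) / 10.0
        tissue = TimeActivityCurve(times, 10.0 * (0.01 * x + 0.5))
        fit = patlak_ki(tissue, plasma, t_star=5.0)
        assert fit.ki == pytest.approx(0.01, rel=1e-12)
        assert fit.intercept == pytest.approx(0.5, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_recovers_closed_form_ki(self, feng_plasma):
        """Noiseless 2TC curves give Ki within 2% of K1*k3/(k2+k3)."""
        times = np.asarray(DEFAULT_SAMPLING_TIMES)
        tissue = solve_irreversible_2tc(STD_PARAMS, feng_plasma, times)
        fit = patlak_ki(tissue, _sample(feng_plasma, times), t_star=20.0)
        assert fit.ki == pytest.approx(patlak_ki_true(STD_PARAMS), rel=0.02)
        assert fit.r_squared > 0.999

    def test_bias_shrinks_with_later_t_star(self, feng_plasma):
        """The equilibration transient fades, so |bias| falls with t*."""
        times = np.asarray(DEFAULT_SAMPLING_TIMES)
        tissue = solve_irreversible_2tc(STD_PARAMS, feng_plasma, times)
        plasma = _sample(feng_plasma, times)
        truth = patlak_ki_true(STD_PARAMS)
        errors = [abs(patlak_ki(tissue, plasma, t_star=t).ki - truth)
                  for t in (10.0, 20.0, 30.0)]
        assert errors[0] >= errors[1] >= errors[2]

    def test_insufficient_late_points_is_estimation_error(self, feng_plasma):
        times = np.asarray(DEFAULT_SAMPLING_TIMES)
        tissue = solve_irreversible_2tc(STD_PARAMS, feng_plasma, times)
        with pytest.raises(EstimationError, match="85"):
            patlak_ki(tissue, _sample(feng_plasma, times), t_star=85.0)

    def test_nonpositive_plasma_is_data_error(self):
        times = np.arange(1.0, 40.0)
        plasma = TimeActivityCurve(times, np.zeros_like(times) )
        tissue = TimeActivityCurve(times, np.ones_like(times))
        with pytest.raises(DataError):
            patlak_ki(tissue, plasma, t_star=10.0)


class TestForwardModel:
    def test_zero_input_gives_zero_tissue(self):
        times = np.arange(1.0, 50.0)
        plasma = TimeActivityCurve(times, np.zeros_like(times))
        ct = solve_irreversible_2tc(STD_PARAMS, plasma, [10.0, 20.0, 40.0])
        assert np.allclose(ct.activities, 0.0)

    def test_no_trapping_equilibrates_at_k1_over_k2(self):
        """k3 = 0 with constant input: Ct -> (K1/k2) Cp."""
        times = np.arange(0.5, 400.0, 0.5)
        plasma = TimeActivityCurve(times, np.full_like(times, 20.0))
        ct = solve_irreversible_2tc((0.1, 0.15, 0.0), plasma, [300.0, 350.0, 399.0])
        assert ct.activities[-1] == pytest.approx(0.1 / 0.15 * 20.0, rel=1e-3)

    def test_late_slope_is_ki_times_input(self):
        """Step input: late dCt/dt -> K1 k3/(k2+k3) * Cp."""
        times = np.arange(0.5, 200.0, 0.5)
        plasma = TimeActivityCurve(times, np.full_like(times, 20.0))
        ct = solve_irreversible_2tc(STD_PARAMS, plasma, [150.0, 160.0, 199.0])
        slope = (ct.activities[-1] - ct.activities[0]) / (199.0 - 150.0)
        assert slope == pytest.approx(patlak_ki_true(STD_PARAMS) * 20.0, rel=1e-3)

    def test_eval_beyond_support_is_error(self):
        times = np.arange(1.0, 30.0)
        plasma = TimeActivityCurve(times, np.ones_like(times))
        with pytest.raises(DataError, match="support"):
            solve_irreversible_2tc(STD_PARAMS, plasma, [40.0, 50.0, 60.0])


class TestGlucoseUptake:
    def test_stated_formula_arithmetic(self):
        gu = tissue_glucose_uptake(0.012, 5.0, "muscle", densities={"muscle": 1.0})
        assert gu == pytest.approx(0.012 * 5000.0 / 1.2)

    def test_zero_ki_gives_zero(self):
        assert tissue_glucose_uptake(0.0, 7.3, "liver") == 0.0

    def test_lumped_constant_ratio(self):
        dens = {"muscle": 1.0, "liver": 1.0}
        gu_liver = tissue_glucose_uptake(0.01, 5.0, "liver", densities=dens)
        gu_muscle = tissue_glucose_uptake(0.01, 5.0, "muscle", densities=dens)
        assert gu_liver / gu_muscle == pytest.approx(1.2)

    def test_unknown_region_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="unknown region"):
            tissue_glucose_uptake(0.01, 5.0, "brain")


def _clamp_with_gir(gir_times, gir_values, glucose_times, glucose_values):
    return ClampRecord(
        subject_id="S1",
        gir_times=np.asarray(gir_times, dtype=float),
        gir_values=np.asarray(gir_values, dtype=float),
        glucose_times=np.asarray(glucose_times, dtype=float),
        glucose_values=np.asarray(glucose_values, dtype=float),
        insulin_times=np.asarray(glucose_times, dtype=float),
        insulin_values=np.full(len(glucose_times), 400.0),
        weight=70.0,
    )


class TestMValue:
    def test_constant_trace(self):
        t = np.arange(0.0, 181.0, 5.0)
        clamp = _clamp_with_gir(t, np.full_like(t, 30.0),
                                [0, 30, 60, 90, 120, 150, 180],
                                [5.6, 5.2, 5.0, 5.0, 5.0, 5.0, 5.0])
        res = m_value(clamp)
        assert res.m_value == pytest.approx(30.0)
        assert res.steady_state_time == 30.0

    def test_mean_of_three_interval_means(self):
        """Interval means 28, 30, 32 average to 30."""
        t = np.arange(30.0, 95.0, 5.0)
        vals = np.where(t < 50, 28.0, np.where(t < 70, 30.0, 32.0))
        clamp = _clamp_with_gir(t, vals, [0, 30], [5.6, 5.0])
        res = m_value(clamp)
        assert res.interval_means == pytest.approx((28.0, 30.0, 32.0))
        assert res.m_value == pytest.approx(30.0)

    def test_never_reaching_target_is_estimation_error(self):
        t = np.arange(0.0, 181.0, 5.0)
        clamp = _clamp_with_gir(t, np.zeros_like(t), [0, 60, 120, 180],
                                [6.5, 6.4, 6.3, 6.2])
        with pytest.raises(EstimationError, match="never reached"):
            m_value(clamp)

    def test_short_trace_is_estimation_error(self):
        t = np.arange(0.0, 61.0, 5.0)
        clamp = _clamp_with_gir(t, np.full_like(t, 30.0), [0, 30], [5.6, 5.0])
        with pytest.raises(EstimationError, match="60"):
            m_value(clamp)


class TestRdAndEgp:
    def test_stated_formula_arithmetic(self):
        """(100-10)/30-equivalent AUC times 5 umol/mL over 70 kg."""
        times = np.array([0.0, 150.0, 300.0])
        plasma = TimeActivityCurve(times, np.full(3, 100.0))  # AUC 30,000 kBq*min/mL
        rd = rate_of_disappearance(100.0, 10.0, plasma, 5.0, 70.0)
        assert rd == pytest.approx((90.0 * 1000.0 / 30000.0) * 5.0 / 70.0)

    def test_linearity_in_urine_correction(self, feng_plasma):
        plasma = _sample(feng_plasma, DEFAULT_SAMPLING_TIMES)
        rd_no_urine = rate_of_disappearance(100.0, 0.0, plasma, 5.0, 70.0)
        rd_urine = rate_of_disappearance(100.0, 10.0, plasma, 5.0, 70.0)
        assert rd_urine / rd_no_urine == pytest.approx(0.9, rel=1e-12)

    def test_auc_tail_matches_closed_form(self, feng_plasma):
        """Trapezoid + mono-exponential tail vs analytic AUC, within 1%."""
        scale = 30.0
        plasma = _sample(feng_plasma, DEFAULT_SAMPLING_TIMES)
        truth = scale * feng_shape_auc_inf()
        assert plasma_auc_with_tail(plasma) == pytest.approx(truth, rel=0.01)

    @pytest.mark.parametrize("rd,gir,expected", [(10.0, 8.0, 2.0),
                                                 (8.0, 8.2, -0.2),
                                                 (8.0, 8.0, 0.0)])
    def test_egp_identity(self, rd, gir, expected):
        res = endogenous_glucose_production(rd, gir)
        assert res.egp == pytest.approx(expected)
        assert res.egp == res.rd - res.gir_steady  # exact, by construction

    def test_bad_inputs_raise(self, feng_plasma):
        plasma = _sample(feng_plasma, DEFAULT_SAMPLING_TIMES)
        with pytest.raises(DataError):
            rate_of_disappearance(10.0, 10.0, plasma, 5.0, 70.0)
        with pytest.raises(DataError):
            rate_of_disappearance(100.0, 1.0, plasma, -5.0, 70.0)
        with pytest.raises(DataError):
            rate_of_disappearance(100.0, 1.0, plasma, 5.0, 0.0)
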