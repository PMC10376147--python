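"""Gas balances, their inversion, cumulative OUR and the biomass soft sensor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainchar import (
    EstimatorParams,
    OffGasRecord,
    compute_cpr,
    compute_our,
    cumulative_our,
    estimate_biomass,
    fit_alpha_beta,
    invert_offgas,
    rmse,
    simulate,
    preset,
)
from strainchar.offgas import InfeasibleGasError, InvalidCompositionError, V_MOL
from strainchar.params import STRAIN_LIBRARY
from strainchar.platforms import Schedule


def record(**kw):
    base = dict(t=0.0, F_in=6.0, V=0.09, x_O2_in=0.2095, x_CO2_in=0.0004,
                x_O2_out=0.19, x_CO2_out=0.02)
    base.update(kw)
    return OffGasRecord(**base)


class TestBalances:
    def test_zero_when_outlet_equals_inlet(self):
        rec = record(x_O2_out=0.2095, x_CO2_out=0.0004)
        assert compute_our(rec) == pytest.approx(0.0, abs=1e-12)
        assert compute_cpr(rec) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_record_matches_hand_evaluation(self):
        # frozen from an independent arithmetic evaluation of the balances
        rec = record()
        assert compute_our(rec) == pytest.approx(57.96413502109703, rel=1e-12)
        assert compute_cpr(rec) == pytest.approx(58.34086799276673, rel=1e-12)

    def test_carbon_dioxide_free_simplification(self):
        rec = record(x_O2_in=0.21, x_CO2_in=0.0, x_O2_out=0.20, x_CO2_out=0.0)
        expected = 1000.0 * (6.0 / (0.09 * V_MOL)) * (0.21 - (0.79 / 0.80) * 0.20)
        assert compute_our(rec) == pytest.approx(expected, rel=1e-12)

    def test_inert_free_outlet_rejected(self):
        with pytest.raises(InvalidCompositionError):
            record(x_O2_out=0.5, x_CO2_out=0.5)

    def test_percent_constructor(self):
        rec = OffGasRecord.from_percent(0.0, 6.0, 0.09, 20.95, 0.04, 19.0, 2.0)
        assert rec.x_O2_in == pytest.approx(0.2095)
        assert compute_our(rec) == pytest.approx(57.96413502109703, rel=1e-12)


class TestInversion:
    def test_zero_rates_return_inlet(self):
        o2, co2 = invert_offgas(0.0, 0.0, 6.0, 0.09)
        assert o2 == pytest.approx(0.2095, rel=1e-12)
        assert co2 == pytest.approx(0.0004, rel=1e-12)

    def test_round_trip_many_random_records(self, rng):
        worst = 0.0
        for _ in range(1000):
            f_in = rng.uniform(0.5, 20.0)
            v = rng.uniform(0.01, 0.2)
            cap = 1000.0 * f_in / (v * V_MOL) * 0.15
            our = rng.uniform(0.0, cap)
            cpr = rng.uniform(0.0, cap)
            o2, co2 = invert_offgas(our, cpr, f_in, v)
            rec = OffGasRecord(0.0, f_in, v, 0.2095, 0.0004, o2, co2)
            err_o = abs(compute_our(rec) - our) / max(our, 1e-6)
            err_c = abs(compute_cpr(rec) - cpr) / max(cpr, 1e-6)
            worst = max(worst, err_o, err_c)
        assert worst < 1e-9

    @given(
        our=st.floats(0.0, 120.0),
        cpr=st.floats(0.0, 120.0),
        f_in=st.floats(2.0, 12.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_property(self, our, cpr, f_in):
        o2, co2 = invert_offgas(our, cpr, f_in, 0.09)
        rec = OffGasRecord(0.0, f_in, 0.09, 0.2095, 0.0004, o2, co2)
        assert compute_our(rec) == pytest.approx(our, rel=1e-9, abs=1e-9)
        assert compute_cpr(rec) == pytest.approx(cpr, rel=1e-9, abs=1e-9)

    def test_direction_at_peak_respiration(self):
        # 1.66 vvm aeration of a 0.09 L stirred tank at a 140 mmol/(L·h) peak
        o2, co2 = invert_offgas(140.0, 140.0, 1.66 * 0.09 * 60, 0.09)
        assert o2 < 0.2095
        assert co2 > 0.0004

    def test_infeasible_demand_raises(self):
        with pytest.raises(InfeasibleGasError):
            invert_offgas(1e5, 0.0, 1.0, 0.09)


class TestCumulativeOur:
    def test_rectangle(self):
        t = np.array([0.0, 1.0])
        c = cumulative_our(t, np.array([1.0, 1.0]))
        np.testing.assert_allclose(c, [0.0, 0.032], rtol=1e-12)

    def test_zero_series(self):
        c = cumulative_our(np.arange(5.0), np.zeros(5))
        np.testing.assert_allclose(c, 0.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            cumulative_our(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_linear_and_monotone(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        t[0] = 0.0
        a = rng.uniform(0, 5, 50)
        b = rng.uniform(0, 5, 50)
        np.testing.assert_allclose(
            cumulative_our(t, a + 2 * b),
            cumulative_our(t, a) + 2 * cumulative_our(t, b), rtol=1e-10)
        assert np.all(np.diff(cumulative_our(t, a)) >= 0)

    def test_matches_specific_rate_integral(self, wg20_str_traj):
        d = wg20_str_traj.data
        c = cumulative_our(d.time_h.to_numpy(), d.OUR_mmolLh.to_numpy())
        direct = np.trapezoid(d.qO.to_numpy() * d.X_gL.to_numpy(),
                              d.time_h.to_numpy())
        assert c[-1] == pytest.approx(direct, rel=5e-3)


class TestSoftSensor:
    def test_returns_x0_at_zero_cumulative_uptake(self):
        est = EstimatorParams(alpha=1.4, X0=0.3)
        np.testing.assert_allclose(estimate_biomass(np.zeros(7), est), 0.3)

    def test_tracks_noiseless_biomass_when_maintenance_off(self):
        p = STRAIN_LIBRARY["WG(10)"].replace(q_m=1e-9, mu_max=5.0)
        plat = preset("MBR", S0=10).replace(
            pulse=None, kla=Schedule.constant(3000.0), t_end=7.0)
        traj = simulate(p, None, plat)
        d = traj.data[traj.data.S_gL > 0.05]
        cour = cumulative_our(d.time_h.to_numpy(), d.OUR_mmolLh.to_numpy())
        xm = estimate_biomass(cour, EstimatorParams(alpha=p.Y_OX,
                                                    X0=float(d.X_gL.iloc[0])))
        rel = np.abs(xm - d.X_gL.to_numpy()) / d.X_gL.to_numpy()
        assert rel.max() < 0.02

    def test_alpha_beta_recovery_zero_noise(self):
        t = np.linspace(0, 8, 41)
        X = 8 / (1 + 39 * np.exp(-0.7 * t))  # decelerating growth
        from scipy.integrate import cumulative_trapezoid

        cour = 1.4 * (X - X[0]) + 0.05 * cumulative_trapezoid(X, t, initial=0.0)
        est, sds = fit_alpha_beta(t, cour, X)
        assert est.alpha == pytest.approx(1.4, rel=0.01)
        assert est.beta == pytest.approx(0.05, rel=0.01)
        assert sds["alpha_sd"] < 1e-6

    def test_positive_maintenance_detected_under_noise(self, rng):
        t = np.linspace(0, 8, 81)
        X = 6 / (1 + 29 * np.exp(-0.8 * t))
        from scipy.integrate import cumulative_trapezoid

        cour = 1.4 * (X - X[0]) + 0.08 * cumulative_trapezoid(X, t, initial=0.0)
        cour = cour + rng.normal(0, 0.002, len(t))
        est, _ = fit_alpha_beta(t, cour, X)
        assert est.beta > 0
        resid = cour - (est.alpha * (X - X[0])
                        + est.beta * cumulative_trapezoid(X, t, initial=0.0))
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(t))

    def test_exponential_growth_degenerate(self):
        t = np.linspace(0, 5, 26)
        X = 0.2 * np.exp(0.4 * t)
        with pytest.raises(np.linalg.LinAlgError):
            fit_alpha_beta(t, 1.4 * (X - X[0]), X)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_alpha_beta(np.array([0.0, 1.0]), np.zeros(2), np.ones(2))


class TestRmse:
    def test_identical_series(self):
        x = np.linspace(0, 4, 9)
        assert rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.linspace(0, 4, 9)
        assert rmse(x + 0.7, x) == pytest.approx(0.7, rel=1e-12)

    def test_interpolates_onto_observation_grid(self):
        t_est = np.linspace(0, 10, 101)
        t_obs = np.array([1.0, 4.0, 9.0])
        assert rmse(2 * t_est, 2 * t_obs + 0.5, t_est=t_est, t_obs=t_obs) == \
            pytest.approx(0.5, rel=1e-9)

    def test_length_mismatch_without_grids(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))
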