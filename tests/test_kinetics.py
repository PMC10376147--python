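"""Rate laws, state derivatives and the batch/pulse simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainchar import (
    AuxiliaryConstants,
    ReactorState,
    Schedule,
    StrainParameters,
    preset,
    simulate,
    specific_rates,
    state_derivatives,
)
from strainchar.kinetics import InvalidStateError, TRAJECTORY_COLUMNS
from strainchar.params import STRAIN_LIBRARY


class TestSpecificRates:
    def test_no_substrate_all_rates_zero(self, wg10, aux):
        r = specific_rates(ReactorState(X=1.3, S=0.0, A=0.0, DOT=90.0), wg10, aux)
        assert (r.q_S, r.q_Ap, r.q_Ac, r.q_O, r.mu) == (0, 0, 0, 0, 0)

    def test_glucose_uptake_saturates_at_q_S_max(self, wg10, aux):
        r = specific_rates(ReactorState(X=1.0, S=1e6, A=0.0, DOT=100.0), wg10, aux)
        assert r.q_S == pytest.approx(1.13, rel=1e-6)

    def test_half_saturation_at_K_S(self, wg10, aux):
        r = specific_rates(ReactorState(X=1.0, S=wg10.K_S, A=0.0, DOT=100.0), wg10, aux)
        assert r.q_S == pytest.approx(wg10.q_S_max / 2, rel=1e-12)

    def test_rate_chain_matches_hand_evaluation(self, wg10, aux):
        # frozen values from an independent arithmetic walk through the
        # glucose-partitioning chain at S=5 g/L, A=0, DOT=100 %
        r = specific_rates(ReactorState(X=1.0, S=5.0, A=0.0, DOT=100.0), wg10, aux)
        assert r.q_S == pytest.approx(1.1279696546216809, rel=1e-12)
        assert r.q_Ap == pytest.approx(0.09982032341784787, rel=1e-12)
        assert r.q_Ac == 0.0
        assert r.mu == pytest.approx(0.5164958385011926, rel=1e-12)
        assert r.q_O == pytest.approx(0.8211196033334426, rel=1e-12)

    def test_oxygen_cap_diverts_growth_to_acetate(self, aux):
        # force the respiratory cap: demand far above q_O_max
        p = STRAIN_LIBRARY["WGP(20)"]
        r = specific_rates(ReactorState(X=1.0, S=15.0, A=0.5, DOT=90.0), p, aux)
        assert r.q_O == pytest.approx(p.q_O_max)
        assert r.mu < 0.35  # capped well below the unconstrained chain
        assert r.q_Ap > p.q_Ap_max  # overflow boost

    def test_acetate_recycling_supports_growth_without_glucose(self, wg10, aux):
        r = specific_rates(ReactorState(X=1.0, S=0.0, A=0.5, DOT=80.0), wg10, aux)
        assert r.q_S == 0 and r.q_Ap == 0
        assert r.q_Ac > 0
        assert r.mu == pytest.approx(r.q_Ac * aux.Y_XA, rel=1e-12)

    def test_non_finite_state_rejected(self):
        with pytest.raises(InvalidStateError):
            ReactorState(X=np.nan, S=1.0, A=0.0, DOT=50.0)

    @given(
        S=st.floats(0.0, 30.0),
        A=st.floats(0.0, 3.0),
        DOT=st.floats(0.0, 100.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rates_bounded_and_nonnegative(self, wg10, aux, S, A, DOT):
        r = specific_rates(ReactorState(X=1.0, S=S, A=A, DOT=DOT), wg10, aux)
        assert 0 <= r.q_S <= wg10.q_S_max + 1e-12
        assert 0 <= r.q_O <= wg10.q_O_max + 1e-12
        assert r.mu >= 0 and r.q_Ac >= 0 and r.q_Ap >= 0


class TestStateDerivatives:
    def test_abiotic_reactor_only_reaerates(self, wg10, aux, mbr10):
        d = state_derivatives(1.0, ReactorState(X=0.0, S=5.0, A=0.2, DOT=40.0),
                              wg10, aux, mbr10)
        kla = mbr10.kla.value_at(1.0)
        np.testing.assert_allclose(d, [0, 0, 0, kla * 60.0], rtol=1e-12)

    def test_saturated_abiotic_state_is_steady(self, wg10, aux, mbr10):
        d = state_derivatives(0.5, ReactorState(X=0.0, S=0.0, A=0.0, DOT=100.0),
                              wg10, aux, mbr10)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_derivatives_match_hand_evaluation(self, wg10, aux, mbr10):
        # X=1, S=5, A=0, DOT=80, kLa=600 1/h (frozen independent arithmetic)
        d = state_derivatives(1.0, ReactorState(X=1.0, S=5.0, A=0.0, DOT=80.0),
                              wg10, aux, mbr10)
        np.testing.assert_allclose(
            d,
            [0.5164958385011926, -1.1279696546216809,
             0.09982032341784787, 623.7201732952399],
            rtol=1e-10,
        )

    def test_nonpositive_kla_rejected(self, wg10, aux, mbr10):
        with pytest.raises(ValueError):
            Schedule.constant(-5.0) and mbr10.replace(kla=Schedule.constant(-5.0))


class TestSimulate:
    def test_yield_balance_without_maintenance_or_acetate(self):
        p = StrainParameters(mu_max=5.0, K_S=0.009, q_S_max=1.13,
                             q_Ap_max=1e-12, q_Ac_max=1e-12, q_O_max=50.0,
                             q_m=1e-12, Y_XS_em=0.56, Y_OX=1.49)
        plat = preset("MBR", S0=10).replace(
            pulse=None, kla=Schedule.constant(20000.0), t_end=9.0)
        traj = simulate(p, None, plat)
        dX = traj.data.X_gL.iloc[-1] - traj.data.X_gL.iloc[0]
        dS = traj.data.S_gL.iloc[0] - traj.data.S_gL.iloc[-1]
        assert abs(dX - p.Y_XS_em * dS) < 1e-6 * dX

    @pytest.mark.parametrize("s0,expected_pulses", [(10.0, 1), (5.0, 2)])
    def test_depletion_triggered_pulse_counts(self, wg10, s0, expected_pulses):
        p = STRAIN_LIBRARY[f"WG({int(s0)})"]
        traj = simulate(p, None, preset("MBR", S0=s0))
        assert len(traj.pulse_times) == expected_pulses
        assert int(traj.data.event_flag.sum()) == expected_pulses

    def test_no_pulse_when_glucose_never_depletes(self, wg10):
        traj = simulate(wg10, None, preset("MBR", S0=10).replace(t_end=1.0))
        assert traj.pulse_times == []

    def test_glucose_monotone_between_pulses(self, wg10):
        traj = simulate(wg10, None, preset("MBR", S0=10))
        s = traj.data.S_gL.to_numpy()
        t = traj.data.time_h.to_numpy()
        ev = traj.pulse_times[0]
        for lo, hi in [(0.0, ev - 1e-9), (ev + 1e-9, t[-1])]:
            seg = s[(t >= lo) & (t <= hi)]
            assert np.all(np.diff(seg) <= 1e-9)

    def test_states_never_negative(self, wg20_str_traj):
        assert (wg20_str_traj.data[["X_gL", "S_gL", "A_gL", "DOT_pct"]].to_numpy()
                >= -1e-9).all()

    def test_oxygen_uptake_capped_and_otr_limited(self, aux):
        p = STRAIN_LIBRARY["WGM(10)"]
        plat = preset("MTP", S0=20)
        traj = simulate(p, None, plat)
        d = traj.data
        assert (d.qO <= p.q_O_max + 1e-9).all()
        # where DOT is pinned near zero the realized OUR cannot exceed the
        # quasi-steady oxygen transfer ceiling kLa·C_O2*/M_O2
        ceiling = plat.kla.value_at(0.0) * aux.C_O2_star * 1000.0 / 32.0
        limited = d.DOT_pct < 0.5
        assert limited.any()
        assert (d.OUR_mmolLh[limited] <= ceiling * 1.05).all()

    def test_acetate_consumed_after_glucose_depletion(self, wg10, aux):
        d = state_derivatives(
            0.0, ReactorState(X=2.0, S=0.0, A=0.4, DOT=70.0), wg10, aux,
            preset("MBR", S0=10))
        r = specific_rates(ReactorState(X=2.0, S=0.0, A=0.4, DOT=70.0), wg10, aux)
        assert d[2] < 0  # dA/dt
        assert r.mu > 0  # recycling sustains growth

    def test_peak_oxygen_uptake_magnitude_str(self, wg20_str_traj):
        # measured stirred-tank peaks reach ~140 mmol O2/(L·h); the model
        # should land in that neighbourhood at batch end
        peak = wg20_str_traj.data.OUR_mmolLh.max()
        assert 0.75 * 140 <= peak <= 1.25 * 140

    def test_lag_phase_freezes_biology(self, wg10):
        plat = preset("MBR", S0=10).replace(lag_h=1.0, t_end=3.0)
        d = simulate(wg10, None, plat).data
        early = d[d.time_h < 0.99]
        assert np.allclose(early.X_gL, early.X_gL.iloc[0])
        assert np.allclose(early[["qS", "mu"]], 0.0)

    def test_trajectory_export_schema(self, tmp_path, wg20_str_traj):
        out = tmp_path / "traj.csv"
        wg20_str_traj.to_csv(out)
        import pandas as pd

        back = pd.read_csv(out)
        assert list(back.columns) == TRAJECTORY_COLUMNS
        assert len(back) == len(wg20_str_traj.data)


@given(
    q_S_max=st.floats(0.4, 2.0),
    Y_XS_em=st.floats(0.2, 0.65),
    q_Ap_max=st.floats(0.01, 0.3),
    S0=st.floats(2.0, 15.0),
)
@settings(max_examples=12, deadline=None, derandomize=True)
def test_nonnegativity_across_parameter_space(q_S_max, Y_XS_em, q_Ap_max, S0):
    """State variables stay non-negative for arbitrary valid strains."""
    p = StrainParameters(mu_max=1.2, K_S=0.01, q_S_max=q_S_max,
                         q_Ap_max=q_Ap_max, q_Ac_max=0.07, q_O_max=0.8,
                         q_m=0.04, Y_XS_em=Y_XS_em, Y_OX=1.4)
    plat = preset("MBR", S0=S0).replace(t_end=6.0)
    traj = simulate(p, None, plat, rtol=1e-6, atol=1e-8)
    assert (traj.data[["X_gL", "S_gL", "A_gL", "DOT_pct"]].to_numpy() >= -1e-9).all()
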