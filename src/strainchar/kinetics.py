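"""Macro-kinetic batch/pulse growth model of *E. coli* with overflow
metabolism and acetate recycling.

State variables: biomass X [g/L], glucose S [g/L], acetate A [g/L] and
dissolved oxygen tension DOT [% air saturation]. Specific rates follow a
glucose-partitioning scheme: Monod glucose uptake feeds maintenance, biomass
formation and a saturation-driven acetate overflow flux; previously secreted
acetate is re-consumed (optionally while glucose is still present) with its
own affinity term; respiration demand follows growth and maintenance and is
capped by the strain's maximum specific oxygen uptake rate — glucose flux that
cannot be respired is diverted to additional acetate overflow.

The ODE system is integrated with a stiff-capable solver with event detection
for depletion-triggered glucose pulses and support for stepped aeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import AuxiliaryConstants, StrainParameters
from .platforms import PlatformConfig, PulseSchedule, Schedule

__all__ = [
    "ReactorState",
    "SpecificRates",
    "InvalidStateError",
    "SimulationError",
    "specific_rates",
    "state_derivatives",
    "simulate",
    "Trajectory",
]

#: molar mass of O2, g/mol — converts specific oxygen fluxes to mmol.
M_O2 = 32.0

TRAJECTORY_COLUMNS = [
    "time_h", "X_gL", "S_gL", "A_gL", "DOT_pct",
    "qS", "qAp", "qAc", "qO", "mu", "OUR_mmolLh", "CPR_mmolLh", "event_flag",
]


class InvalidStateError(ValueError):
    """Raised when a reactor state contains non-finite components."""


class _WorkLimit(Exception):
    def __init__(self, t: float):
        self.t = float(t)


class SimulationError(RuntimeError):
    """Integration failure; carries the last time the solver reached."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(f"{message} (last valid time: {last_valid_time:.4f} h)")
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class ReactorState:
    """Instantaneous culture state."""

    X: float  # biomass, g/L
    S: float  # glucose, g/L
    A: float  # acetate, g/L
    DOT: float = 100.0  # % air saturation

    def __post_init__(self) -> None:
        vals = (self.X, self.S, self.A, self.DOT)
        if not all(np.isfinite(vals)):
            raise InvalidStateError(f"non-finite reactor state {vals}")
        if min(vals) < -1e-9:
            raise InvalidStateError(f"negative reactor state {vals}")
        if self.DOT > 100.0 + 1e-6:
            raise InvalidStateError(f"DOT above saturation: {self.DOT}")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.S, self.A, self.DOT], dtype=float)


@dataclass(frozen=True)
class SpecificRates:
    """Specific conversion rates, g per g biomass per h; mu in 1/h."""

    q_S: float
    q_Ap: float
    q_Ac: float
    q_O: float
    mu: float


def _rates_arrays(X, S, A, DOT, p: StrainParameters, aux: AuxiliaryConstants):
    """Vectorised rate-law core. Inputs broadcastable arrays; returns a dict
    of arrays (q_S, q_Ap, q_Ac, q_O, mu)."""
    S = np.maximum(np.asarray(S, dtype=float), 0.0)
    A = np.maximum(np.asarray(A, dtype=float), 0.0)
    DOT = np.maximum(np.asarray(DOT, dtype=float), 0.0)

    monod_S = np.where(S > 0, S / (S + p.K_S), 0.0)
    q_S = p.q_S_max * monod_S
    q_Ap = p.q_Ap_max * monod_S
    q_Ac = np.where(
        A > 0,
        p.q_Ac_max
        * (A / (A + aux.K_A))
        * (aux.K_IS / (aux.K_IS + S))
        * (DOT / (DOT + aux.K_O)),
        0.0,
    )

    # maintenance cannot exceed actual uptake; this zeroes maintenance (and
    # its oxygen demand) when glucose is gone
    q_m_eff = np.minimum(p.q_m, q_S)

    # potential growth from the glucose partition (uptake minus maintenance
    # minus overflow-diverted glucose) plus growth on recycled acetate
    mu_pot = (q_S - q_m_eff - q_Ap / aux.Y_AS) * p.Y_XS_em + q_Ac * aux.Y_XA

    o_scale = DOT / (DOT + aux.K_O)
    q_O_dem = np.maximum(p.Y_OX * mu_pot + aux.c_Om * q_m_eff, 0.0) * o_scale

    limited = q_O_dem > p.q_O_max
    mu_lim = np.maximum((p.q_O_max - aux.c_Om * q_m_eff) / p.Y_OX, 0.0)
    mu = np.where(limited, mu_lim, np.maximum(mu_pot, 0.0))
    q_O = np.where(limited, p.q_O_max, q_O_dem)
    # respiratory shortfall: divert the unrespirable glucose to acetate
    q_Ap = q_Ap + np.where(
        limited, aux.Y_AS * np.maximum(mu_pot - mu, 0.0) / p.Y_XS_em, 0.0
    )

    # hard growth-rate cap; surplus flux again overflows to acetate
    over_cap = mu > p.mu_max
    if np.any(over_cap):
        q_Ap = q_Ap + np.where(
            over_cap, aux.Y_AS * (mu - p.mu_max) / p.Y_XS_em, 0.0
        )
        q_O = np.where(
            over_cap,
            np.minimum(q_O, (p.Y_OX * p.mu_max + aux.c_Om * q_m_eff) * o_scale),
            q_O,
        )
        mu = np.minimum(mu, p.mu_max)

    return {"q_S": q_S, "q_Ap": q_Ap, "q_Ac": q_Ac, "q_O": q_O, "mu": mu}


def specific_rates(
    state: ReactorState, p: StrainParameters, aux: AuxiliaryConstants | None = None
) -> SpecificRates:
    """Evaluate the specific rate laws at one reactor state."""
    aux = aux or AuxiliaryConstants()
    r = _rates_arrays(state.X, state.S, state.A, state.DOT, p, aux)
    return SpecificRates(
        q_S=float(r["q_S"]), q_Ap=float(r["q_Ap"]), q_Ac=float(r["q_Ac"]),
        q_O=float(r["q_O"]), mu=float(r["mu"]),
    )


def state_derivatives(
    t: float,
    state: ReactorState | np.ndarray,
    p: StrainParameters,
    aux: AuxiliaryConstants,
    platform: PlatformConfig,
) -> np.ndarray:
    """Time derivatives (dX, dS, dA, dDOT) at time ``t``.

    dDOT combines gas-liquid transfer kLa·(100 − DOT) with the biological
    uptake q_O·X expressed on the % saturation scale via 100/C_O2_star.
    """
    if isinstance(state, ReactorState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    kla = platform.kla.value_at(t)
    if kla <= 0:
        raise ValueError("kLa must be positive")
    return _rhs(t, y, p, aux, platform, kla, lag_active=t < platform.lag_h)


def _rhs(t, y, p, aux, platform, kla, lag_active: bool) -> np.ndarray:
    X, S, A, DOT = y
    if lag_active:
        return np.array([0.0, 0.0, 0.0, kla * (100.0 - DOT)])
    r = _rates_arrays(X, S, A, DOT, p, aux)
    X_eff = max(X, 0.0)
    dX = r["mu"] * X_eff
    dS = -r["q_S"] * X_eff
    dA = (r["q_Ap"] - r["q_Ac"]) * X_eff
    dDOT = kla * (100.0 - DOT) - r["q_O"] * X_eff * (100.0 / aux.C_O2_star)
    return np.array([float(dX), float(dS), float(dA), float(dDOT)])


@dataclass
class Trajectory:
    """Simulation result: a tidy frame plus the pulse-event log.

    ``data`` columns: time_h, X_gL, S_gL, A_gL, DOT_pct, qS, qAp, qAc, qO,
    mu, OUR_mmolLh, CPR_mmolLh, event_flag.
    """

    data: pd.DataFrame
    pulse_times: list[float]
    params: StrainParameters
    aux: AuxiliaryConstants
    platform: PlatformConfig

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def interp(self, channel: str, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.data["time_h"].to_numpy(), self.data[channel].to_numpy())

    @property
    def final_state(self) -> ReactorState:
        row = self.data.iloc[-1]
        return ReactorState(
            X=max(row.X_gL, 0.0), S=max(row.S_gL, 0.0),
            A=max(row.A_gL, 0.0), DOT=min(max(row.DOT_pct, 0.0), 100.0),
        )

    def depletion_time(self, threshold: float = 0.05) -> float:
        """Last time glucose drops below ``threshold`` g/L (batch length)."""
        s = self.data["S_gL"].to_numpy()
        t = self.data["time_h"].to_numpy()
        below = s < threshold
        if not below.any():
            return float("nan")
        # last crossing from above into the depleted region
        crossings = np.flatnonzero(below & ~np.r_[False, below[:-1]])
        return float(t[crossings[-1]])


def simulate(
    p: StrainParameters,
    aux: AuxiliaryConstants | None,
    platform: PlatformConfig,
    x0: ReactorState | None = None,
    t_end: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_rhs_evals: int = 500_000,
) -> Trajectory:
    """Simulate one batch/pulse cultivation.

    Depletion-triggered pulses are located by event root-finding on the
    glucose threshold crossing; timed pulses and aeration steps partition the
    integration into segments with constant operating conditions. The
    trajectory is reported on a uniform grid of spacing ``platform.dt_out``
    plus the pulse instants (post-pulse state, ``event_flag = 1``).
    """
    aux = aux or AuxiliaryConstants()
    if x0 is None:
        x0 = ReactorState(X=platform.X0, S=platform.S0, A=platform.A0, DOT=platform.DOT0)
    t_end = float(t_end if t_end is not None else platform.t_end)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if min(platform.kla.values) <= 0:
        raise ValueError("kLa must be positive")

    # work guard: pathological parameter regions (met during optimization)
    # can make the integrator grind; bound the total right-hand-side work
    n_evals = [0]

    def guarded_rhs(t, yy, *args):
        n_evals[0] += 1
        if n_evals[0] > max_rhs_evals:
            raise _WorkLimit(t)
        return _rhs(t, yy, *args)

    pulse = platform.pulse
    pulses_left = pulse.max_pulses if pulse is not None else 0
    timed_pulses = sorted(pulse.times) if (pulse and pulse.mode == "timed") else []

    seg_edges = sorted({0.0, t_end, *platform.breakpoints()})
    grid = np.arange(0.0, t_end + platform.dt_out / 2, platform.dt_out)

    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    event_times: list[float] = []

    y = x0.as_array().copy()
    t_cur = 0.0
    guard = 0
    while t_cur < t_end - 1e-12:
        guard += 1
        if guard > 50:
            raise SimulationError("too many integration segments", t_cur)
        t_next = next(e for e in seg_edges if e > t_cur + 1e-12)
        kla = platform.kla.value_at(t_cur + 1e-9)
        lag_active = t_cur + 1e-9 < platform.lag_h

        events = []
        if (
            pulse is not None
            and pulse.mode == "depletion"
            and pulses_left > 0
            and not lag_active
        ):
            def depletion(t, yy, *args, thr=pulse.threshold):
                return yy[1] - thr
            depletion.terminal = True
            depletion.direction = -1
            events.append(depletion)

        t_eval = grid[(grid > t_cur + 1e-12) & (grid < t_next - 1e-12)]
        try:
            sol = solve_ivp(
                guarded_rhs, (t_cur, t_next), y, method=method, rtol=rtol,
                atol=atol, t_eval=np.r_[t_eval, t_next], events=events or None,
                args=(p, aux, platform, kla, lag_active),
            )
        except _WorkLimit as wl:
            raise SimulationError(
                f"integration exceeded {max_rhs_evals} derivative evaluations",
                wl.t,
            ) from None
        if not sol.success and sol.status != 1:
            raise SimulationError(f"solver failed: {sol.message}", t_cur)

        fired = sol.status == 1 and events and len(sol.t_events[0]) > 0
        if fired:
            t_ev = float(sol.t_events[0][0])
            keep = sol.t < t_ev - 1e-12
            rows_t.append(sol.t[keep])
            rows_y.append(sol.y[:, keep].T)
            y = sol.y_events[0][0].copy()
            y[1] = pulse.target  # glucose restored by the pulse
            pulses_left -= 1
            event_times.append(t_ev)
            rows_t.append(np.array([t_ev]))
            rows_y.append(y[None, :].copy())
            t_cur = t_ev
        else:
            rows_t.append(sol.t)
            rows_y.append(sol.y.T)
            y = sol.y[:, -1].copy()
            t_cur = t_next
            if timed_pulses and pulses_left > 0 and any(
                abs(t_cur - tp) < 1e-9 for tp in timed_pulses
            ):
                y[1] = pulse.target
                pulses_left -= 1
                event_times.append(t_cur)
                rows_t.append(np.array([t_cur]))
                rows_y.append(y[None, :].copy())
        y = np.maximum(y, 0.0)  # clip numerical undershoot

    t_all = np.concatenate([np.array([0.0]), *rows_t])
    y_all = np.vstack([x0.as_array()[None, :], *rows_y])
    y_all = np.maximum(y_all, 0.0)

    r = _rates_arrays(y_all[:, 0], y_all[:, 1], y_all[:, 2], y_all[:, 3], p, aux)
    lag_mask = t_all < platform.lag_h
    for k in r:
        r[k] = np.where(lag_mask, 0.0, r[k])
    our = r["q_O"] * y_all[:, 0] / M_O2 * 1000.0  # mmol O2/(L·h)
    cpr = platform.rq * our

    flags = np.zeros(len(t_all), dtype=int)
    for t_ev in event_times:
        flags[np.argmin(np.abs(t_all - t_ev))] = 1

    df = pd.DataFrame({
        "time_h": t_all,
        "X_gL": y_all[:, 0], "S_gL": y_all[:, 1],
        "A_gL": y_all[:, 2], "DOT_pct": y_all[:, 3],
        "qS": r["q_S"], "qAp": r["q_Ap"], "qAc": r["q_Ac"],
        "qO": r["q_O"], "mu": r["mu"],
        "OUR_mmolLh": our, "CPR_mmolLh": cpr,
        "event_flag": flags,
    })
    return Trajectory(df, event_times, p, aux, platform)
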