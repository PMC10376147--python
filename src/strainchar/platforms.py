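"""Reactor/platform context shared by the simulator and the data generator.

A :class:`PlatformConfig` bundles everything about the cultivation vessel and
its instrumentation that is *not* a strain property: liquid volume, gas-liquid
mass transfer (kLa) and aeration schedules, inlet gas composition, the glucose
pulse policy, per-channel sampling grids and measurement-noise magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["Schedule", "PulseSchedule", "NoiseSpec", "PlatformConfig"]


@dataclass(frozen=True)
class Schedule:
    """Piecewise-constant schedule: value ``values[i]`` holds from
    ``times[i]`` until the next breakpoint."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) == 0 or len(self.times) != len(self.values):
            raise ValueError("schedule needs equally many times and values, at least one each")
        if any(t2 < t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("schedule times must be non-decreasing")
        if self.times[0] > 0:
            raise ValueError("schedule must define a value from t=0")

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls((0.0,), (float(value),))

    def value_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.values[max(idx, 0)]

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return self.times[1:]


@dataclass(frozen=True)
class PulseSchedule:
    """Glucose re-feed policy.

    ``depletion`` mode fires when glucose falls below ``threshold`` g/L and
    restores it to ``target`` g/L, at most ``max_pulses`` times. ``timed``
    mode replays logged pulse times (used when fitting to data whose pulse
    times are known inputs).
    """

    mode: str = "depletion"  # "depletion" | "timed"
    target: float = 10.0
    threshold: float = 0.05
    max_pulses: int = 1
    times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("depletion", "timed"):
            raise ValueError(f"unknown pulse mode {self.mode!r}")
        if self.max_pulses not in (0, 1, 2):
            raise ValueError("max_pulses must be 0, 1 or 2")
        if self.threshold < 0:
            raise ValueError("pulse threshold must be >= 0")
        if self.mode == "timed" and len(self.times) > self.max_pulses:
            raise ValueError("more timed pulses than max_pulses allows")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: sd = max(rel · |value|, abs). Gaussian, clipped so
    samples of non-negative quantities stay non-negative."""

    rel: float = 0.0
    abs: float = 0.0

    def __post_init__(self) -> None:
        if self.rel < 0 or self.abs < 0:
            raise ValueError("noise sds must be >= 0")

    def sd(self, value):
        return np.maximum(self.rel * np.abs(value), self.abs)


@dataclass(frozen=True)
class PlatformConfig:
    tag: str                      # MTP | MBR | STR (or custom)
    V: float                      # liquid volume, L
    kla: Schedule                 # 1/h
    F_in: Schedule                # inlet gas flow, L/h
    x_O2_in: float = 0.2095       # inlet mole fractions (dry air)
    x_CO2_in: float = 0.0004
    pulse: PulseSchedule | None = None
    X0: float = 0.185             # g DCW/L (OD600 0.5 × 0.37)
    S0: float = 10.0              # g/L
    A0: float = 0.0
    DOT0: float = 100.0           # % air saturation
    rq: float = 1.0               # respiratory quotient for model CPR
    lag_h: float = 0.0            # initial dead time with zero biological rates
    t_end: float = 12.0
    dt_out: float = 1.0 / 60.0    # output grid spacing, h
    sampling: dict = field(default_factory=dict)   # channel -> grid spacing, h
    noise: dict = field(default_factory=dict)      # channel -> NoiseSpec

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("reactor volume must be positive")
        if min(self.kla.values) <= 0:
            raise ValueError("kLa must be strictly positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not (0 <= self.x_O2_in < 1 and 0 <= self.x_CO2_in < 1):
            raise ValueError("inlet mole fractions must lie in [0, 1)")

    @property
    def channels(self) -> set[str]:
        return set(self.sampling)

    def replace(self, **kw) -> "PlatformConfig":
        return replace(self, **kw)

    def breakpoints(self) -> list[float]:
        """Times at which operating conditions change discontinuously."""
        pts = set(self.kla.breakpoints) | set(self.F_in.breakpoints)
        if self.lag_h > 0:
            pts.add(self.lag_h)
        if self.pulse is not None and self.pulse.mode == "timed":
            pts |= set(self.pulse.times)
        return sorted(p for p in pts if 0 < p < self.t_end)


def uniform_grid(t_end: float, spacing: float, t0: float = 0.0) -> np.ndarray:
    """Sampling instants ``t0, t0+spacing, ...`` up to and including t_end."""
    n = int(np.floor((t_end - t0) / spacing + 1e-9))
    return t0 + spacing * np.arange(n + 1)
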