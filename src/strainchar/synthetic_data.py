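"""In-silico cultivation campaigns emulating three platform scales.

Presets
-------
``MTP``  24-well microtiter plate, 1 mL, DOT optode only, mass transfer sized
         to an oxygen-transfer ceiling of ~30 mmol O2/(L·h) — wells at high
         glucose run into an extended DOT≈0 plateau.
``MBR``  10 mL stirred mini-bioreactor, 5 or 10 g/L initial glucose with
         depletion-triggered glucose pulses (twice at 5 g/L, once at 10 g/L),
         1-min DOT plus atline biomass/glucose/acetate every 30 min.
``STR``  100 mL stirred tank, 20 g/L glucose, 1-min off-gas O2/CO2 with a
         stepped aeration schedule (0.22 → 0.66 vvm at 2.75 h → 1.66 vvm at
         6.8 h), hourly atline samples.

``generate`` simulates the true trajectory, samples each channel on its grid,
applies the channel noise model (multiplicative for X/S/A with absolute
floors, additive for DOT and gas mole fractions), and for off-gas platforms
fabricates outlet gas fractions by analytically inverting the gas balances at
the model's OUR/CPR before adding analyzer noise. Everything is reproducible
from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import offgas as og
from .estimation import Channel, Dataset
from .kinetics import Trajectory, simulate
from .params import AuxiliaryConstants, StrainParameters
from .platforms import NoiseSpec, PlatformConfig, PulseSchedule, Schedule, uniform_grid

__all__ = [
    "preset",
    "generate",
    "SyntheticCampaign",
    "campaign_table",
    "DEFAULT_NOISE",
]

#: default measurement-noise magnitudes per channel: sd = max(rel·|v|, abs).
DEFAULT_NOISE: dict[str, NoiseSpec] = {
    "X": NoiseSpec(rel=0.05),
    "S": NoiseSpec(rel=0.03, abs=0.05),
    "A": NoiseSpec(rel=0.05, abs=0.02),
    "DOT": NoiseSpec(abs=2.0),
    "OUR": NoiseSpec(rel=0.03, abs=0.3),
    "CPR": NoiseSpec(rel=0.03, abs=0.3),
    "gas": NoiseSpec(abs=2.0e-4),  # analyzer noise on outlet mole fractions
}

#: kLa [1/h] giving the ~30 mmol O2/(L·h) microtiter OTR ceiling:
#: OTR_max = kLa · C_O2* / M_O2 · 1000 with C_O2* = 7.2 mg/L.
MTP_KLA = 30.0 * 32.0 / 7.2


def preset(tag: str, S0: float | None = None, **overrides) -> PlatformConfig:
    """Platform preset; ``overrides`` replace any PlatformConfig field."""
    minute = 1.0 / 60.0
    if tag == "MTP":
        cfg = PlatformConfig(
            tag="MTP", V=0.001,
            kla=Schedule.constant(MTP_KLA),
            F_in=Schedule.constant(3.0),
            pulse=None,
            X0=0.25 * 0.37, S0=10.0 if S0 is None else float(S0),
            t_end=15.0,
            sampling={"DOT": minute},
            noise={"DOT": DEFAULT_NOISE["DOT"]},
        )
    elif tag == "MBR":
        s0 = 10.0 if S0 is None else float(S0)
        cfg = PlatformConfig(
            tag="MBR", V=0.010,
            kla=Schedule.constant(600.0),
            F_in=Schedule.constant(300.0),
            pulse=PulseSchedule(
                mode="depletion", target=s0, threshold=0.05,
                max_pulses=2 if s0 <= 5.0 else 1,
            ),
            X0=0.5 * 0.37, S0=s0,
            t_end=12.0,
            sampling={"DOT": minute, "X": 0.5, "S": 0.5, "A": 0.5},
            noise={k: DEFAULT_NOISE[k] for k in ("DOT", "X", "S", "A")},
        )
    elif tag == "STR":
        s0 = 20.0 if S0 is None else float(S0)
        V = 0.090
        vvm = (0.22, 0.66, 1.66)  # gas volume flow per liquid volume per min
        cfg = PlatformConfig(
            tag="STR", V=V,
            kla=Schedule(times=(0.0, 2.75, 6.8), values=(300.0, 500.0, 900.0)),
            F_in=Schedule(times=(0.0, 2.75, 6.8),
                          values=tuple(v * V * 60.0 for v in vvm)),
            pulse=None,
            X0=0.5 * 0.37, S0=s0,
            # long enough that even the slowest strain passes glucose
            # depletion and shows the acetate-consumption tail
            t_end=14.0,
            sampling={"DOT": minute, "OUR": minute, "CPR": minute,
                      "X": 1.0, "S": 1.0, "A": 1.0},
            noise={**{k: DEFAULT_NOISE[k] for k in
                      ("DOT", "X", "S", "A", "OUR", "CPR")},
                   "gas": DEFAULT_NOISE["gas"]},
        )
    else:
        raise ValueError(f"unknown platform tag {tag!r} (expected MTP, MBR or STR)")
    return cfg.replace(**overrides) if overrides else cfg


def _sample_channel(traj: Trajectory, column: str, grid: np.ndarray,
                    spec: NoiseSpec, rng: np.random.Generator,
                    clip_nonneg: bool = True) -> Channel:
    truth = traj.interp(column, grid)
    sd = np.asarray(spec.sd(truth), dtype=float)
    sd_w = np.where(sd > 0, sd, 0.0)
    sample = truth + rng.standard_normal(len(grid)) * sd_w
    if clip_nonneg:
        sample = np.maximum(sample, 0.0)
    # weights for fitting: never exactly zero even in noiseless studies
    sd_fit = np.where(sd > 0, sd, np.maximum(1e-6 * np.abs(truth), 1e-9))
    return Channel(t=grid, value=sample, sd=sd_fit)


def generate(
    p: StrainParameters,
    config: PlatformConfig,
    seed: int,
    aux: AuxiliaryConstants | None = None,
    name: str = "",
) -> tuple[Dataset, Trajectory]:
    """One synthetic cultivation: returns the noisy Dataset and the
    ground-truth trajectory."""
    aux = aux or AuxiliaryConstants()
    rng = np.random.default_rng(seed)
    traj = simulate(p, aux, config)

    from .kinetics import TRAJECTORY_COLUMNS  # noqa: F401  (column names doc)
    colmap = {"X": "X_gL", "S": "S_gL", "A": "A_gL", "DOT": "DOT_pct",
              "OUR": "OUR_mmolLh", "CPR": "CPR_mmolLh"}

    channels: dict[str, Channel] = {}
    offgas_df = None
    oxygen_limited = bool((traj.data["DOT_pct"] < 1.0).any())

    gas_channels = {"OUR", "CPR"} & set(config.sampling)
    for ch_name, spacing in config.sampling.items():
        if ch_name in gas_channels:
            continue  # handled through the fabricated off-gas below
        grid = uniform_grid(config.t_end, spacing)
        spec = config.noise.get(ch_name, NoiseSpec())
        channels[ch_name] = _sample_channel(traj, colmap[ch_name], grid, spec, rng)

    if gas_channels:
        spacing = min(config.sampling[c] for c in gas_channels)
        grid = uniform_grid(config.t_end, spacing)
        our_true = traj.interp("OUR_mmolLh", grid)
        cpr_true = traj.interp("CPR_mmolLh", grid)
        gas_spec = config.noise.get("gas", NoiseSpec())
        records, our_meas, cpr_meas = [], [], []
        for t, our_i, cpr_i in zip(grid, our_true, cpr_true):
            f_in = config.F_in.value_at(t)
            try:
                o2, co2 = og.invert_offgas(our_i, cpr_i, f_in, config.V,
                                           config.x_O2_in, config.x_CO2_in)
            except og.InfeasibleGasError:
                # demand beyond what the aeration can carry: scale the rates
                # down to the largest physical transfer (outlet O2 pinned near
                # zero) and flag the run as oxygen limited
                oxygen_limited = True
                scale = 1.0
                while True:
                    scale *= 0.9
                    try:
                        o2, co2 = og.invert_offgas(
                            our_i * scale, cpr_i * scale, f_in, config.V,
                            config.x_O2_in, config.x_CO2_in)
                        break
                    except og.InfeasibleGasError:
                        if scale < 1e-6:
                            o2, co2 = config.x_O2_in, config.x_CO2_in
                            break
            noisy = np.clip(
                np.array([o2, co2]) + rng.standard_normal(2) * gas_spec.abs,
                0.0, 0.999,
            )
            rec = og.OffGasRecord(t=float(t), F_in=f_in, V=config.V,
                                  x_O2_in=config.x_O2_in, x_CO2_in=config.x_CO2_in,
                                  x_O2_out=float(noisy[0]), x_CO2_out=float(noisy[1]))
            records.append(rec)
            our_meas.append(og.compute_our(rec))
            cpr_meas.append(og.compute_cpr(rec))
        offgas_df = og.offgas_frame(records)
        for ch_name, meas, truth in (("OUR", our_meas, our_true),
                                     ("CPR", cpr_meas, cpr_true)):
            if ch_name in gas_channels:
                spec = config.noise.get(ch_name, NoiseSpec())
                sd_fit = np.maximum(spec.sd(truth), 1e-9)
                channels[ch_name] = Channel(t=grid, value=np.asarray(meas), sd=sd_fit)

    # fitting replays the realized pulses at their logged times
    fit_platform = config
    if config.pulse is not None and config.pulse.mode == "depletion":
        fit_platform = config.replace(
            pulse=PulseSchedule(
                mode="timed", target=config.pulse.target,
                threshold=config.pulse.threshold,
                max_pulses=config.pulse.max_pulses,
                times=tuple(traj.pulse_times),
            )
        )

    ds = Dataset(platform=fit_platform, channels=channels, aux=aux, name=name,
                 offgas=offgas_df, oxygen_limited=oxygen_limited)
    return ds, traj


@dataclass
class SyntheticCampaign:
    """A batch of synthetic runs: (name, parameters, platform, seed) entries
    plus their generated datasets and ground truths."""

    entries: list[tuple[str, StrainParameters, PlatformConfig, int]]
    aux: AuxiliaryConstants = field(default_factory=AuxiliaryConstants)
    datasets: list[Dataset] = field(default_factory=list)
    truths: list[Trajectory] = field(default_factory=list)

    def run(self) -> "SyntheticCampaign":
        self.datasets, self.truths = [], []
        for name, p, cfg, seed in self.entries:
            ds, traj = generate(p, cfg, seed, aux=self.aux, name=name)
            self.datasets.append(ds)
            self.truths.append(traj)
        return self


def campaign_table(campaign: SyntheticCampaign) -> pd.DataFrame:
    """One summary row per run: batch length (time of final glucose
    depletion), peak oxygen uptake, final biomass, acetate peak."""
    rows = []
    for (name, p, cfg, seed), traj in zip(campaign.entries, campaign.truths):
        d = traj.data
        rows.append({
            "run": name,
            "platform": cfg.tag,
            "S0_gL": cfg.S0,
            "seed": seed,
            "batch_length_h": traj.depletion_time(),
            "peak_OUR_mmolLh": float(d["OUR_mmolLh"].max()),
            "final_X_gL": float(d["X_gL"].iloc[-1]),
            "peak_acetate_gL": float(d["A_gL"].max()),
        })
    return pd.DataFrame(rows, columns=["run", "platform", "S0_gL", "seed",
                                       "batch_length_h", "peak_OUR_mmolLh",
                                       "final_X_gL", "peak_acetate_gL"])
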