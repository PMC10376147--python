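"""Parameter estimation: weighted nonlinear least squares across one or more
cultivation datasets, with linearized uncertainties and identifiability
profiles.

Free parameters are optimized in log-space (all are strictly positive and
span two orders of magnitude); multi-start uses Latin-hypercube samples of the
log-bounds box. Uncertainties come from the linearized covariance
σ²·(JᵀJ)⁻¹ at the optimum, mapped back to the linear scale by the delta
method.

Which parameters *can* be estimated depends on the experiment: the maximum
specific oxygen uptake rate only leaves a signature when the respiratory cap
actually binds (high-glucose stirred-tank runs), the glucose affinity K_S only
matters near depletion, and the growth-rate cap mu_max is inactive for all
library parameter sets (growth is set by the yield chain), so it is never in
the default free set. ``default_free_set`` encodes these choices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import SimulationError, simulate
from .params import PARAMETER_NAMES, AuxiliaryConstants, StrainParameters
from .platforms import PlatformConfig

__all__ = [
    "Channel",
    "Dataset",
    "FitResult",
    "NoFitError",
    "DEFAULT_BOUNDS",
    "default_free_set",
    "objective",
    "fit_parameters",
    "profile_identifiability",
    "fit_table",
]

#: trajectory column backing each observation channel
CHANNEL_COLUMNS = {
    "X": "X_gL", "S": "S_gL", "A": "A_gL", "DOT": "DOT_pct",
    "OUR": "OUR_mmolLh", "CPR": "CPR_mmolLh",
}

#: DOT observations below this % saturation are dropped from the objective
#: (optode floor).
DOT_FLOOR = 5.0

#: finite penalty residual used when a candidate parameter set cannot be
#: simulated (keeps the optimizer moving instead of raising).
PENALTY_RESIDUAL = 1.0e3

#: default box bounds for the free parameters (linear scale).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_max": (0.05, 1.5),
    "K_S": (1e-4, 0.5),
    "q_S_max": (0.2, 2.5),
    "q_Ap_max": (1e-3, 0.5),
    "q_Ac_max": (1e-3, 0.5),
    "q_O_max": (0.1, 2.0),
    "q_m": (1e-3, 0.3),
    "Y_XS_em": (0.05, 0.7),
    "Y_OX": (0.5, 2.5),
}


class NoFitError(RuntimeError):
    """All optimization starts failed."""


@dataclass(frozen=True)
class Channel:
    """One observation series: times [h], values, and standard deviations."""

    t: np.ndarray
    value: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        v = np.asarray(self.value, float)
        s = np.asarray(self.sd, float)
        if not (t.shape == v.shape == s.shape) or t.ndim != 1:
            raise ValueError("t, value, sd must be 1-D arrays of equal length")
        if np.any(s <= 0):
            raise ValueError("channel sd must be strictly positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        object.__setattr__(self, "sd", s)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Dataset:
    """One cultivation run as seen by the estimator.

    The platform carries the known inputs (initial state, pulse times,
    aeration schedule); channels are a subset of X, S, A, DOT, OUR, CPR.
    """

    platform: PlatformConfig
    channels: dict[str, Channel]
    aux: AuxiliaryConstants = field(default_factory=AuxiliaryConstants)
    name: str = ""
    offgas: pd.DataFrame | None = None
    oxygen_limited: bool = False

    def __post_init__(self) -> None:
        if not self.channels or all(len(c) == 0 for c in self.channels.values()):
            raise ValueError("dataset needs at least one non-empty channel")
        unknown = set(self.channels) - set(CHANNEL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")

    @property
    def n_obs(self) -> int:
        return sum(self._channel_mask(name).sum() for name in self.channels)

    def _channel_mask(self, name: str) -> np.ndarray:
        ch = self.channels[name]
        if name == "DOT":
            return ch.value > DOT_FLOOR
        return np.ones(len(ch), dtype=bool)


def default_free_set(dataset: Dataset) -> tuple[str, ...]:
    """Platform/condition-aware default choice of free parameters."""
    tag = dataset.platform.tag
    if tag == "MTP":
        return ("q_S_max", "K_S", "Y_OX")
    # q_m stays fixed: in a batch at S >> K_S the growth rate is constant, so
    # only (q_S_max - q_m - q_Ap_max/Y_AS)·Y_XS_em and Y_OX·mu + c_Om·q_m are
    # constrained and maintenance trades off flatly against the two yields
    free = ["q_S_max", "q_Ac_max", "Y_XS_em", "Y_OX"]
    if dataset.platform.S0 < 15:
        free.append("K_S")  # identifiable only when S passes through ~K_S
        free.append("q_Ap_max")
    if tag == "STR":
        # the respiratory cap binds in high-glucose STRs, which makes q_O_max
        # estimable but q_Ap_max degenerate: glucose flux above the cap ends
        # up as acetate regardless of the overflow routing parameter
        free.append("q_O_max")
    else:
        if "q_Ap_max" not in free:
            free.append("q_Ap_max")
    return tuple(free)


def _simulate_dataset(p: StrainParameters, ds: Dataset, sim_kwargs: dict):
    return simulate(p, ds.aux, ds.platform, **sim_kwargs)


def _residuals_for(p: StrainParameters, ds: Dataset, sim_kwargs: dict) -> np.ndarray:
    traj = _simulate_dataset(p, ds, sim_kwargs)
    parts = []
    for name, ch in ds.channels.items():
        mask = ds._channel_mask(name)
        model = traj.interp(CHANNEL_COLUMNS[name], ch.t[mask])
        parts.append((model - ch.value[mask]) / ch.sd[mask])
    return np.concatenate(parts) if parts else np.empty(0)


def objective(
    theta: np.ndarray,
    datasets: list[Dataset],
    free: tuple[str, ...],
    base: StrainParameters,
    log_scale: bool = True,
    sim_kwargs: dict | None = None,
) -> np.ndarray:
    """Weighted residual vector (model − data)/sd, concatenated over channels
    and datasets. Simulation failures yield large finite penalty residuals."""
    sim_kwargs = dict(sim_kwargs or {})
    vals = np.exp(theta) if log_scale else np.asarray(theta, float)
    try:
        p = base.replace(**dict(zip(free, vals)))
    except ValueError:
        return PENALTY_RESIDUAL * np.ones(sum(ds.n_obs for ds in datasets))
    out = []
    for ds in datasets:
        try:
            out.append(_residuals_for(p, ds, sim_kwargs))
        except (SimulationError, ValueError, RuntimeError):
            out.append(PENALTY_RESIDUAL * np.ones(ds.n_obs))
    return np.concatenate(out)


@dataclass
class FitResult:
    """Point estimates with uncertainties for one strain×condition fit."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    fixed: dict[str, float]
    rss: float
    channel_rmse: dict[str, float]
    success: bool
    n_obs: int
    seed: int
    n_starts: int
    start_points: list[dict[str, float]]
    n_failed_starts: int = 0
    name: str = ""

    @property
    def parameters(self) -> StrainParameters:
        return StrainParameters(**{**self.fixed, **self.estimates})

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "estimates": self.estimates,
            "stderr": self.stderr,
            "fixed": self.fixed,
            "rss": self.rss,
            "channel_rmse": self.channel_rmse,
            "success": self.success,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "start_points": self.start_points,
            "n_failed_starts": self.n_failed_starts,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_parameters(
    datasets: list[Dataset] | Dataset,
    free: tuple[str, ...] | None = None,
    base: StrainParameters | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    sim_kwargs: dict | None = None,
    name: str = "",
    extra_starts: list[dict[str, float]] | None = None,
    max_nfev: int = 100,
    staged: bool = True,
) -> FitResult:
    """Multi-start trust-region least squares.

    ``base`` supplies values for the fixed parameters (and the fallback for
    any free one); start points are Latin-hypercube samples of the log-bounds
    box (plus any ``extra_starts``), the global best by residual norm wins,
    ties broken by smaller parameter-vector norm. Deterministic given
    ``seed``.

    With ``staged=True`` (default) and datasets that mix sparse atline
    channels (X/S/A) with dense 1-min signals (DOT/OUR/CPR), a pilot fit on
    the atline channels alone seeds the full fit: the dense gas channels
    dominate the joint objective and make it multimodal, while the atline
    channels constrain uptake and yields smoothly.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    if not datasets:
        raise ValueError("need at least one dataset")
    if free is None:
        free = default_free_set(datasets[0])
    if not free:
        raise ValueError("free parameter set is empty")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    base = base or StrainParameters(
        **{k: float(np.sqrt(lo * hi)) for k, (lo, hi) in DEFAULT_BOUNDS.items()}
    )
    sim_kwargs = dict(sim_kwargs or {"rtol": 1e-6, "atol": 1e-8})
    sim_kwargs.setdefault("max_rhs_evals", 40_000)
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.log([bnds[k][0] for k in free])
    hi = np.log([bnds[k][1] for k in free])

    if staged:
        atline = [
            Dataset(platform=ds.platform,
                    channels={k: v for k, v in ds.channels.items()
                              if k in ("X", "S", "A")},
                    aux=ds.aux, name=ds.name)
            for ds in datasets
            if {"X", "S", "A"} & set(ds.channels)
        ]
        dense = any({"DOT", "OUR", "CPR"} & set(ds.channels) for ds in datasets)
        s1_free = tuple(k for k in free if k not in ("Y_OX", "q_O_max"))
        if atline and dense and s1_free:
            pilot = fit_parameters(
                atline, free=s1_free, base=base, bounds=bounds,
                n_starts=n_starts, seed=seed, sim_kwargs=sim_kwargs,
                max_nfev=max_nfev, staged=False,
            )
            seed_start = {k: getattr(base, k) for k in free}
            seed_start.update(pilot.estimates)
            extra_starts = [seed_start] + list(extra_starts or [])

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    if extra_starts:
        extra = np.log([[np.clip(s[k], bnds[k][0], bnds[k][1]) for k in free]
                        for s in extra_starts])
        starts = np.vstack([extra, starts])

    best = None
    n_failed = 0
    for x0 in starts:
        try:
            res = least_squares(
                objective, x0, bounds=(lo, hi), method="trf",
                diff_step=1e-4, max_nfev=max_nfev,
                args=(datasets, free, base),
                kwargs={"sim_kwargs": sim_kwargs},
            )
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(res.cost):
            n_failed += 1
            continue
        key = (res.cost, float(np.linalg.norm(res.x)))
        if best is None or key < (best.cost, float(np.linalg.norm(best.x))):
            best = res
    if best is None:
        raise NoFitError(f"all {len(starts)} starts failed for fit {name!r}")

    theta = best.x
    values = np.exp(theta)
    p_hat = base.replace(**dict(zip(free, values)))
    n_obs = int(sum(ds.n_obs for ds in datasets))
    rss = float(2.0 * best.cost)

    # linearized covariance in log-space, delta method back to linear scale
    J = best.jac
    dof = max(n_obs - len(free), 1)
    sigma2 = rss / dof
    cov_log = sigma2 * np.linalg.pinv(J.T @ J)
    sd_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    stderr = {k: float(v * s) for k, v, s in zip(free, values, sd_log)}

    channel_rmse: dict[str, float] = {}
    report_kwargs = {**sim_kwargs, "max_rhs_evals": 500_000}
    for ds in datasets:
        try:
            traj = _simulate_dataset(p_hat, ds, report_kwargs)
        except SimulationError:
            for cname in ds.channels:
                key = cname if len(datasets) == 1 else f"{ds.name}:{cname}"
                channel_rmse[key] = float("nan")
            continue
        for cname, ch in ds.channels.items():
            mask = ds._channel_mask(cname)
            model = traj.interp(CHANNEL_COLUMNS[cname], ch.t[mask])
            err = float(np.sqrt(np.mean((model - ch.value[mask]) ** 2)))
            key = cname if len(datasets) == 1 else f"{ds.name}:{cname}"
            channel_rmse[key] = err

    return FitResult(
        estimates={k: float(v) for k, v in zip(free, values)},
        stderr=stderr,
        fixed={k: getattr(base, k) for k in PARAMETER_NAMES if k not in free},
        rss=rss,
        channel_rmse=channel_rmse,
        success=bool(best.status > 0),
        n_obs=n_obs,
        seed=seed,
        n_starts=len(starts),
        start_points=[{k: float(v) for k, v in zip(free, np.exp(s))}
                      for s in starts],
        n_failed_starts=n_failed,
        name=name,
    )


def profile_identifiability(
    datasets: list[Dataset] | Dataset,
    parameter: str,
    grid: np.ndarray,
    base: StrainParameters,
    free: tuple[str, ...] | None = None,
    seed: int = 0,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Objective profile: fix ``parameter`` at each grid value, re-optimize
    the remaining free parameters (warm-started along the grid), and report
    the residual sum of squares."""
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    if free is None:
        free = default_free_set(datasets[0])
    others = tuple(k for k in free if k != parameter)
    rows = []
    warm = None
    for val in np.asarray(grid, float):
        b = base.replace(**{parameter: float(val)})
        if others:
            fit = fit_parameters(
                datasets, free=others, base=b, n_starts=1, seed=seed,
                sim_kwargs=sim_kwargs,
                extra_starts=[warm] if warm else None,
            )
            warm = fit.estimates
            rows.append({"value": float(val), "rss": fit.rss})
        else:
            r = objective(np.array([np.log(val)]), datasets, (parameter,), b,
                          sim_kwargs=sim_kwargs)
            rows.append({"value": float(val), "rss": float(r @ r)})
    return pd.DataFrame(rows)


def fit_table(results: dict[str, FitResult]) -> pd.DataFrame:
    """Parameter-by-strain(condition) report: rows are the nine kinetic
    parameters, cells 'value ± sd' for free parameters and 'value (fixed)'
    otherwise."""
    cols = {}
    for label, fr in results.items():
        col = {}
        for k in PARAMETER_NAMES:
            if k in fr.estimates:
                col[k] = f"{fr.estimates[k]:.3g} ± {fr.stderr.get(k, float('nan')):.2g}"
            else:
                col[k] = f"{fr.fixed[k]:.3g} (fixed)"
        cols[label] = col
    return pd.DataFrame(cols).reindex(list(PARAMETER_NAMES))
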