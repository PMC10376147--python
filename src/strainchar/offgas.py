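"""Off-gas mass balances, cumulative oxygen uptake, and the biomass soft
sensor.

OUR and CPR are computed from inlet/outlet O2 and CO2 mole fractions via the
inert-gas balance (dry-gas assumption; humidity and pressure corrections are
out of scope):

    OUR = F_in/(V·V_mol) · [x_O2,in − r · x_O2,out]
    CPR = F_in/(V·V_mol) · [r · x_CO2,out − x_CO2,in]
    r   = (1 − x_O2,in − x_CO2,in) / (1 − x_O2,out − x_CO2,out)

with V_mol = 22.4 L/mol, reported in mmol/(L·h). The balances admit a closed
form inversion (used to fabricate synthetic outlet fractions).

The soft sensor follows a Luedeking–Piret-type relation between cumulative
oxygen uptake and biomass: cOUR(t) = α·(X(t) − X0) + β·∫X dt, and, when
maintenance is negligible, X_m(t) ≈ cOUR_mass(t)/α + X0 with α in g O2 per g
biomass. Working in cumulative quantities improves the signal-to-noise ratio
of the 1-min off-gas signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "OffGasRecord",
    "EstimatorParams",
    "InvalidCompositionError",
    "InfeasibleGasError",
    "V_MOL",
    "compute_our",
    "compute_cpr",
    "invert_offgas",
    "cumulative_our",
    "estimate_biomass",
    "fit_alpha_beta",
    "rmse",
]

#: molar gas volume, L/mol
V_MOL = 22.4
#: molar mass of O2, g/mol
M_O2 = 32.0


class InvalidCompositionError(ValueError):
    """Outlet composition leaves no inert fraction (denominator <= 0)."""


class InfeasibleGasError(ValueError):
    """Requested OUR/CPR has no physical outlet composition."""


@dataclass(frozen=True)
class OffGasRecord:
    """One timestamped off-gas measurement.

    Mole fractions are dimensionless (0–1). Use ``from_percent`` when the
    analyzer reports %.
    """

    t: float        # h
    F_in: float     # inlet gas flow, L/h
    V: float        # liquid volume, L
    x_O2_in: float
    x_CO2_in: float
    x_O2_out: float
    x_CO2_out: float

    def __post_init__(self) -> None:
        fr = (self.x_O2_in, self.x_CO2_in, self.x_O2_out, self.x_CO2_out)
        if not all(0.0 <= x < 1.0 for x in fr):
            raise ValueError(f"mole fractions must lie in [0, 1): {fr}")
        if self.x_O2_out + self.x_CO2_out >= 1.0:
            raise InvalidCompositionError(
                "outlet O2 + CO2 fractions leave no inert gas"
            )
        if self.F_in <= 0 or self.V <= 0:
            raise ValueError("F_in and V must be positive")

    @classmethod
    def from_percent(cls, t, F_in, V, x_O2_in, x_CO2_in, x_O2_out, x_CO2_out):
        return cls(t, F_in, V, x_O2_in / 100, x_CO2_in / 100,
                   x_O2_out / 100, x_CO2_out / 100)


@dataclass(frozen=True)
class EstimatorParams:
    """Soft-sensor coefficients: yield α [g biomass per g O2 relation, see
    below], maintenance β [g/(g·h)], and initial biomass X0 [g/L].

    α multiplies biomass increments in the cumulative relation, so it carries
    units of g O2 per g biomass (the oxygen-on-biomass yield)."""

    alpha: float
    beta: float = 0.0
    X0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0 or self.X0 < 0:
            raise ValueError("beta and X0 must be non-negative")


def _inert_ratio(rec: OffGasRecord) -> float:
    denom = 1.0 - rec.x_O2_out - rec.x_CO2_out
    if denom <= 0:
        raise InvalidCompositionError("outlet fractions sum to >= 1")
    return (1.0 - rec.x_O2_in - rec.x_CO2_in) / denom


def compute_our(rec: OffGasRecord) -> float:
    """Oxygen uptake rate, mmol O2/(L·h)."""
    c = rec.F_in / (rec.V * V_MOL)  # mol gas /(L·h)
    return 1000.0 * c * (rec.x_O2_in - _inert_ratio(rec) * rec.x_O2_out)


def compute_cpr(rec: OffGasRecord) -> float:
    """Carbon dioxide production rate, mmol CO2/(L·h)."""
    c = rec.F_in / (rec.V * V_MOL)
    return 1000.0 * c * (_inert_ratio(rec) * rec.x_CO2_out - rec.x_CO2_in)


def invert_offgas(
    our: float,
    cpr: float,
    F_in: float,
    V: float,
    x_O2_in: float = 0.2095,
    x_CO2_in: float = 0.0004,
) -> tuple[float, float]:
    """Outlet mole fractions (x_O2_out, x_CO2_out) producing the given OUR and
    CPR [mmol/(L·h)] at the given aeration.

    Closed form: with u = OUR/c, v = CPR/c (c the molar aeration rate) and
    inert inlet fraction I = 1 − x_O2,in − x_CO2,in,

        x_O2_out  = (x_O2,in − u) / (I + x_O2,in − u + x_CO2,in + v)
        x_CO2_out = (x_CO2,in + v) / (I + x_O2,in − u + x_CO2,in + v)

    which satisfies the inert balance exactly; applying the forward balances
    recovers (OUR, CPR) to machine precision.
    """
    if F_in <= 0 or V <= 0:
        raise ValueError("F_in and V must be positive")
    c = 1000.0 * F_in / (V * V_MOL)  # mmol gas /(L·h)
    u = our / c
    v = cpr / c
    inert = 1.0 - x_O2_in - x_CO2_in
    denom = inert + (x_O2_in - u) + (x_CO2_in + v)
    o2 = (x_O2_in - u) / denom
    co2 = (x_CO2_in + v) / denom
    if denom <= 0 or not (0.0 <= o2 < 1.0 and 0.0 <= co2 < 1.0) or o2 + co2 >= 1.0:
        raise InfeasibleGasError(
            f"no physical outlet composition for OUR={our}, CPR={cpr} "
            f"at F_in={F_in} L/h, V={V} L"
        )
    return float(o2), float(co2)


def cumulative_our(t: np.ndarray, our: np.ndarray) -> np.ndarray:
    """Cumulative oxygen uptake as mass, g O2/L, by trapezoidal integration
    of an OUR series in mmol/(L·h). First value is 0."""
    t = np.asarray(t, dtype=float)
    our = np.asarray(our, dtype=float)
    if t.ndim != 1 or t.shape != our.shape:
        raise ValueError("t and OUR must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    c_mmol = cumulative_trapezoid(our, t, initial=0.0)
    return c_mmol * M_O2 / 1000.0


def estimate_biomass(cour_mass: np.ndarray, est: EstimatorParams) -> np.ndarray:
    """Soft-sensor biomass X_m(t) = cOUR_mass(t)/α + X0, g/L."""
    return np.asarray(cour_mass, dtype=float) / est.alpha + est.X0


def fit_alpha_beta(
    t: np.ndarray,
    cour_mass: np.ndarray,
    X_obs: np.ndarray,
    fit_beta: bool = True,
) -> tuple[EstimatorParams, dict[str, float]]:
    """Estimate α (and optionally β) from paired cumulative-OUR / biomass
    observations.

    Ordinary least squares on cOUR(t_i) = α·(X_i − X_0) + β·∫_0^{t_i} X dt
    (the biomass integral by trapezoid on the observation grid). With
    ``fit_beta=False`` the maintenance term is dropped and α becomes the
    *effective* oxygen yield, i.e. the coefficient the maintenance-free
    estimator form should use. Returns the fitted :class:`EstimatorParams`
    (with X0 = the first observation) and standard errors.

    Note the classic caveat: under pure exponential growth ∫X dt is exactly
    proportional to X − X0, so α and β are not jointly identifiable; the
    design-rank guard rejects such data.
    """
    t = np.asarray(t, dtype=float)
    cour_mass = np.asarray(cour_mass, dtype=float)
    X_obs = np.asarray(X_obs, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    X0 = float(X_obs[0])
    dX = X_obs - X0
    if fit_beta:
        intX = cumulative_trapezoid(X_obs, t, initial=0.0)
        design = np.column_stack([dX, intX])
    else:
        design = dX[:, None]
    # rank check on the scaled design (columns can differ in magnitude)
    scale = np.linalg.norm(design, axis=0)
    if np.any(scale == 0) or np.linalg.matrix_rank(design / scale, tol=1e-6) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "degenerate design: biomass constant, or exactly exponential so "
            "that the growth and maintenance regressors are collinear"
        )
    coef, *_ = np.linalg.lstsq(design, cour_mass, rcond=None)
    alpha = float(coef[0])
    beta = float(coef[1]) if fit_beta else 0.0
    resid = cour_mass - design @ coef
    dof = max(len(t) - design.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    params = EstimatorParams(alpha=alpha, beta=max(beta, 0.0), X0=X0)
    return params, {"alpha_sd": float(sds[0]),
                    "beta_sd": float(sds[1]) if fit_beta else 0.0}


def rmse(estimated: np.ndarray, observed: np.ndarray,
         t_est: np.ndarray | None = None, t_obs: np.ndarray | None = None) -> float:
    """Root mean squared error, g/L. If both time vectors are given, the
    estimate is linearly interpolated onto the observation times first."""
    estimated = np.asarray(estimated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if t_est is not None and t_obs is not None:
        estimated = np.interp(np.asarray(t_obs, float), np.asarray(t_est, float), estimated)
    if estimated.shape != observed.shape:
        raise ValueError("series lengths differ and no time grids were given")
    return float(np.sqrt(np.mean((estimated - observed) ** 2)))


OFFGAS_COLUMNS = ["t_h", "F_in_Lh", "V_L", "xO2_in", "xCO2_in",
                  "xO2_out", "xCO2_out"]


def offgas_frame(records: list[OffGasRecord]) -> pd.DataFrame:
    """Tidy off-gas table (the CSV dialect written and read by this package)."""
    return pd.DataFrame(
        {
            "t_h": [r.t for r in records],
            "F_in_Lh": [r.F_in for r in records],
            "V_L": [r.V for r in records],
            "xO2_in": [r.x_O2_in for r in records],
            "xCO2_in": [r.x_CO2_in for r in records],
            "xO2_out": [r.x_O2_out for r in records],
            "xCO2_out": [r.x_CO2_out for r in records],
        }
    )


def write_offgas(frame: pd.DataFrame, path, units: str = "fraction") -> None:
    """Write the off-gas CSV dialect with an explicit unit flag in the header
    metadata line (mole fractions as 'fraction' or 'percent')."""
    if units not in ("fraction", "percent"):
        raise ValueError("units must be 'fraction' or 'percent'")
    out = frame.copy()
    if units == "percent":
        for c in ("xO2_in", "xCO2_in", "xO2_out", "xCO2_out"):
            out[c] = out[c] * 100.0
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        out.to_csv(fh, index=False)


def read_offgas(path) -> list[OffGasRecord]:
    """Read the off-gas CSV dialect (canonical internal form: fractions)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# units:"):
            raise ValueError("off-gas CSV must start with a '# units:' line")
        units = first.split(":", 1)[1].strip()
        frame = pd.read_csv(fh)
    if list(frame.columns) != OFFGAS_COLUMNS:
        raise ValueError(f"expected columns {OFFGAS_COLUMNS}")
    scale = 0.01 if units == "percent" else 1.0
    return [
        OffGasRecord(
            t=row.t_h, F_in=row.F_in_Lh, V=row.V_L,
            x_O2_in=row.xO2_in * scale, x_CO2_in=row.xCO2_in * scale,
            x_O2_out=row.xO2_out * scale, x_CO2_out=row.xCO2_out * scale,
        )
        for row in frame.itertuples()
    ]
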