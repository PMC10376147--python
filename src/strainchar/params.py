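"""Strain parameter sets and auxiliary model constants.

The macro-kinetic growth model is parameterised by nine strain-specific
quantities (maximum specific rates, yields, affinity and maintenance
coefficients) plus a handful of stoichiometric/physical constants that are
shared across strains and never fitted.

``STRAIN_LIBRARY`` holds published point estimates for three *E. coli* W3110
glucose-uptake knockout strains (WG = ΔptsG, WGM = ΔptsG ΔmanX,
WGP = ΔptsG ΔgalP) characterised in batch culture at initial glucose
concentrations of 5, 10 (10 mL mini-bioreactors) and 20 g/L (100 mL stirred
tanks). They serve as ground truth for synthetic campaigns and as starting
references for fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "StrainParameters",
    "AuxiliaryConstants",
    "STRAIN_LIBRARY",
    "PARAMETER_NAMES",
    "OD_TO_DCW",
    "load_parameters",
    "save_parameters",
]

#: g dry cell weight per litre per OD600 unit (configurable; optical biomass
#: readouts are converted with this factor when building initial states).
OD_TO_DCW = 0.37

#: Canonical order of the nine fittable strain parameters.
PARAMETER_NAMES = (
    "mu_max",
    "K_S",
    "q_S_max",
    "q_Ap_max",
    "q_Ac_max",
    "q_O_max",
    "q_m",
    "Y_XS_em",
    "Y_OX",
)


@dataclass(frozen=True)
class StrainParameters:
    """The nine strain-specific kinetic parameters.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate, 1/h. Acts as a hard cap on growth.
    K_S : float
        Glucose affinity (half-saturation) constant, g/L.
    q_S_max : float
        Maximum specific glucose uptake rate, g glucose/(g DCW · h).
    q_Ap_max : float
        Maximum specific acetate production rate, g/(g·h).
    q_Ac_max : float
        Maximum specific acetate consumption rate, g/(g·h).
    q_O_max : float
        Maximum specific oxygen uptake rate, g O2/(g·h).
    q_m : float
        Maintenance coefficient on glucose, g/(g·h).
    Y_XS_em : float
        Biomass-on-glucose yield excluding maintenance, g/g.
    Y_OX : float
        Oxygen-on-biomass yield, g O2 per g biomass formed.
    """

    mu_max: float
    K_S: float
    q_S_max: float
    q_Ap_max: float
    q_Ac_max: float
    q_O_max: float
    q_m: float
    Y_XS_em: float
    Y_OX: float

    #: thermodynamic sanity cap on the biomass yield (g/g); configurable.
    yield_cap: float = field(default=0.7, compare=False, repr=False)

    def __post_init__(self) -> None:
        for f in PARAMETER_NAMES:
            v = getattr(self, f)
            if not (v > 0.0):
                raise ValueError(f"StrainParameters.{f} must be strictly positive, got {v!r}")
        if self.Y_XS_em > self.yield_cap:
            raise ValueError(
                f"Y_XS_em={self.Y_XS_em} exceeds the thermodynamic bound {self.yield_cap}"
            )
        if not self.q_m < self.q_S_max:
            raise ValueError("maintenance q_m must be smaller than q_S_max")

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAMETER_NAMES}

    def replace(self, **kw: float) -> "StrainParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class AuxiliaryConstants:
    """Stoichiometric and physical constants the rate laws need but that are
    not strain-fitted.

    Defaults: Y_AS = 0.667 g/g (2 mol acetate per mol glucose, the overflow
    stoichiometric ceiling), Y_XA = 0.40 g/g biomass on acetate, K_A = 0.05 g/L
    acetate affinity, K_O = 1.0 % DOT affinity of oxygen-dependent rates,
    c_Om = 1.067 g O2 per g maintenance glucose (complete oxidation),
    K_IS = 1e6 g/L glucose inhibition of acetate uptake (effectively disabled,
    i.e. glucose/acetate co-consumption is allowed), C_O2_star = 7.2e-3 g/L
    dissolved-oxygen saturation at 37 °C.
    """

    Y_AS: float = 0.667
    Y_XA: float = 0.40
    K_A: float = 0.05
    K_O: float = 1.0
    c_Om: float = 1.067
    K_IS: float = 1.0e6
    C_O2_star: float = 7.2e-3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0.0):
                raise ValueError(f"AuxiliaryConstants.{f.name} must be positive, got {v!r}")
        if self.Y_AS > 0.667 + 1e-12:
            raise ValueError("Y_AS cannot exceed 0.667 g/g (2 mol acetate per mol glucose)")


def load_parameters(path) -> StrainParameters:
    """Read a strain parameter set from YAML or JSON (keys = the nine
    canonical field names)."""
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    raw = (json.loads(text) if str(path).endswith(".json")
           else yaml.safe_load(text))
    unknown = set(raw) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    missing = set(PARAMETER_NAMES) - set(raw)
    if missing:
        raise ValueError(f"missing parameter fields: {sorted(missing)}")
    return StrainParameters(**{k: float(raw[k]) for k in PARAMETER_NAMES})


def save_parameters(p: StrainParameters, path) -> None:
    """Write a strain parameter set to YAML or JSON, by file extension."""
    import json
    from pathlib import Path

    import yaml

    d = p.to_dict()
    out = (json.dumps(d, indent=2) if str(path).endswith(".json")
           else yaml.safe_dump(d, sort_keys=False))
    Path(path).write_text(out)


def _sp(mu, ks, qs, qap, qac, qo, qm, yxs, yox) -> StrainParameters:
    return StrainParameters(mu, ks, qs, qap, qac, qo, qm, yxs, yox)


#: Published point estimates per strain and initial glucose concentration
#: (g/L, in parentheses in the key). 5/10 g/L columns come from 10 mL MBR
#: cultivations, 20 g/L columns from 100 mL stirred tanks.
STRAIN_LIBRARY: dict[str, StrainParameters] = {
    "WG(5)":   _sp(0.55, 0.010, 1.12, 0.10, 0.07, 0.79, 0.047, 0.53, 1.43),
    "WG(10)":  _sp(0.62, 0.009, 1.13, 0.10, 0.07, 0.91, 0.056, 0.56, 1.49),
    "WGP(5)":  _sp(0.46, 0.011, 0.98, 0.05, 0.06, 0.67, 0.044, 0.49, 1.45),
    "WGP(10)": _sp(0.45, 0.010, 0.97, 0.04, 0.06, 0.66, 0.047, 0.49, 1.47),
    "WGM(5)":  _sp(0.41, 0.010, 0.87, 0.13, 0.06, 0.62, 0.044, 0.50, 1.46),
    "WGM(10)": _sp(0.47, 0.011, 0.98, 0.08, 0.07, 0.68, 0.044, 0.51, 1.45),
    "WG(20)":  _sp(0.44, 0.010, 1.03, 0.06, 0.08, 0.55, 0.044, 0.45, 1.25),
    "WGP(20)": _sp(0.36, 0.010, 0.98, 0.06, 0.0708, 0.41, 0.044, 0.39, 1.24),
}

#: Reported standard uncertainties accompanying STRAIN_LIBRARY (same keys);
#: used only for display/reference, never inside the model.
STRAIN_LIBRARY_SD: dict[str, dict[str, float]] = {
    "WG(5)":   dict(mu_max=0.06, K_S=0.002, q_S_max=0.01, q_Ap_max=0.01, q_Ac_max=0.00,
                    q_O_max=0.01, q_m=0.002, Y_XS_em=0.06, Y_OX=0.01),
    "WG(10)":  dict(mu_max=0.09, K_S=0.002, q_S_max=0.01, q_Ap_max=0.01, q_Ac_max=0.01,
                    q_O_max=0.01, q_m=0.004, Y_XS_em=0.08, Y_OX=0.01),
    "WGP(5)":  dict(mu_max=0.04, K_S=0.002, q_S_max=0.01, q_Ap_max=0.00, q_Ac_max=0.00,
                    q_O_max=0.01, q_m=0.003, Y_XS_em=0.04, Y_OX=0.01),
    "WGP(10)": dict(mu_max=0.04, K_S=0.002, q_S_max=0.01, q_Ap_max=0.00, q_Ac_max=0.01,
                    q_O_max=0.01, q_m=0.004, Y_XS_em=0.05, Y_OX=0.01),
    "WGM(5)":  dict(mu_max=0.03, K_S=0.002, q_S_max=0.01, q_Ap_max=0.01, q_Ac_max=0.01,
                    q_O_max=0.01, q_m=0.004, Y_XS_em=0.04, Y_OX=0.01),
    "WGM(10)": dict(mu_max=0.05, K_S=0.002, q_S_max=0.01, q_Ap_max=0.01, q_Ac_max=0.00,
                    q_O_max=0.01, q_m=0.003, Y_XS_em=0.05, Y_OX=0.01),
    "WG(20)":  dict(mu_max=0.03, K_S=0.002, q_S_max=0.01, q_Ap_max=0.01, q_Ac_max=0.00,
                    q_O_max=0.01, q_m=0.002, Y_XS_em=0.03, Y_OX=0.01),
    "WGP(20)": dict(mu_max=0.02, K_S=0.002, q_S_max=0.01, q_Ap_max=0.01, q_Ac_max=0.00,
                    q_O_max=0.01, q_m=0.003, Y_XS_em=0.02, Y_OX=0.01),
}
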