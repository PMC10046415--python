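"""Complex permittivity of biological tissues versus frequency and temperature.

Tissues are modelled with a two-pole Cole-Cole dispersion plus a static
conductivity term,

    eps_r(w, T) = eps_inf + d_eps1 / (1 + (j w tau1)^(1-alpha1))
                          + d_eps2 / (1 + (j w tau2)^(1-alpha2))
                          + sigma / (j w eps0),

under the e^{jwt} time convention, so eps_r = eps' - j eps'' with eps'' >= 0
for passive media.  Temperature enters through per-parameter linear relative
rates referenced to 37 degC (normothermia), applied to heat-sensitive tissues
(tumor, spinal cord) during treatment.

The contrast function chi = eps_r / eps_rb - 1 normalises a tissue's
permittivity to the immersion (background) medium; it is the quantity the
scattering equations see.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from importlib import resources
from typing import NamedTuple

__all__ = [
    "EPS0",
    "MU0",
    "C0",
    "ColeColeParams",
    "TemperatureCoefficients",
    "ComplexPermittivity",
    "cole_cole",
    "params_at_temperature",
    "contrast",
    "load_tissue_table",
    "TissueEntry",
]

#: Vacuum permittivity [F/m] (CODATA).
EPS0 = 8.8541878128e-12
#: Vacuum permeability [H/m].
MU0 = 4.0e-7 * math.pi
#: Speed of light in vacuum [m/s].
C0 = 1.0 / math.sqrt(EPS0 * MU0)

#: Reference (physiological) temperature [degC].
T_REF = 37.0


@dataclass(frozen=True)
class ColeColeParams:
    """Two-pole Cole-Cole dispersion parameters of one tissue at 37 degC.

    Parameters
    ----------
    eps_inf : float
        Permittivity at infinite frequency (dimensionless, >= 1).
    delta_eps1, delta_eps2 : float
        Dispersion amplitudes (dimensionless, >= 0).
    tau1, tau2 : float
        Relaxation times [s], > 0.
    alpha1, alpha2 : float
        Dispersion broadening exponents, in [0, 1).
    sigma : float
        Static ionic conductivity [S/m], >= 0.
    """

    eps_inf: float
    delta_eps1: float
    delta_eps2: float
    tau1: float
    tau2: float
    alpha1: float
    alpha2: float
    sigma: float

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.delta_eps1 < 0 or self.delta_eps2 < 0:
            raise ValueError("dispersion amplitudes must be non-negative")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("relaxation times must be positive")
        for a in (self.alpha1, self.alpha2):
            if not 0.0 <= a < 1.0:
                raise ValueError(f"alpha must lie in [0, 1), got {a}")
        if self.sigma < 0:
            raise ValueError("conductivity must be non-negative")


@dataclass(frozen=True)
class TemperatureCoefficients:
    """Linear relative rate of change per degC of each Cole-Cole parameter.

    Parameter p at temperature T becomes ``p * (1 + c_p * (T - 37))``.
    All-zero coefficients describe a temperature-insensitive tissue.
    """

    eps_inf: float = 0.0
    delta_eps1: float = 0.0
    delta_eps2: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    sigma: float = 0.0


class ComplexPermittivity(NamedTuple):
    """Relative complex permittivity eps_r = eps' - j eps'' (e^{jwt})."""

    eps_prime: float
    eps_double_prime: float

    def to_complex(self) -> complex:
        return self.eps_prime - 1j * self.eps_double_prime

    @classmethod
    def from_complex(cls, z: complex) -> "ComplexPermittivity":
        return cls(z.real, -z.imag)


def cole_cole(params: ColeColeParams, f: float, eps0: float = EPS0) -> ComplexPermittivity:
    """Evaluate the two-pole Cole-Cole model at frequency ``f`` [Hz].

    The fractional exponent ``(1 - alpha)`` on ``j w tau`` is taken on the
    principal branch.  ``eps0`` is configurable for bit-matching experiments
    against sources that use a rounded vacuum permittivity.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    w = 2.0 * math.pi * f
    eps = complex(params.eps_inf)
    for d_eps, tau, alpha in (
        (params.delta_eps1, params.tau1, params.alpha1),
        (params.delta_eps2, params.tau2, params.alpha2),
    ):
        if d_eps != 0.0:
            eps += d_eps / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    if params.sigma != 0.0:
        eps += params.sigma / (1j * w * eps0)
    return ComplexPermittivity(eps.real, max(-eps.imag, 0.0))


def params_at_temperature(
    base: ColeColeParams,
    coeffs: TemperatureCoefficients,
    T: float,
    window: tuple[float, float] = (37.0, 46.0),
) -> ColeColeParams:
    """Scale each Cole-Cole parameter linearly with temperature.

    Each parameter p becomes ``p * (1 + c_p * (T - 37))``; at T = 37 degC the
    base parameters are returned unchanged.  ``T`` must lie inside the
    configured validity window of the linear model.
    """
    lo, hi = window
    if not lo <= T <= hi:
        raise ValueError(f"temperature {T} degC outside validity window [{lo}, {hi}]")
    dT = T - T_REF
    if dT == 0.0:
        return base
    updates = {}
    for fld in fields(ColeColeParams):
        c = getattr(coeffs, fld.name)
        if c != 0.0:
            updates[fld.name] = getattr(base, fld.name) * (1.0 + c * dT)
    return replace(base, **updates) if updates else base


def contrast(eps: complex | ComplexPermittivity, eps_background: complex | ComplexPermittivity) -> complex:
    """Contrast function chi = eps_r / eps_rb - 1 of a tissue in the background."""
    if isinstance(eps, ComplexPermittivity):
        eps = eps.to_complex()
    if isinstance(eps_background, ComplexPermittivity):
        eps_background = eps_background.to_complex()
    if eps_background == 0:
        raise ValueError("background permittivity must be non-zero")
    return eps / eps_background - 1.0


@dataclass(frozen=True)
class TissueEntry:
    """One tissue's dispersion parameters and temperature sensitivity."""

    name: str
    params: ColeColeParams
    coeffs: TemperatureCoefficients


def load_tissue_table(path: str | None = None) -> dict[str, TissueEntry]:
    """Load the tissue dielectric table (bundled JSON by default).

    Schema: ``{"tissues": {<name>: {"cole_cole": {<8 fields>},
    "temperature_coefficients": {<subset of the 8 fields>}}}}``.
    """
    if path is None:
        text = resources.files("thermowave.data").joinpath("tissue_table.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    table: dict[str, TissueEntry] = {}
    for name, entry in raw["tissues"].items():
        params = ColeColeParams(**entry["cole_cole"])
        coeffs = TemperatureCoefficients(**entry.get("temperature_coefficients", {}))
        table[name] = TissueEntry(name=name, params=params, coeffs=coeffs)
    return table
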