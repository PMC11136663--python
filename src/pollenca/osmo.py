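"""Water-potential and osmolarity arithmetic.

The water potential of a solution decomposes as

    psi_w = psi_s + psi_p + psi_m        (all in MPa)

where ``psi_s`` is the solute (osmotic) component, ``psi_p`` the hydrostatic
pressure (turgor) component and ``psi_m`` the matric component.  The solute
component follows the van't Hoff relation

    psi_s = -i * C * R * T

with ``i`` the dimensionless ionization (van't Hoff) factor, ``C`` the osmotic
concentration in osmol L^-1, ``R`` the pressure-form gas constant and ``T`` the
absolute temperature.  Osmolarity is accepted in mOsm (mosmol L^-1), the unit
vapour-pressure osmometers report, and divided by 1000 internally.

With the defaults (i = 1, T = 298.15 K) a 1,800 mOsm medium has
psi_s = -4.46 MPa and a 12 mOsm medium -0.0297 MPa, spanning the roughly
150-fold osmolarity range a germinating pollen grain may encounter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

#: Gas constant in pressure form, L MPa mol^-1 K^-1.
R_MPA = 0.008314

#: Default absolute temperature (25 degC) used when none is given.
DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class OsmoCondition:
    """One osmotic condition: concentration, temperature and ionization factor.

    Parameters
    ----------
    osmolarity_mosm:
        Osmotically effective concentration in mOsm (>= 0).
    temperature_k:
        Absolute temperature in kelvin (> 0).
    ionization_i:
        van't Hoff factor (>= 1).  Defaults to 1 because an osmolarity already
        counts dissociated particles.
    """

    osmolarity_mosm: float
    temperature_k: float = DEFAULT_TEMPERATURE_K
    ionization_i: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.osmolarity_mosm) or self.osmolarity_mosm < 0:
            raise InvalidInputError(f"osmolarity must be >= 0 mOsm, got {self.osmolarity_mosm}")
        if not math.isfinite(self.temperature_k) or self.temperature_k <= 0:
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature_k}")
        if not math.isfinite(self.ionization_i) or self.ionization_i < 1:
            raise InvalidInputError(f"ionization factor must be >= 1, got {self.ionization_i}")


@dataclass(frozen=True)
class WaterPotential:
    """Water potential and its three components, all in MPa."""

    psi_s: float
    psi_p: float
    psi_m: float
    psi_w: float

    def __post_init__(self) -> None:
        if abs(self.psi_w - (self.psi_s + self.psi_p + self.psi_m)) > 1e-9:
            raise InvalidInputError("psi_w must equal psi_s + psi_p + psi_m")
        if self.psi_s > 0:
            raise InvalidInputError("solute potential cannot be positive")


def solute_potential(
    cond: OsmoCondition | float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    ionization_i: float = 1.0,
) -> float:
    """Solute (osmotic) potential in MPa via the van't Hoff relation -iCRT.

    ``cond`` may be an :class:`OsmoCondition` or a bare osmolarity in mOsm,
    in which case ``temperature_k`` and ``ionization_i`` apply.
    """
    if not isinstance(cond, OsmoCondition):
        cond = OsmoCondition(float(cond), temperature_k, ionization_i)
    c_osmol_per_l = cond.osmolarity_mosm / 1000.0
    return -cond.ionization_i * c_osmol_per_l * R_MPA * cond.temperature_k


def water_potential(psi_s: float, psi_p: float = 0.0, psi_m: float = 0.0) -> WaterPotential:
    """Assemble a :class:`WaterPotential` from its components (psi_w = sum)."""
    for name, v in (("psi_s", psi_s), ("psi_p", psi_p), ("psi_m", psi_m)):
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v}")
    return WaterPotential(psi_s, psi_p, psi_m, psi_s + psi_p + psi_m)


def fold_range(min_mosm: float, max_mosm: float) -> float:
    """Fold difference max/min between two osmolarities (dimensionless)."""
    if not math.isfinite(min_mosm) or min_mosm <= 0:
        raise InvalidInputError(f"minimum osmolarity must be > 0, got {min_mosm}")
    if not math.isfinite(max_mosm) or max_mosm < min_mosm:
        raise InvalidInputError("maximum osmolarity must be >= minimum")
    return max_mosm / min_mosm
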