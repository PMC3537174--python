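"""Wind-driven air-water CO2 exchange.

The areal flux between atmosphere and lake is

    fCO2 = k_x * K_H * (pCO2atm - pCO2w)      [mmol C m**-2 d**-1]

with the transfer velocity k_x obtained by rescaling the wind-based k600
(Cole-Caraco power law) to the CO2 Schmidt number at the in-situ
temperature:

    k600 = 2.07 + 0.215 * U10**1.7            [cm h**-1]
    k_x  = k600 * (Sc/600)**(-x)

where x = 0.66 for winds at or below 3.0 m s**-1 and 0.5 above, and
Sc(T) is the Wanninkhof cubic for CO2 in fresh water.  K_H(T) supplies the
solubility needed to turn a partial-pressure difference into a molar flux.

Positive flux = net invasion (atmosphere to lake); negative = net efflux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .carbonate import ValidityWarning, henry_constant
from .constants import CELSIUS_TO_KELVIN, PCO2_ATM_DEFAULT

__all__ = [
    "GasExchangeResult",
    "schmidt_number",
    "k600_wind",
    "wind_exponent",
    "transfer_velocity",
    "co2_flux",
    "air_water_exchange",
]

#: Wind speed (m s**-1) at which the Schmidt exponent switches regimes.
WIND_EXPONENT_SWITCH = 3.0


@dataclass(frozen=True)
class GasExchangeResult:
    """One air-water exchange computation.

    schmidt: CO2 Schmidt number (dimensionless); k600 and kx in cm h**-1;
    exponent_x the Schmidt exponent actually used (0.66 or 0.5); fco2 in
    mmol C m**-2 d**-1 (positive = into the lake); pco2_atm in μatm.
    """

    schmidt: float
    k600: float
    kx: float
    exponent_x: float
    fco2: float
    pco2_atm: float


def schmidt_number(temperature_c):
    """CO2 Schmidt number in fresh water at `temperature_c` (degC).

    Cubic fit Sc = 1911.1 - 118.11 T + 3.4527 T^2 - 0.04132 T^3, normalized
    so that Sc ~ 600 at 20 degC.  Outside 0-35 degC a ValidityWarning is
    issued and the polynomial is still evaluated.
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any((t < 0.0) | (t > 35.0)):
        warnings.warn(
            "temperature outside the 0-35 degC Schmidt-number fit window",
            ValidityWarning,
            stacklevel=2,
        )
    sc = 1911.1 - 118.11 * t + 3.4527 * t**2 - 0.04132 * t**3
    return float(sc) if np.isscalar(temperature_c) else sc


def k600_wind(u10):
    """k600 (cm h**-1) from wind speed at 10 m (m s**-1): 2.07 + 0.215 U10^1.7."""
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    k = 2.07 + 0.215 * u**1.7
    return float(k) if np.isscalar(u10) else k


def wind_exponent(u10: float) -> float:
    """Schmidt exponent x: 0.66 for U10 <= 3.0 m s**-1, else 0.5.

    Winds of exactly 3.0 m s**-1 take the low-wind exponent for continuity
    with the smooth-surface regime.
    """
    return 0.66 if u10 <= WIND_EXPONENT_SWITCH else 0.5


def transfer_velocity(temperature_c: float, u10: float) -> float:
    """Gas transfer velocity k_x (cm h**-1) for CO2 at the given
    temperature and wind speed: k600 * (Sc/600)**(-x)."""
    sc = schmidt_number(temperature_c)
    x = wind_exponent(u10)
    return k600_wind(u10) * (sc / 600.0) ** (-x)


def air_water_exchange(
    pco2_water: float,
    temperature_c: float,
    u10: float,
    pco2_atm: float = PCO2_ATM_DEFAULT,
) -> GasExchangeResult:
    """Full air-water CO2 exchange computation for one sample.

    Unit chain for the flux: k_x [cm h**-1] * 0.24 -> m d**-1;
    K_H [mol L**-1 atm**-1] * 1000 -> mol m**-3 atm**-1;
    (pCO2atm - pCO2w) [μatm] * 1e-6 -> atm; mol * 1000 -> mmol.
    The factors collapse to fco2 = 0.24 * k_x * K_H * Δp(μatm).
    """
    sc = schmidt_number(temperature_c)
    k6 = k600_wind(u10)
    x = wind_exponent(u10)
    kx = k6 * (sc / 600.0) ** (-x)
    kh = henry_constant(temperature_c + CELSIUS_TO_KELVIN)
    fco2 = 0.24 * kx * kh * (pco2_atm - pco2_water)
    return GasExchangeResult(
        schmidt=sc, k600=k6, kx=kx, exponent_x=x, fco2=fco2, pco2_atm=pco2_atm
    )


def co2_flux(
    pco2_water: float,
    temperature_c: float,
    u10: float,
    pco2_atm: float = PCO2_ATM_DEFAULT,
) -> float:
    """Air-water CO2 flux, mmol C m**-2 d**-1 (positive = into the lake)."""
    return air_water_exchange(pco2_water, temperature_c, u10, pco2_atm).fco2
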