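"""Carbonate-system chemistry for dilute fresh waters.

Computes ionic strength from conductivity, CO2 solubility (Henry's law),
the carbonic-acid dissociation constants corrected for temperature and
ionic strength, the fraction of dissolved inorganic carbon (DIC) present
as free CO2 (alpha_0), and from these the equilibrium partial pressure of
CO2 in the water column (pCO2w, μatm).

The chain is

    pCO2w = alpha_0 * DIC / K_H

with DIC in mol C L**-1 and K_H in mol L**-1 atm**-1.  alpha_0 follows
from pH and the two apparent dissociation constants:

    alpha_0 = 1 / (1 + K1'/{H+} + K1'K2'/{H+}**2)

Thermodynamic K1/K2 use the Plummer & Busenberg (1982) freshwater
temperature functions (valid 0-50 degC); the Davies equation converts them
to apparent constants at the sample ionic strength (valid to IS ~0.1 M).
pH is taken as the activity of H+ directly, as delivered by a calibrated
potentiometric electrode.

Scalar floats in, scalar floats out, except where noted; `henry_constant`
and the alpha functions also accept numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import CELSIUS_TO_KELVIN, MOLAR_MASS_C

__all__ = [
    "CarbonateConstants",
    "CarbonateState",
    "ValidityWarning",
    "ionic_strength",
    "henry_constant",
    "equilibrium_constants",
    "alpha0",
    "alpha_fractions",
    "carbonate_state",
    "pco2_water",
]

#: Debye-Hückel limiting slope at 25 degC, used by the Davies equation.
DAVIES_A = 0.509

#: Conversion factor from conductivity (μS cm**-1) to ionic strength (mol L**-1)
#: for dilute natural waters (Snoeyink-Jenkins approximation).
IONIC_STRENGTH_PER_USCM = 1.6e-5


class ValidityWarning(UserWarning):
    """An input fell outside the documented validity window; the result is
    still computed but should be interpreted with care."""


@dataclass(frozen=True)
class CarbonateConstants:
    """Equilibrium constants for one water sample.

    Attributes
    ----------
    temperature_k : float
        Absolute temperature, K.
    ionic_strength : float
        Ionic strength, mol L**-1.
    k1, k2 : float
        First and second apparent dissociation constants of carbonic acid
        (molar concentration scale, H+ on the activity scale).
    kh : float
        CO2 solubility (Henry) constant, mol L**-1 atm**-1.
    """

    temperature_k: float
    ionic_strength: float
    k1: float
    k2: float
    kh: float


@dataclass(frozen=True)
class CarbonateState:
    """Speciation of one sample: ionic strength, the CO2 fraction of DIC,
    DIC and free CO2 in mol L**-1, and the equilibrium pCO2 in μatm."""

    ionic_strength: float
    alpha0: float
    dic: float
    co2_aq: float
    pco2_water: float


def ionic_strength(conductivity: float) -> float:
    """Ionic strength (mol L**-1) from electrical conductivity (μS cm**-1).

    Uses the dilute-water approximation IS = 1.6e-5 * conductivity.
    """
    if conductivity < 0:
        raise ValueError(f"conductivity must be >= 0, got {conductivity!r}")
    return IONIC_STRENGTH_PER_USCM * conductivity


def henry_constant(temperature_k):
    """CO2 solubility K_H (mol L**-1 atm**-1) at `temperature_k` (K).

    Weiss-type fit for fresh water (zero salinity):

        ln K_H = -58.0931 + 90.5069 (100/Tk) + 22.294 ln(Tk/100)

    Temperatures outside (270, 320) K raise a :class:`ValidityWarning` but
    are still evaluated.
    """
    tk = np.asarray(temperature_k, dtype=float)
    if np.any((tk <= 270.0) | (tk >= 320.0)):
        warnings.warn(
            "temperature outside the 270-320 K validity window of the "
            "CO2 solubility fit",
            ValidityWarning,
            stacklevel=2,
        )
    ln_kh = -58.0931 + 90.5069 * (100.0 / tk) + 22.294 * np.log(tk / 100.0)
    out = np.exp(ln_kh)
    return float(out) if np.isscalar(temperature_k) else out


def _log10_k1_freshwater(tk: float) -> float:
    # Plummer & Busenberg (1982) fit, T in kelvin, valid 0-50 degC.
    return (
        -356.3094
        - 0.06091964 * tk
        + 21834.37 / tk
        + 126.8339 * np.log10(tk)
        - 1684915.0 / tk**2
    )


def _log10_k2_freshwater(tk: float) -> float:
    return (
        -107.8871
        - 0.03252849 * tk
        + 5151.79 / tk
        + 38.92561 * np.log10(tk)
        - 563713.9 / tk**2
    )


def davies_log_gamma(charge: int, is_molar: float, a: float = DAVIES_A) -> float:
    """log10 of the single-ion activity coefficient from the Davies equation.

    log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I).  Returns 0 at I = 0.
    """
    if is_molar == 0.0:
        return 0.0
    root = np.sqrt(is_molar)
    return -a * charge**2 * (root / (1.0 + root) - 0.3 * is_molar)


def equilibrium_constants(
    temperature_c: float, ionic_strength: float = 0.0
) -> CarbonateConstants:
    """Apparent K1, K2 and K_H for a sample at `temperature_c` (degC) and
    `ionic_strength` (mol L**-1).

    Thermodynamic constants come from the Plummer-Busenberg freshwater
    temperature functions; the Davies equation (A = 0.509) converts them to
    apparent constants.  With pH read as H+ activity and the neutral CO2
    species assigned unit activity coefficient:

        K1' = K1 / gamma_1        (gamma_1: monovalent ions)
        K2' = K2 * gamma_1 / gamma_2

    At zero ionic strength the correction is the identity.

    Raises
    ------
    ValueError
        If ionic strength exceeds 0.1 mol L**-1, outside the Davies range.
    """
    if not (0.0 <= temperature_c <= 40.0):
        warnings.warn(
            f"temperature {temperature_c} degC outside the 0-40 degC window",
            ValidityWarning,
            stacklevel=2,
        )
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength > 0.1:
        raise ValueError(
            f"ionic strength {ionic_strength} mol/L exceeds 0.1, beyond the "
            "validity of the Davies activity correction"
        )
    tk = temperature_c + CELSIUS_TO_KELVIN
    k1 = 10.0 ** _log10_k1_freshwater(tk)
    k2 = 10.0 ** _log10_k2_freshwater(tk)
    lg1 = davies_log_gamma(1, ionic_strength)
    lg2 = davies_log_gamma(2, ionic_strength)
    k1_app = k1 / 10.0**lg1
    k2_app = k2 * 10.0**lg1 / 10.0**lg2
    return CarbonateConstants(
        temperature_k=tk,
        ionic_strength=ionic_strength,
        k1=k1_app,
        k2=k2_app,
        kh=henry_constant(tk),
    )


def alpha_fractions(ph, constants: CarbonateConstants):
    """Fractions of DIC as (CO2*, HCO3-, CO3--) at the given pH.

    The three fractions sum to one by construction.
    """
    h = 10.0 ** (-np.asarray(ph, dtype=float))
    denom = 1.0 + constants.k1 / h + constants.k1 * constants.k2 / h**2
    a0 = 1.0 / denom
    a1 = (constants.k1 / h) * a0
    a2 = (constants.k1 * constants.k2 / h**2) * a0
    if np.isscalar(ph):
        return float(a0), float(a1), float(a2)
    return a0, a1, a2


def alpha0(ph, constants: CarbonateConstants):
    """Fraction of DIC present as free CO2 at the given pH; in (0, 1]."""
    ph_arr = np.asarray(ph, dtype=float)
    if np.any((ph_arr < 2.0) | (ph_arr > 12.0)):
        warnings.warn(
            "pH outside the 2-12 window", ValidityWarning, stacklevel=2
        )
    return alpha_fractions(ph, constants)[0]


def carbonate_state(
    dic_mg_c_l: float,
    ph: float,
    temperature_c: float,
    conductivity: float,
) -> CarbonateState:
    """Full speciation of one sample from field measurements.

    Parameters
    ----------
    dic_mg_c_l : float
        Dissolved inorganic carbon, mg C L**-1 (must be positive).
    ph : float
        Potentiometric pH (activity scale).
    temperature_c : float
        Water temperature, degC.
    conductivity : float
        Electrical conductivity, μS cm**-1.
    """
    if dic_mg_c_l <= 0:
        raise ValueError(f"DIC must be positive, got {dic_mg_c_l!r}")
    is_ = ionic_strength(conductivity)
    consts = equilibrium_constants(temperature_c, is_)
    a0 = alpha0(ph, consts)
    dic_mol = dic_mg_c_l / MOLAR_MASS_C / 1000.0  # mg C/L -> mol C/L
    co2_aq = a0 * dic_mol
    pco2 = co2_aq / consts.kh * 1.0e6  # atm -> μatm
    return CarbonateState(
        ionic_strength=is_,
        alpha0=a0,
        dic=dic_mol,
        co2_aq=co2_aq,
        pco2_water=pco2,
    )


def pco2_water(
    dic_mg_c_l: float, ph: float, temperature_c: float, conductivity: float
) -> float:
    """Equilibrium water pCO2 (μatm) from DIC, pH, temperature and
    conductivity.  Convenience wrapper around :func:`carbonate_state`."""
    return carbonate_state(dic_mg_c_l, ph, temperature_c, conductivity).pco2_water
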