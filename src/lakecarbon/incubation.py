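"""Respiration and CO2 accumulation from dark-bottle incubations.

Dark incubations suppress photosynthesis, so the decline in dissolved O2
and the build-up of free CO2 over the incubation measure community
respiration.  Rates are linear two-point estimates (start vs end), which
assumes respiration is constant over the incubation.

Oxygen consumption converts to carbon respired with an O2:CO2 molar
conversion factor of 1.0 (respiratory quotient), i.e.

    rate_C [μg C L**-1 h**-1] = ΔO2/Δt [mg O2 L**-1 h**-1]
                                / 31.998 * 1.0 * 12.011 * 1000

CO2 accumulation is obtained indirectly from DIC and pH at the two
endpoints via the carbonate-system speciation (free CO2 = alpha_0 * DIC at
the incubation temperature and sample ionic strength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbonate import alpha0, equilibrium_constants, ionic_strength
from .constants import (
    MOLAR_CONVERSION_O2_TO_C,
    MOLAR_MASS_C,
    MOLAR_MASS_CO2,
    MOLAR_MASS_O2,
)

__all__ = [
    "IncubationSeries",
    "RespirationRate",
    "CO2Accumulation",
    "o2_consumption_rate",
    "co2_accumulation",
    "dic_accumulation_summary",
]

#: Default dark-incubation temperature (thermal box), degC.
DEFAULT_INCUBATION_TEMPERATURE_C = 23.0

#: μg C per mg O2 at a molar conversion factor of 1.0.
UG_C_PER_MG_O2 = MOLAR_CONVERSION_O2_TO_C * MOLAR_MASS_C / MOLAR_MASS_O2 * 1000.0


@dataclass
class IncubationSeries:
    """One dark-bottle incubation.

    Start/end O2 in mg O2 L**-1, DIC in mg C L**-1, pH in pH units,
    duration in hours.  `time_course` optionally holds (time_h, dic mg C/L)
    pairs for multi-day DIC-accumulation experiments.
    """

    sample_id: str
    zone: str | None = None
    temperature_c: float = DEFAULT_INCUBATION_TEMPERATURE_C
    conductivity: float = 0.0
    duration_h: float = 120.0
    o2_start: float | None = None
    o2_end: float | None = None
    dic_start: float | None = None
    dic_end: float | None = None
    ph_start: float | None = None
    ph_end: float | None = None
    time_course: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("incubation duration must be positive")
        for name in ("o2_start", "o2_end", "dic_start", "dic_end"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        times = [t for t, _ in self.time_course]
        if times and not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("time-course times must be strictly increasing")


@dataclass(frozen=True)
class RespirationRate:
    """Two-point respiration rate on both measurement bases."""

    o2_rate_mg_l_h: float
    carbon_rate_ug_l_h: float
    o2_consumed_mg_l: float
    duration_h: float


@dataclass(frozen=True)
class CO2Accumulation:
    """Change in free CO2 over an incubation, on both mass conventions."""

    delta_co2_mg_co2_l: float
    delta_co2_mg_c_l: float
    co2_start_mg_c_l: float
    co2_end_mg_c_l: float


def o2_consumption_rate(series: IncubationSeries) -> RespirationRate:
    """Respiration rate from start/end dissolved O2.

    Returns the oxygen-basis rate (mg O2 L**-1 h**-1) and the carbon-basis
    rate (μg C L**-1 h**-1).  If O2 increased during the dark incubation the
    rate is returned negative with a warning — net production in the dark
    indicates a measurement problem and is never silently clipped.
    """
    if series.o2_start is None or series.o2_end is None:
        raise ValueError("o2_start and o2_end are required")
    consumed = series.o2_start - series.o2_end
    if consumed < 0:
        warnings.warn(
            f"sample {series.sample_id}: O2 increased during dark incubation "
            "(apparent net production); returning a negative rate",
            UserWarning,
            stacklevel=2,
        )
    o2_rate = consumed / series.duration_h
    carbon_rate = o2_rate * UG_C_PER_MG_O2
    return RespirationRate(
        o2_rate_mg_l_h=o2_rate,
        carbon_rate_ug_l_h=carbon_rate,
        o2_consumed_mg_l=consumed,
        duration_h=series.duration_h,
    )


def _free_co2_mg_c(dic_mg_c_l: float, ph: float, temperature_c: float,
                   conductivity: float) -> float:
    consts = equilibrium_constants(temperature_c, ionic_strength(conductivity))
    return alpha0(ph, consts) * dic_mg_c_l


def co2_accumulation(series: IncubationSeries) -> CO2Accumulation:
    """Change in free CO2 between incubation endpoints.

    CO2 at each endpoint is alpha_0(pH, T, IS) * DIC evaluated at the
    incubation temperature and the sample's ionic strength; the difference
    end - start is reported both as mg CO2 L**-1 and mg C L**-1.
    """
    if series.ph_start is None or series.ph_end is None:
        raise ValueError("pH at both endpoints is required")
    if series.dic_start is None or series.dic_end is None:
        raise ValueError("DIC at both endpoints is required")
    start = _free_co2_mg_c(
        series.dic_start, series.ph_start, series.temperature_c, series.conductivity
    )
    end = _free_co2_mg_c(
        series.dic_end, series.ph_end, series.temperature_c, series.conductivity
    )
    delta_c = end - start
    return CO2Accumulation(
        delta_co2_mg_co2_l=delta_c * MOLAR_MASS_CO2 / MOLAR_MASS_C,
        delta_co2_mg_c_l=delta_c,
        co2_start_mg_c_l=start,
        co2_end_mg_c_l=end,
    )


def dic_accumulation_summary(
    observations: pd.DataFrame,
    time_col: str = "time_h",
    value_col: str = "dic",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Replicate-wise summary of a DIC accumulation time course.

    `observations` holds one row per vial with a retrieval time, a DIC
    value, and optionally a treatment/group column.  Returns a table with
    per-time (and per-group) mean, sample SD (NaN for single replicates)
    and n, plus an ``overall`` row per group pooling all retrievals — the
    form consumed by the permutation tests for zone and time effects.
    """
    if observations[time_col].nunique() < 2:
        raise ValueError("need at least two distinct time points")
    keys = [group_col, time_col] if group_col else [time_col]
    per_time = (
        observations.groupby(keys, sort=True)[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    pool_keys = [group_col] if group_col else []
    if pool_keys:
        pooled = (
            observations.groupby(pool_keys, sort=True)[value_col]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
        )
    else:
        v = observations[value_col]
        pooled = pd.DataFrame(
            {"mean": [v.mean()], "sd": [v.std(ddof=1)], "n": [v.count()]}
        )
    pooled[time_col] = "overall"
    return pd.concat([per_time, pooled], ignore_index=True)
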