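"""Synthetic limnological data with the structure the analysis assumes.

Emulates the field design of a subtropical shallow-lake monitoring
program: 19 stations (12 littoral within 1 km of shore, 7 pelagic beyond)
visited in seven campaigns over two years, each visit yielding a row of
water-chemistry and optical measurements plus wind speed, and dark-bottle
incubations yielding O2 consumption and CO2 accumulation.

Per-zone means and SDs of the chemical/optical variables default to the
whole-period littoral vs pelagic summaries of the emulated survey (e.g.
chlorophyll a 3.03 ± 1.09 μg/L littoral vs 3.89 ± 1.49 pelagic, DOC
1.89 ± 1.23 vs 2.38 ± 1.51 mg/L).  Variables are drawn independently per
station-month from zero-truncated Gaussians (resample-on-negative), which
approximately preserves the arithmetic mean ± SD at these coefficients of
variation.  The Abs250:365 ratio is always computed from the drawn
absorbances, never drawn itself.  An optional shared month intercept
introduces between-campaign structure; an optional Gaussian copula induces
predictor correlation for tree-sensitivity studies.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .incubation import IncubationSeries, UG_C_PER_MG_O2

__all__ = [
    "ZoneStats",
    "GeneratorConfig",
    "ZONE_VARIABLE_DEFAULTS",
    "DEFAULT_MONTHS",
    "generate_station_table",
    "generate_incubation_series",
    "generate_dic_experiment",
    "generate_null_dataset",
]


@dataclass(frozen=True)
class ZoneStats:
    """Mean ± SD of one variable in one zone."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be >= 0")
        if self.sd > 0 and self.mean < -5.0 * self.sd:
            raise ValueError(
                f"mean {self.mean} more than 5 SD below zero: zero-truncated "
                "sampling is infeasible"
            )


# Whole-period per-zone summaries of the emulated monitoring survey.
ZONE_VARIABLE_DEFAULTS: dict[str, dict[str, ZoneStats]] = {
    "ph": {"littoral": ZoneStats(7.83, 0.28), "pelagic": ZoneStats(7.84, 0.27)},
    "abs250": {
        "littoral": ZoneStats(0.093, 0.033),
        "pelagic": ZoneStats(0.086, 0.021),
    },
    "abs365": {
        "littoral": ZoneStats(0.016, 0.008),
        "pelagic": ZoneStats(0.017, 0.008),
    },
    "tp": {"littoral": ZoneStats(0.033, 0.020), "pelagic": ZoneStats(0.037, 0.018)},
    "tn": {"littoral": ZoneStats(0.33, 0.14), "pelagic": ZoneStats(0.35, 0.16)},
    "chl_a": {"littoral": ZoneStats(3.03, 1.09), "pelagic": ZoneStats(3.89, 1.49)},
    "doc": {"littoral": ZoneStats(1.89, 1.23), "pelagic": ZoneStats(2.38, 1.51)},
    "dic": {"littoral": ZoneStats(15.03, 4.36), "pelagic": ZoneStats(14.41, 3.99)},
    "o2_consumption": {
        "littoral": ZoneStats(2.57, 1.64),
        "pelagic": ZoneStats(2.74, 1.52),
    },
    "co2_accumulation": {
        "littoral": ZoneStats(5.81, 4.14),
        "pelagic": ZoneStats(5.60, 4.40),
    },
}

#: The seven campaigns: three in year one, four in year two.
DEFAULT_MONTHS = (
    "2010-05",
    "2010-08",
    "2010-11",
    "2011-03",
    "2011-05",
    "2011-08",
    "2011-11",
)

# Southern-hemisphere seasonal water temperatures by calendar month (degC).
_MONTH_TEMPERATURE_C = {1: 26.0, 2: 25.0, 3: 23.0, 4: 21.0, 5: 18.0, 6: 15.0,
                        7: 13.0, 8: 13.0, 9: 15.0, 10: 18.0, 11: 20.0, 12: 24.0}


@dataclass
class GeneratorConfig:
    """Parameters of the station-table generator.

    Zone counts and per-variable zone statistics default to the emulated
    survey design (12 littoral + 7 pelagic stations, whole-period
    summaries).  Shore distances are drawn uniformly within per-zone
    ranges straddling the 1000-m littoral/pelagic threshold.  Temperature
    follows a seasonal cycle with `temperature_sd` station-level scatter;
    wind and conductivity are zero-truncated Gaussians.  A positive
    `month_effect_sd` adds a shared month intercept (in units of each
    variable's SD) to every chemical/optical variable, emulating
    lake-wide campaign-to-campaign shifts.
    """

    months: tuple = DEFAULT_MONTHS
    n_littoral: int = 12
    n_pelagic: int = 7
    variables: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in ZONE_VARIABLE_DEFAULTS.items()
        }
    )
    littoral_distance_range_m: tuple = (50.0, 950.0)
    pelagic_distance_range_m: tuple = (1000.0, 5000.0)
    temperature_sd: float = 1.0
    conductivity_mean: float = 300.0
    conductivity_sd: float = 50.0
    wind_mean: float = 5.0
    wind_sd: float = 2.0
    month_effect_sd: float = 0.0
    correlation: np.ndarray | None = None  # Gaussian-copula predictor correlation

    def __post_init__(self) -> None:
        if self.n_littoral < 1 or self.n_pelagic < 1:
            raise ValueError("need at least one station per zone")
        for var, zones in self.variables.items():
            for zone, stats in zones.items():
                if not isinstance(stats, ZoneStats):
                    zones[zone] = ZoneStats(*stats)


@functools.lru_cache(maxsize=4096)
def _debiased_location(mean: float, sd: float) -> float:
    """Location of the underlying Gaussian whose zero-truncated mean is
    `mean`.

    Resampling-on-negative draws from N(loc, sd) have expectation
    loc + sd * phi(loc/sd) / Phi(loc/sd); for means within a few SD of
    zero (e.g. total phosphorus) the naive loc = mean inflates the
    realized mean by several percent, so loc is solved for instead.
    """
    if mean <= 0 or mean >= 5.0 * sd:
        return mean  # bias negligible (or no feasible correction)
    f = lambda loc: loc + sd * scipy.stats.norm.pdf(
        loc / sd
    ) / scipy.stats.norm.cdf(loc / sd) - mean
    return scipy.optimize.brentq(f, mean - 20.0 * sd, mean, xtol=1e-12)


def _truncated_normal(rng, mean, sd, size):
    """Zero-truncated Gaussian with realized mean equal to `mean`."""
    if sd == 0:
        return np.full(size, float(mean))
    loc = _debiased_location(float(mean), float(sd))
    out = rng.normal(loc, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(loc, sd, int(bad.sum()))
        bad = out < 0
    return out


def generate_station_table(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw one full station x month table.

    Returns a DataFrame with one row per station visit carrying station id,
    month, zone, shore distance, temperature, conductivity, wind speed, the
    chemical/optical variables configured in `config.variables`, and the
    computed abs250_365 ratio.  Regeneration with the same seed and config
    is byte-identical.  The seed is recorded in ``df.attrs["seed"]``.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    n_stations = config.n_littoral + config.n_pelagic
    zones = ["littoral"] * config.n_littoral + ["pelagic"] * config.n_pelagic
    ids = [f"L{i+1:02d}" for i in range(config.n_littoral)] + [
        f"P{i+1:02d}" for i in range(config.n_pelagic)
    ]
    # Station positions are fixed across campaigns.
    lo, hi = config.littoral_distance_range_m
    dist_l = rng.uniform(lo, hi, config.n_littoral)
    lo, hi = config.pelagic_distance_range_m
    dist_p = rng.uniform(lo, hi, config.n_pelagic)
    distances = np.concatenate([dist_l, dist_p])

    var_names = list(config.variables)
    month_shift = {
        m: (
            rng.normal(0.0, config.month_effect_sd, len(var_names))
            if config.month_effect_sd > 0
            else np.zeros(len(var_names))
        )
        for m in config.months
    }

    use_copula = config.correlation is not None
    if use_copula:
        corr = np.asarray(config.correlation, dtype=float)
        if corr.shape != (len(var_names), len(var_names)):
            raise ValueError(
                "correlation matrix must be square with one row per variable"
            )
        chol = np.linalg.cholesky(corr)

    rows = []
    for month in config.months:
        cal_month = int(month.split("-")[1])
        t_mean = _MONTH_TEMPERATURE_C[cal_month]
        temps = rng.normal(t_mean, config.temperature_sd, n_stations)
        conds = _truncated_normal(
            rng, config.conductivity_mean, config.conductivity_sd, n_stations
        )
        winds = _truncated_normal(rng, config.wind_mean, config.wind_sd, n_stations)
        if use_copula:
            z = rng.standard_normal((n_stations, len(var_names))) @ chol.T
        for s in range(n_stations):
            row = {
                "station_id": ids[s],
                "month": month,
                "zone": zones[s],
                "distance_m": distances[s],
                "temperature_c": temps[s],
                "conductivity": conds[s],
                "u10": winds[s],
            }
            for j, var in enumerate(var_names):
                stats = config.variables[var][zones[s]]
                mean = stats.mean + month_shift[month][j] * stats.sd
                if use_copula:
                    value = mean + stats.sd * z[s, j]
                    while value < 0:
                        value = mean + stats.sd * rng.standard_normal()
                else:
                    value = _truncated_normal(rng, mean, stats.sd, 1)[0]
                row[var] = value
            # Optical ratio is derived, and absorbance ordering is physical:
            # redraw the rare inverted pair rather than emit abs365 > abs250.
            if "abs250" in row and "abs365" in row:
                while row["abs365"] >= row["abs250"]:
                    sa = config.variables["abs250"][zones[s]]
                    sb = config.variables["abs365"][zones[s]]
                    row["abs250"] = _truncated_normal(rng, sa.mean, sa.sd, 1)[0]
                    row["abs365"] = _truncated_normal(rng, sb.mean, sb.sd, 1)[0]
                row["abs250_365"] = row["abs250"] / row["abs365"] if row[
                    "abs365"
                ] > 0 else np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    return df


def generate_incubation_series(
    true_rate_ug_c_l_h: float,
    duration_h: float = 120.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    o2_start: float = 8.0,
    sample_id: str = "synthetic",
    zone: str | None = None,
    temperature_c: float = 23.0,
    conductivity: float = 300.0,
    dic_start: float | None = None,
    dic_rate_mg_c_l_h: float | None = None,
    ph_start: float | None = None,
    ph_end: float | None = None,
    time_course_hours: tuple = (),
) -> IncubationSeries:
    """Construct a dark-bottle series consistent with a known carbon rate.

    The O2 endpoints satisfy the molar-factor-1.0 unit chain exactly at
    `noise_sd` = 0; Gaussian measurement noise (mg O2/L) is added to both
    endpoints otherwise.  If `dic_start` and `dic_rate_mg_c_l_h` are given,
    DIC endpoints (and optionally a time course at `time_course_hours`)
    accumulate linearly.  Raises if the requested rate would drive O2
    negative by the end of the incubation.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    delta_o2 = true_rate_ug_c_l_h * duration_h / UG_C_PER_MG_O2
    o2_end = o2_start - delta_o2
    if o2_end < 0:
        raise ValueError(
            f"rate {true_rate_ug_c_l_h} μg C/L/h over {duration_h} h implies "
            f"negative end O2 ({o2_end:.3f} mg/L)"
        )
    if noise_sd > 0:
        o2_start = o2_start + rng.normal(0.0, noise_sd)
        o2_end = o2_end + rng.normal(0.0, noise_sd)
    dic_end = None
    course: list[tuple[float, float]] = []
    if dic_start is not None and dic_rate_mg_c_l_h is not None:
        dic_end = dic_start + dic_rate_mg_c_l_h * duration_h
        for t in time_course_hours:
            value = dic_start + dic_rate_mg_c_l_h * t
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd)
            course.append((float(t), float(value)))
    return IncubationSeries(
        sample_id=sample_id,
        zone=zone,
        temperature_c=temperature_c,
        conductivity=conductivity,
        duration_h=duration_h,
        o2_start=float(o2_start),
        o2_end=float(o2_end),
        dic_start=dic_start,
        dic_end=dic_end,
        ph_start=ph_start,
        ph_end=ph_end,
        time_course=course,
    )


def generate_dic_experiment(
    seed: int | None = None,
    littoral: ZoneStats = ZoneStats(16.82, 1.72),
    pelagic: ZoneStats = ZoneStats(23.24, 1.54),
    days: tuple = (0, 1, 3, 5, 7, 10, 14),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Vial-retrieval table for a two-water 14-day DIC incubation.

    Triplicate vials per water type and retrieval day (42 rows at the
    defaults), DIC drawn from the per-water zero-truncated Gaussian with no
    time trend — the null the time-effect test should not reject.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for water, stats in (("littoral", littoral), ("pelagic", pelagic)):
        for day in days:
            values = _truncated_normal(rng, stats.mean, stats.sd, n_replicates)
            for r, v in enumerate(values):
                rows.append(
                    {
                        "water": water,
                        "time_h": 24.0 * day,
                        "replicate": r + 1,
                        "dic": float(v),
                    }
                )
    return pd.DataFrame(rows)


def generate_null_dataset(
    n_per_group, n_variables: int = 1, seed: int | None = None
):
    """Exchangeable-null labeled data for permutation-test calibration.

    `n_per_group` is a sequence of group sizes; every observation is drawn
    iid standard normal so labels carry no information.  Returns (values,
    labels) with values 1-D when `n_variables` == 1.
    """
    sizes = [int(n) for n in np.atleast_1d(n_per_group)]
    if any(n < 2 for n in sizes):
        raise ValueError("every group needs n >= 2")
    rng = np.random.default_rng(seed)
    total = sum(sizes)
    values = rng.standard_normal((total, n_variables))
    if n_variables == 1:
        values = values[:, 0]
    labels = np.repeat([f"g{i}" for i in range(len(sizes))], sizes)
    return values, labels
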