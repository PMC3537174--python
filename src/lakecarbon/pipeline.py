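"""End-to-end orchestration: I/O, derived quantities, zone contrasts,
regression trees, and the analysis report.

The flow mirrors a littoral-vs-pelagic field study: station tables (one
row per station visit) are read or generated, carbonate speciation turns
DIC/pH/temperature/conductivity into water pCO2, the wind model turns
pCO2 into an air-water flux, variables are z-scored within month, each is
tested for a zone difference by permutational ANOVA with Bonferroni
adjustment across variables, and regression trees relate the metabolic
responses to the chemical/optical predictors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .carbonate import carbonate_state
from .constants import LITTORAL_PELAGIC_THRESHOLD_M, PCO2_ATM_DEFAULT
from .gas_exchange import co2_flux
from .permstats import bonferroni_adjust, permutation_test, zscore_within_month
from .tree import TreeFitConfig, TreeNode, fit_tree, render_tree

__all__ = [
    "AnalysisReport",
    "STATION_COLUMNS",
    "CONTRAST_VARIABLES",
    "TREE_RESPONSES",
    "TREE_PREDICTORS",
    "assign_zone",
    "read_station_table",
    "write_station_table",
    "validate_station_table",
    "derive_quantities",
    "zone_contrasts",
    "flux_sign_histogram",
    "run_full_analysis",
]

log = logging.getLogger("lakecarbon")

#: Canonical station-table schema (CSV header order).
STATION_COLUMNS = [
    "station_id",
    "month",
    "zone",
    "distance_m",
    "temperature_c",
    "conductivity",
    "u10",
    "ph",
    "dic",
    "doc",
    "tp",
    "tn",
    "chl_a",
    "abs250",
    "abs365",
    "abs250_365",
    "o2_consumption",
    "co2_accumulation",
]

_REQUIRED_COLUMNS = [
    "station_id",
    "month",
    "distance_m",
    "temperature_c",
    "conductivity",
    "ph",
    "dic",
]

_NONNEGATIVE_COLUMNS = [
    "distance_m",
    "conductivity",
    "dic",
    "doc",
    "tp",
    "tn",
    "chl_a",
    "abs250",
    "abs365",
    "u10",
]

#: Variables contrasted between zones by default (those present in the
#: table are used).  DIC and pCO2 are deliberately not part of the default
#: family — pass `variables` explicitly to test them — so the Bonferroni
#: factor matches the number of planned comparisons.
CONTRAST_VARIABLES = [
    "ph",
    "abs250",
    "abs365",
    "abs250_365",
    "tp",
    "tn",
    "chl_a",
    "doc",
    "o2_consumption",
    "co2_accumulation",
    "fco2",
]

#: Regression-tree responses and the shared predictor set.
TREE_RESPONSES = ["o2_consumption", "co2_accumulation", "pco2_water", "fco2"]
TREE_PREDICTORS = ["ph", "abs250", "abs365", "abs250_365", "tp", "tn", "chl_a", "doc"]


def assign_zone(distance_to_shore_m: float) -> str:
    """Zone label from shore distance: littoral below 1000 m, pelagic at or
    beyond (the boundary itself is pelagic)."""
    if distance_to_shore_m < 0:
        raise ValueError("distance to shore must be >= 0")
    return (
        "littoral"
        if distance_to_shore_m < LITTORAL_PELAGIC_THRESHOLD_M
        else "pelagic"
    )


def read_station_table(path) -> pd.DataFrame:
    """Read a station CSV (UTF-8, comma, '.' decimal, empty = missing)."""
    df = pd.read_csv(path)
    log.info("read %d rows from %s", len(df), path)
    return df


def write_station_table(df: pd.DataFrame, path) -> None:
    """Write a station CSV in the canonical column order (extra columns
    appended after), full float precision."""
    cols = [c for c in STATION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)
    log.info("wrote %d rows to %s", len(df), path)


def validate_station_table(df: pd.DataFrame) -> list[str]:
    """Schema validation; returns a list of human-readable problems
    (empty when valid)."""
    problems = []
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    for col in _NONNEGATIVE_COLUMNS:
        if col in df.columns:
            bad = df[col].dropna() < 0
            if bad.any():
                problems.append(f"{int(bad.sum())} negative values in {col!r}")
    if "ph" in df.columns:
        ph = df["ph"].dropna()
        out = (ph < 2) | (ph > 12)
        if out.any():
            problems.append(f"{int(out.sum())} pH values outside [2, 12]")
    return problems


def derive_quantities(
    df: pd.DataFrame,
    pco2_atm: float = PCO2_ATM_DEFAULT,
    flux_months: list[str] | None = None,
) -> pd.DataFrame:
    """Add zone, water pCO2 and air-water flux columns to a station table.

    Zone is (re)derived from shore distance.  pCO2 needs dic/ph/
    temperature/conductivity; flux additionally needs u10.  When
    `flux_months` is given, pCO2/flux are computed only for those months
    (rows from other months get NaN), mirroring surveys where flux inputs
    exist for a subset of campaigns.  Rows with missing inputs get NaN and
    are counted in the log.
    """
    out = df.copy()
    out["zone"] = [assign_zone(d) for d in out["distance_m"]]
    pco2 = np.full(len(out), np.nan)
    fco2 = np.full(len(out), np.nan)
    n_skip = 0
    month_ok = (
        out["month"].isin(flux_months)
        if flux_months is not None
        else pd.Series(True, index=out.index)
    )
    for i, row in enumerate(out.itertuples(index=False)):
        if not month_ok.iloc[i]:
            continue
        try:
            state = carbonate_state(
                row.dic, row.ph, row.temperature_c, row.conductivity
            )
        except (ValueError, TypeError):
            n_skip += 1
            continue
        pco2[i] = state.pco2_water
        u10 = getattr(row, "u10", None)
        if u10 is not None and np.isfinite(u10):
            fco2[i] = co2_flux(
                state.pco2_water, row.temperature_c, u10, pco2_atm
            )
    if n_skip:
        log.info("pCO2 skipped for %d rows with invalid/missing inputs", n_skip)
    out["pco2_water"] = pco2
    out["fco2"] = fco2
    return out


def zone_contrasts(
    df: pd.DataFrame,
    variables: list[str] | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
    by_month: bool = False,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-variable littoral-vs-pelagic permutation tests.

    Pooled mode z-scores each variable within month first (so campaigns
    with different baselines are comparable) and tests all months together;
    `by_month` runs one test per campaign instead.  Each variable is a
    planned individual comparison, so its permutation p stands at face
    value; the Bonferroni column carries the a-posteriori pairwise-contrast
    correction (n_pairs x p), which is the identity for the two-zone
    design and only bites for multi-group factors.  The direction column
    reports which zone had the higher raw mean.
    """
    if variables is None:
        variables = [v for v in CONTRAST_VARIABLES if v in df.columns]
    work = df.copy()
    if standardize and not by_month:
        work = zscore_within_month(work, columns=[v for v in variables])
    rows = []
    seeds = iter(np.random.SeedSequence(seed).generate_state(10_000))
    month_groups = (
        [(m, g) for m, g in work.groupby("month", sort=False)]
        if by_month
        else [("all", work)]
    )
    for month, sub in month_groups:
        for var in variables:
            vals = sub[var]
            ok = vals.notna()
            if ok.sum() < 4 or sub.loc[ok, "zone"].nunique() < 2:
                continue
            raw = df.loc[sub.index[ok], var] if not by_month else sub.loc[ok, var]
            means = raw.groupby(sub.loc[ok, "zone"]).mean()
            try:
                res = permutation_test(
                    vals[ok].to_numpy(),
                    sub.loc[ok, "zone"].to_numpy(),
                    n_permutations=n_permutations,
                    seed=int(next(seeds)),
                )
            except ValueError:
                continue
            direction = (
                "littoral > pelagic"
                if means.get("littoral", np.nan) > means.get("pelagic", np.nan)
                else "pelagic > littoral"
            )
            rows.append(
                {
                    "month": month,
                    "variable": var,
                    "pseudo_f": res.pseudo_f,
                    "p_perm": res.p_perm,
                    "n_permutations": res.n_permutations,
                    "n_littoral": res.group_sizes.get("littoral"),
                    "n_pelagic": res.group_sizes.get("pelagic"),
                    "direction": direction,
                    "seed": res.seed,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        n_zones = df["zone"].nunique()
        n_pairs = max(1, n_zones * (n_zones - 1) // 2)
        table["p_bonferroni"] = [
            bonferroni_adjust(p, n_pairs) for p in table["p_perm"]
        ]
    return table


def flux_sign_histogram(df: pd.DataFrame, n_bins: int = 8) -> dict:
    """Per-zone histogram of CO2 fluxes plus sink/source counts.

    Bins are shared across zones; counts per zone sum to that zone's
    number of non-missing flux records."""
    fluxes = df["fco2"].dropna()
    if fluxes.empty:
        return {"bins": [], "zones": {}}
    edges = np.histogram_bin_edges(fluxes, bins=n_bins)
    zones = {}
    for zone, sub in df.groupby("zone"):
        vals = sub["fco2"].dropna().to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        zones[zone] = {
            "counts": counts.tolist(),
            "n": int(len(vals)),
            "n_influx": int((vals > 0).sum()),
            "n_efflux": int((vals < 0).sum()),
            "n_zero": int((vals == 0).sum()),
            "mean": float(vals.mean()) if len(vals) else None,
        }
    return {"bins": edges.tolist(), "zones": zones}


@dataclass
class AnalysisReport:
    """Full analysis output: contrasts, fitted trees, flux histogram,
    and run metadata sufficient to regenerate the report bit-identically."""

    contrasts: pd.DataFrame
    contrasts_by_month: pd.DataFrame
    trees: dict[str, TreeNode]
    tree_text: dict[str, str]
    flux_histogram: dict
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "contrasts": self.contrasts.to_dict(orient="records"),
            "contrasts_by_month": self.contrasts_by_month.to_dict(
                orient="records"
            ),
            "trees": self.tree_text,
            "flux_histogram": self.flux_histogram,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def _config_hash(items: dict) -> str:
    blob = json.dumps(items, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_analysis(
    df: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int | None = None,
    pco2_atm: float = PCO2_ATM_DEFAULT,
    flux_months: list[str] | None = None,
    tree_config: TreeFitConfig | None = None,
) -> AnalysisReport:
    """Run the complete littoral-vs-pelagic analysis on a station table.

    Steps: schema validation, derived quantities (zone, pCO2, flux),
    pooled and per-month zone contrasts, four regression trees (responses
    O2 consumption, CO2 accumulation, pCO2 and flux on the chemical/
    optical predictors; the flux-based trees use only months with flux
    inputs), and the per-zone flux histogram.
    """
    problems = validate_station_table(df)
    if problems:
        raise ValueError("invalid station table: " + "; ".join(problems))
    work = derive_quantities(df, pco2_atm=pco2_atm, flux_months=flux_months)
    log.info(
        "analysis on %d rows (%d littoral, %d pelagic)",
        len(work),
        int((work["zone"] == "littoral").sum()),
        int((work["zone"] == "pelagic").sum()),
    )
    ss = np.random.SeedSequence(seed)
    s_pooled, s_monthly = (int(x) for x in ss.generate_state(2))
    contrasts = zone_contrasts(
        work, n_permutations=n_permutations, seed=s_pooled, by_month=False
    )
    by_month = zone_contrasts(
        work, n_permutations=n_permutations, seed=s_monthly, by_month=True
    )
    trees: dict[str, TreeNode] = {}
    tree_text: dict[str, str] = {}
    predictors = [p for p in TREE_PREDICTORS if p in work.columns]
    for response in TREE_RESPONSES:
        if response not in work.columns or work[response].notna().sum() == 0:
            continue
        sub = work
        if response in ("pco2_water", "fco2") and flux_months is not None:
            sub = work[work["month"].isin(flux_months)]
        try:
            trees[response] = fit_tree(
                sub, response, predictors=predictors, config=tree_config
            )
            tree_text[response] = render_tree(trees[response])
        except ValueError as exc:
            warnings.warn(f"tree for {response!r} not fitted: {exc}", UserWarning)
    metadata = {
        "package_version": __version__,
        "seed": seed,
        "n_permutations": n_permutations,
        "pco2_atm": pco2_atm,
        "n_records": int(len(work)),
        "flux_months": flux_months,
        "config_hash": _config_hash(
            {
                "n_permutations": n_permutations,
                "seed": seed,
                "pco2_atm": pco2_atm,
                "flux_months": flux_months,
            }
        ),
    }
    return AnalysisReport(
        contrasts=contrasts,
        contrasts_by_month=by_month,
        trees=trees,
        tree_text=tree_text,
        flux_histogram=flux_sign_histogram(work),
        metadata=metadata,
    )
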