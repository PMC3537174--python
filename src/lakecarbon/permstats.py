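"""Permutational one-way (NP)MANOVA and companion tests.

The central test is a one-way permutational ANOVA on Euclidean distances
(univariate mode), as popularized for ecological data by Anderson's
PERMANOVA.  The statistic is the pseudo-F

    F = (SS_between / (a - 1)) / (SS_within / (N - a))

computed from the sum-of-squares decomposition of the pairwise squared
Euclidean distances; in the univariate case it is algebraically identical
to the classical one-way ANOVA F.  Significance comes from permuting group
labels: p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), with the
observed labelling counted once (the "add-one" estimator, which can never
return zero).  When the number of distinct relabellings is small the test
enumerates all of them exactly instead of sampling.

Also here: pseudo-F reconstruction from published group summaries,
Bonferroni adjustment (n * p capped at 1), within-month z-scoring, and the
ln-transform ANOVA / regression used for respiration-vs-distance data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "PermTestResult",
    "RespirationDistanceReport",
    "pseudo_f",
    "permutation_test",
    "pseudo_f_from_summary",
    "bonferroni_adjust",
    "zscore_within_month",
    "log_anova_and_regression",
]

#: Enumerate all relabellings exactly when there are at most this many.
EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of one permutational test.

    n_permutations counts the permuted datasets evaluated (all distinct
    relabellings when ``exhaustive``); group_sizes/group_means are keyed by
    group label; seed is the RNG seed used (None for exhaustive tests).
    """

    pseudo_f: float
    p_perm: float
    n_permutations: int
    exhaustive: bool
    group_sizes: dict
    group_means: dict
    seed: int | None


def _validate_groups(values: np.ndarray, groups: np.ndarray):
    labels, group_idx = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(group_idx)
    if np.any(sizes < 2):
        small = [str(l) for l, n in zip(labels, sizes) if n < 2]
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    return labels, group_idx, sizes


def _f_univariate(v: np.ndarray, group_idx: np.ndarray, a: int) -> float:
    n = len(v)
    total = v.sum()
    sst = (v**2).sum() - total**2 / n
    if sst <= 0:
        return 0.0
    gsum = np.bincount(group_idx, weights=v, minlength=a)
    gn = np.bincount(group_idx, minlength=a)
    ssb = (gsum**2 / gn).sum() - total**2 / n
    ssw = sst - ssb
    if ssw <= 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n - a))


def _f_from_distances(d2: np.ndarray, group_idx: np.ndarray, a: int) -> float:
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    if sst <= 0:
        return 0.0
    ssw = 0.0
    for g in range(a):
        members = np.flatnonzero(group_idx == g)
        ssw += d2[np.ix_(members, members)].sum() / (2.0 * len(members))
    ssb = sst - ssw
    if ssw <= 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n - a))


def pseudo_f(values, groups) -> float:
    """Pseudo-F of a one-way Euclidean-distance partition.

    `values` may be a 1-D vector (univariate mode, where the statistic
    equals the classical ANOVA F) or an (N, p) matrix of observation
    vectors.  Every group must contain at least two observations.
    """
    v = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    _, group_idx, _ = _validate_groups(v, groups)
    a = group_idx.max() + 1
    if v.ndim == 1:
        return _f_univariate(v, group_idx, a)
    d2 = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(v, metric="sqeuclidean")
    )
    return _f_from_distances(d2, group_idx, a)


def _n_relabellings(sizes: np.ndarray) -> int:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _iter_assignments(n: int, sizes):
    """Yield group-index vectors for every distinct relabelling."""

    def rec(remaining: tuple, g: int, assign: np.ndarray):
        if g == len(sizes) - 1:
            assign[list(remaining)] = g
            yield assign
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            assign[list(combo)] = g
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(rest, g + 1, assign)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def permutation_test(
    values,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    strata=None,
) -> PermTestResult:
    """One-way permutational (NP)MANOVA, Euclidean distance.

    Permutes group labels freely (or within `strata`, e.g. sampling months,
    when given) and reports the add-one Monte-Carlo p-value.  When the
    total number of distinct relabellings is at most 20,000 and no strata
    are given, all of them are enumerated and the p-value is exact.

    Ties between permuted and observed F count as "at least as extreme"
    (inclusive), which is conservative.
    """
    v = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, group_idx, sizes = _validate_groups(v, groups)
    a = len(labels)
    n = len(v)

    if v.ndim == 1:
        group_means = {
            str(l): float(v[group_idx == g].mean()) for g, l in enumerate(labels)
        }
    else:
        group_means = {
            str(l): v[group_idx == g].mean(axis=0).tolist()
            for g, l in enumerate(labels)
        }
    group_sizes = {str(l): int(s) for l, s in zip(labels, sizes)}

    univariate = v.ndim == 1
    if univariate:
        f_obs = _f_univariate(v, group_idx, a)
    else:
        d2 = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(v, metric="sqeuclidean")
        )
        f_obs = _f_from_distances(d2, group_idx, a)

    tol = 1e-12 * max(1.0, abs(f_obs))
    total = _n_relabellings(sizes)
    if strata is None and total <= EXHAUSTIVE_LIMIT:
        count = 0
        for assign in _iter_assignments(n, sizes.tolist()):
            f_p = (
                _f_univariate(v, assign, a)
                if univariate
                else _f_from_distances(d2, assign, a)
            )
            if f_p >= f_obs - tol:
                count += 1
        return PermTestResult(
            pseudo_f=f_obs,
            p_perm=count / total,
            n_permutations=total,
            exhaustive=True,
            group_sizes=group_sizes,
            group_means=group_means,
            seed=None,
        )

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
    if univariate and strata is None:
        # Vectorized: permuting values is equivalent to permuting labels,
        # so group membership can be taken as fixed contiguous blocks.
        boundaries = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        perms = rng.permuted(np.tile(v, (n_permutations, 1)), axis=1)
        gsum = np.add.reduceat(perms, boundaries, axis=1)
        total_sum = v.sum()
        sst = (v**2).sum() - total_sum**2 / n
        with np.errstate(divide="ignore", invalid="ignore"):
            ssb = (gsum**2 / sizes).sum(axis=1) - total_sum**2 / n
            ssw = sst - ssb
            f_perm = (ssb / (a - 1)) / (ssw / (n - a))
        f_perm = np.where((ssw <= 0) & (ssb > 0), np.inf, f_perm)
        f_perm = np.where(sst <= 0, 0.0, f_perm)
        exceed = int(np.count_nonzero(f_perm >= f_obs - tol))
    else:
        exceed = 0
        for _ in range(n_permutations):
            if strata is None:
                perm_idx = rng.permutation(group_idx)
            else:
                perm_idx = group_idx.copy()
                for s in np.unique(strata):
                    members = np.flatnonzero(strata == s)
                    perm_idx[members] = perm_idx[rng.permutation(members)]
            f_p = (
                _f_univariate(v, perm_idx, a)
                if univariate
                else _f_from_distances(d2, perm_idx, a)
            )
            if f_p >= f_obs - tol:
                exceed += 1
    return PermTestResult(
        pseudo_f=f_obs,
        p_perm=(1 + exceed) / (1 + n_permutations),
        n_permutations=n_permutations,
        exhaustive=False,
        group_sizes=group_sizes,
        group_means=group_means,
        seed=seed,
    )


def pairwise_contrasts(
    values,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """A posteriori pairwise contrasts with Bonferroni correction.

    Runs the two-group permutation test for every pair of group labels and
    multiplies each raw permutation p by the number of pairs (capped at 1).
    For two groups this is the identity; it matters for multi-group tests
    such as a time effect across incubation retrieval days.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    pairs = list(itertools.combinations(labels, 2))
    seeds = iter(np.random.SeedSequence(seed).generate_state(len(pairs)))
    rows = []
    for a, b in pairs:
        mask = (groups == a) | (groups == b)
        res = permutation_test(
            values[mask],
            groups[mask],
            n_permutations=n_permutations,
            seed=int(next(seeds)),
        )
        rows.append(
            {
                "group_a": str(a),
                "group_b": str(b),
                "pseudo_f": res.pseudo_f,
                "p_raw": res.p_perm,
                "p_adjusted": bonferroni_adjust(res.p_perm, len(pairs)),
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def pseudo_f_from_summary(means, sds, ns) -> float:
    """Univariate pseudo-F reconstructed from group means, SDs and sizes.

    SS_between = sum n_i (xbar_i - xbar)^2 with xbar the size-weighted grand
    mean; SS_within = sum (n_i - 1) s_i^2.  Useful for re-deriving the
    statistic from published summary tables.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if len(means) < 2:
        raise ValueError("need at least two groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    grand = (ns * means).sum() / ns.sum()
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    a = len(means)
    n_total = ns.sum()
    if ssw <= 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n_total - a))


def bonferroni_adjust(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value: min(n * p, 1)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(n_comparisons * p, 1.0)


def zscore_within_month(
    table: pd.DataFrame,
    month_col: str = "month",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Z-score each variable within each month stratum.

    Uses the sample SD (ddof=1).  Missing values propagate; a stratum with
    zero spread yields standardized zeros and a degenerate-stratum warning.
    Standardization is idempotent (z-scoring a z-scored table is a no-op up
    to floating point).
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != month_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    out = table.copy()
    grouped = table.groupby(month_col, sort=False)
    degenerate: list[tuple] = []
    for col in columns:
        mean = grouped[col].transform("mean")
        sd = grouped[col].transform(lambda s: s.std(ddof=1))
        z = (table[col] - mean) / sd
        # identical values can leave an SD of ~1e-16 from cancellation error,
        # so "zero spread" is judged relative to the stratum mean
        bad = (sd <= 1e-10 * np.maximum(mean.abs(), 1.0)) & table[col].notna()
        if bad.any():
            degenerate.extend((m, col) for m in table.loc[bad, month_col].unique())
            z = z.mask(bad, 0.0)
        out[col] = z
    if degenerate:
        warnings.warn(
            f"zero within-month SD (standardized to 0) for: {degenerate}",
            UserWarning,
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class RespirationDistanceReport:
    """ln-transform ANOVA by zone plus OLS of ln(rate) on ln(distance)."""

    anova_f: float
    anova_p: float
    slope: float
    intercept: float
    adjusted_r2: float
    slope_p: float
    slope_ci: tuple
    n_used: int
    n_excluded: int
    degenerate: bool


def log_anova_and_regression(rates, distances, groups) -> RespirationDistanceReport:
    """Zone contrast and distance trend for respiration rates.

    Natural-log transforms the rates (non-positive rates are excluded with
    a logged count), runs a classical one-way ANOVA on ln(rate) by group,
    and fits ln(rate) = a + b ln(distance) by ordinary least squares,
    reporting the slope, its p-value and 95% CI, and the adjusted R^2.
    Zero within-group spread makes the ANOVA F unbounded; this is flagged
    as degenerate rather than reported as a finite statistic.
    """
    rates = np.asarray(rates, dtype=float)
    distances = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    ok = (rates > 0) & (distances > 0) & np.isfinite(rates) & np.isfinite(distances)
    n_excluded = int(np.count_nonzero(~ok))
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} records with non-positive rate or distance "
            "before log transformation",
            UserWarning,
            stacklevel=2,
        )
    ln_rate = np.log(rates[ok])
    ln_dist = np.log(distances[ok])
    grp = groups[ok]

    samples = [ln_rate[grp == g] for g in np.unique(grp)]
    degenerate = all(s.var(ddof=1) == 0 for s in samples if len(s) > 1)
    if degenerate:
        anova_f, anova_p = math.inf, 0.0
    else:
        anova_f, anova_p = scipy.stats.f_oneway(*samples)

    model = sm.OLS(ln_rate, sm.add_constant(ln_dist)).fit()
    ci = model.conf_int(alpha=0.05)
    return RespirationDistanceReport(
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adjusted_r2=float(model.rsquared_adj),
        slope_p=float(model.pvalues[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n_used=int(ok.sum()),
        n_excluded=n_excluded,
        degenerate=degenerate,
    )
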