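"""Permutational ANOVA, summaries, Bonferroni, z-scoring, and the
log-transform respiration analyses."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lakecarbon import permstats
from lakecarbon.permstats import (
    bonferroni_adjust,
    log_anova_and_regression,
    permutation_test,
    pseudo_f,
    pseudo_f_from_summary,
    zscore_within_month,
)


class TestPseudoF:
    def test_hand_computed_two_group_case(self):
        # groups {1,2,3} vs {4,5,6}: SSB = 13.5, MSW = 1
        f = pseudo_f([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(13.5, rel=1e-12)

    def test_equal_group_means_give_zero_between(self):
        f = pseudo_f([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_matches_classical_anova_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            sizes = rng.integers(3, 12, size=rng.integers(2, 5))
            values = rng.normal(size=sizes.sum())
            labels = np.repeat(np.arange(len(sizes)), sizes)
            expected = scipy.stats.f_oneway(
                *[values[labels == g] for g in range(len(sizes))]
            ).statistic
            assert pseudo_f(values, labels) == pytest.approx(expected, rel=1e-9)

    def test_univariate_equals_one_column_multivariate(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=10)
        labels = ["a"] * 5 + ["b"] * 5
        assert pseudo_f(v, labels) == pytest.approx(
            pseudo_f(v[:, None], labels), rel=1e-9
        )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            pseudo_f([1, 2, 3], ["a", "a", "b"])

    def test_matches_skbio_permanova_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(55)
        v = np.concatenate([rng.normal(0, 1, 9), rng.normal(1, 1, 7)])
        labels = ["a"] * 9 + ["b"] * 7
        dm = skbio_distance.DistanceMatrix(
            np.abs(v[:, None] - v[None, :]), ids=[str(i) for i in range(16)]
        )
        ref = skbio_distance.permanova(dm, labels, permutations=99)
        assert pseudo_f(v, labels) == pytest.approx(
            ref["test statistic"], rel=1e-9
        )


class TestPermutationTest:
    def test_exhaustive_two_group_example(self):
        # 20 distinct relabelings; observed and its mirror tie the max F
        res = permutation_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.exhaustive
        assert res.n_permutations == 20
        assert res.p_perm == pytest.approx(0.10, abs=1e-12)

    def test_identical_observations_give_p_one(self):
        res = permutation_test([5.0] * 12, ["a"] * 6 + ["b"] * 6, 499, seed=0)
        assert res.pseudo_f == 0.0
        assert res.p_perm == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=25)
        labels = ["a"] * 13 + ["b"] * 12
        r1 = permutation_test(v, labels, 999, seed=42)
        r2 = permutation_test(v, labels, 999, seed=42)
        assert r1.p_perm == r2.p_perm
        r3 = permutation_test(v, labels, 9999, seed=43)
        # different seeds agree within Monte-Carlo error
        se = math.sqrt(r1.p_perm * (1 - r1.p_perm) / 999)
        assert abs(r3.p_perm - r1.p_perm) < 4 * se + 2 / 999

    def test_add_one_estimator_never_zero(self):
        v = np.concatenate([np.zeros(10), np.ones(10) * 50])
        res = permutation_test(v, ["a"] * 10 + ["b"] * 10, 199, seed=1)
        assert res.p_perm >= 1.0 / 200.0

    def test_monte_carlo_agrees_with_exhaustive(self, monkeypatch):
        rng = np.random.default_rng(21)
        for trial in range(5):
            v = rng.normal(size=8)
            labels = ["a"] * 4 + ["b"] * 4
            exact = permutation_test(v, labels).p_perm
            monkeypatch.setattr(permstats, "EXHAUSTIVE_LIMIT", 1)
            mc = permutation_test(v, labels, 4999, seed=trial)
            monkeypatch.setattr(permstats, "EXHAUSTIVE_LIMIT", 20_000)
            assert not mc.exhaustive
            se = math.sqrt(exact * (1 - exact) / 4999)
            assert abs(mc.p_perm - exact) < 3 * se + 2 / 5000

    def test_three_groups_exhaustive(self):
        # brute-force oracle over all 3-group assignments
        v = np.array([1.0, 2.0, 7.0, 8.0, 20.0, 21.0])
        labels = ["a", "a", "b", "b", "c", "c"]
        res = permutation_test(v, labels)
        assert res.exhaustive
        assert res.n_permutations == 90  # 6!/(2!2!2!)
        assert 0 < res.p_perm <= 1

    def test_stratified_permutation_runs(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=20)
        labels = (["a"] * 5 + ["b"] * 5) * 2
        strata = ["m1"] * 10 + ["m2"] * 10
        res = permutation_test(v, labels, 499, seed=9, strata=strata)
        assert 0 < res.p_perm <= 1
        assert not res.exhaustive

    def test_multivariate_euclidean_mode(self):
        rng = np.random.default_rng(8)
        v = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(2, 1, (6, 3))])
        res = permutation_test(v, ["a"] * 6 + ["b"] * 6, 499, seed=4)
        assert res.pseudo_f > 1
        assert res.p_perm < 0.05


class TestPseudoFFromSummary:
    def test_published_dic_experiment_summaries(self):
        # 23.24 +- 1.54 vs 16.82 +- 1.72, n = 21 each -> F ~ 162.4
        f = pseudo_f_from_summary([23.24, 16.82], [1.54, 1.72], [21, 21])
        assert f == pytest.approx(162.4, abs=0.1)

    def test_equal_means_give_zero(self):
        assert pseudo_f_from_summary([5.0, 5.0], [1.0, 2.0], [10, 10]) == 0.0

    def test_agrees_with_raw_data_of_exact_moments(self):
        rng = np.random.default_rng(17)
        means, sds, ns = [3.0, 5.5, 4.1], [1.2, 0.7, 2.0], [8, 12, 5]
        chunks, labels = [], []
        for g, (m, s, n) in enumerate(zip(means, sds, ns)):
            raw = rng.normal(size=n)
            raw = (raw - raw.mean()) / raw.std(ddof=1)  # exact moments
            chunks.append(m + s * raw)
            labels += [g] * n
        values = np.concatenate(chunks)
        assert pseudo_f_from_summary(means, sds, ns) == pytest.approx(
            pseudo_f(values, labels), rel=1e-9
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pseudo_f_from_summary([1.0, 2.0], [0.5, 0.5], [1, 10])


class TestPairwiseContrasts:
    def test_two_groups_identity_adjustment(self):
        rng = np.random.default_rng(44)
        v = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8)])
        labels = ["a"] * 8 + ["b"] * 8
        table = permstats.pairwise_contrasts(v, labels, 499, seed=3)
        assert len(table) == 1
        assert table["p_adjusted"].iloc[0] == table["p_raw"].iloc[0]

    def test_multi_group_pair_count_and_monotone_adjustment(self):
        rng = np.random.default_rng(45)
        v = np.concatenate(
            [rng.normal(m, 1, 6) for m in (0.0, 0.3, 4.0)]
        )
        labels = np.repeat(["t0", "t1", "t2"], 6)
        table = permstats.pairwise_contrasts(v, labels, 499, seed=5)
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["p_raw"]).all()
        assert (table["p_adjusted"] <= 1.0).all()
        # the separated group drives the small adjusted p-values
        far = table[table["group_b"] == "t2"]
        assert (far["p_adjusted"] < 0.1).all()


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, n, expected", [(0.02, 3, 0.06), (0.5, 10, 1.0), (0.123, 1, 0.123)]
    )
    def test_adjustment(self, p, n, expected):
        assert bonferroni_adjust(p, n) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)


class TestZscoreWithinMonth:
    def test_hand_example(self):
        df = pd.DataFrame({"month": ["m"] * 3, "x": [2.0, 4.0, 6.0]})
        z = zscore_within_month(df)
        assert list(z["x"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_per_month_normalization(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "month": np.repeat(["a", "b", "c"], 10),
                "x": rng.normal(5, 2, 30),
                "y": rng.normal(-1, 0.5, 30),
            }
        )
        z = zscore_within_month(df)
        for _, sub in z.groupby("month"):
            for col in ("x", "y"):
                assert sub[col].mean() == pytest.approx(0.0, abs=1e-12)
                assert sub[col].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"month": np.repeat(["a", "b"], 8), "x": rng.normal(size=16)}
        )
        once = zscore_within_month(df)
        twice = zscore_within_month(once)
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_degenerate_stratum_warns_and_zeros(self):
        df = pd.DataFrame({"month": ["m"] * 3, "x": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="zero within-month SD"):
            z = zscore_within_month(df)
        assert (z["x"] == 0.0).all()

    def test_missing_values_propagate(self):
        df = pd.DataFrame(
            {"month": ["m"] * 4, "x": [1.0, np.nan, 3.0, 5.0]}
        )
        z = zscore_within_month(df)
        assert z["x"].isna().sum() == 1


class TestLogAnovaAndRegression:
    def test_perfect_power_law_recovered(self):
        dist = np.geomspace(10.0, 5000.0, 40)
        rates = 0.07 * dist**0.559
        groups = ["littoral" if d < 1000 else "pelagic" for d in dist]
        rep = log_anova_and_regression(rates, dist, groups)
        assert rep.slope == pytest.approx(0.559, rel=1e-9)
        assert rep.intercept == pytest.approx(math.log(0.07), rel=1e-9)
        assert rep.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_within_spread_flagged_degenerate(self):
        rates = np.array([1.0] * 5 + [2.0] * 5)
        dist = np.linspace(100, 2000, 10)
        groups = ["a"] * 5 + ["b"] * 5
        rep = log_anova_and_regression(rates, dist, groups)
        assert rep.degenerate
        assert math.isinf(rep.anova_f)

    def test_nonpositive_rates_excluded_with_count(self):
        rates = np.array([0.0, -1.0, 2.0, 3.0, 4.0, 5.0])
        dist = np.linspace(100, 2000, 6)
        groups = ["a", "a", "a", "a", "b", "b"]
        with pytest.warns(UserWarning, match="excluded 2"):
            rep = log_anova_and_regression(rates, dist, groups)
        assert rep.n_excluded == 2
        assert rep.n_used == 4

    def test_slope_ci_coverage_at_low_r2(self):
        """With ln(rate) = -2.648 + 0.559 ln(dist) plus noise tuned to
        adjusted R^2 ~ 0.05, the 95% CI covers the true slope in >=90%
        of replicates."""
        rng = np.random.default_rng(13)
        true_slope, true_intercept = 0.559, -2.648
        n = 47
        ln_dist = rng.uniform(math.log(30), math.log(5000), n)
        # sigma chosen so explained fraction ~ 0.05
        sigma = abs(true_slope) * ln_dist.std() * math.sqrt(0.95 / 0.05)
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            ln_rate = (
                true_intercept + true_slope * ln_dist + rng.normal(0, sigma, n)
            )
            rates = np.exp(ln_rate)
            rep = log_anova_and_regression(
                rates, np.exp(ln_dist), ["a"] * 24 + ["b"] * 23
            )
            lo, hi = rep.slope_ci
            covered += lo <= true_slope <= hi
        assert covered / n_rep >= 0.90
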