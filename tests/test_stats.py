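"""Association layer: Fisher exact, Kaplan-Meier, log-rank, Cox, Spearman."""

import math
from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

from ith_biomarker import stats
from ith_biomarker.stats import ContingencyTable2x2


def enumeration_fisher_p(a, b, c, d):
    """Exact-integer hypergeometric enumeration of the two-sided p-value.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (up to the standard
    1e-7 relative tolerance for floating-point ties).
    """
    from math import comb

    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    total = comb(n, c1)
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs * (1 + 1e-7))
    return num / total


class TestFisher:
    def test_ith_group_dcb_table(self):
        # 45.7% of 35 = 16 benefiters vs 11.8% of 34 = 4
        odds, p = stats.fisher_exact(ContingencyTable2x2(16, 19, 4, 30))
        assert odds == pytest.approx(6.3158, abs=1e-3)
        assert p == pytest.approx(0.003, abs=5e-4)
        assert p == pytest.approx(enumeration_fisher_p(16, 19, 4, 30), rel=1e-9)

    def test_symmetric_table_p_one(self):
        _, p = stats.fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert p == 1.0

    def test_diagonal_table_by_enumeration(self):
        _, p = stats.fisher_exact(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(enumeration_fisher_p(10, 0, 0, 10), rel=1e-9)
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            _, p = stats.fisher_exact(ContingencyTable2x2(0, 0, 3, 4))
        assert p == 1.0

    def test_conditional_mle_odds_ratio_option(self):
        odds, _ = stats.fisher_exact(ContingencyTable2x2(16, 19, 4, 30), "cmle")
        oracle = sps.contingency.odds_ratio([[16, 19], [4, 30]]).statistic
        assert odds == pytest.approx(oracle)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = stats.fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(enumeration_fisher_p(a, b, c, d), rel=1e-7)


class TestKaplanMeier:
    def test_all_events_median_by_hand(self):
        # S drops 0.8, 0.6, 0.4 ... -> first time S <= 0.5 is t = 3
        assert stats.km_median([1, 2, 3, 4, 5], [1, 1, 1, 1, 1]) == 3

    def test_single_event(self):
        assert stats.km_median([10], [1]) == 10

    def test_all_censored_undefined(self):
        assert stats.km_median([5, 8, 12], [0, 0, 0]) is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stats.km_median([], [])

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(100, size=80).round(1) + 0.5
        sf = stats.km_survival_function(times, np.ones_like(times, dtype=bool))
        for t in sf.index[1:]:
            empirical = np.mean(times > t)
            assert sf.loc[t].iloc[0] == pytest.approx(empirical, abs=1e-12)

    def test_step_function_non_increasing(self, rng):
        times = rng.exponential(50, size=60) + 1
        events = rng.random(60) < 0.7
        sf = stats.km_survival_function(times, events).iloc[:, 0].to_numpy()
        assert np.all(np.diff(sf) <= 1e-12)


class TestLogrank:
    def test_identical_groups_p_near_one(self):
        times = [5, 10, 15, 20, 30, 40] * 2
        events = [1, 1, 0, 1, 1, 0] * 2
        groups = ["A"] * 6 + ["B"] * 6
        assert stats.logrank(times, events, groups) > 0.95

    def test_time_rescaling_invariance(self, rng):
        times = rng.exponential(100, size=50) + 1
        events = rng.random(50) < 0.8
        groups = rng.integers(0, 2, size=50)
        p1 = stats.logrank(times, events, groups)
        p2 = stats.logrank(times * 37.5, events, groups)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_power_under_planted_hazard_ratio(self):
        """HR 2.7 at n=500/arm: p < 0.001 in at least 95% of replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            t0 = rng.exponential(1.0, size=500)
            t1 = rng.exponential(1.0 / 2.7, size=500)
            times = np.concatenate([t0, t1])
            events = np.ones(1000, dtype=bool)
            groups = np.repeat([0, 1], 500)
            if stats.logrank(times, events, groups) < 0.001:
                hits += 1
        assert hits >= 95

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError, match="2"):
            stats.logrank([1, 2, 3], [1, 1, 0], ["A", "A", "A"])


class TestCox:
    def test_null_indicator_hr_near_one(self, rng):
        times = rng.exponential(100, size=1200)
        events = np.ones(1200, dtype=bool)
        indicator = rng.integers(0, 2, size=1200)
        hr, lo, hi = stats.cox_hr(times, events, indicator)
        assert lo < 1.0 < hi
        assert 0.8 < hr < 1.25

    def test_constant_indicator_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            stats.cox_hr([1, 2, 3, 4, 5], [1] * 5, [1] * 5)

    def test_group_swap_gives_reciprocal_hr(self, rng):
        times = rng.exponential(80, size=300)
        events = rng.random(300) < 0.8
        ind = rng.integers(0, 2, size=300)
        hr, lo, hi = stats.cox_hr(times, events, ind)
        hr2, lo2, hi2 = stats.cox_hr(times, events, 1 - ind)
        assert hr2 == pytest.approx(1 / hr, rel=1e-6)
        assert lo2 == pytest.approx(1 / hi, rel=1e-6)
        assert hi2 == pytest.approx(1 / lo, rel=1e-6)

    def test_tie_free_beta_matches_breslow_oracle(self, rng):
        """Without ties, Efron and Breslow partial likelihoods coincide."""
        import statsmodels.duration.hazard_regression as hz

        times = rng.exponential(100, size=200)  # continuous: no ties
        events = np.ones(200, dtype=bool)
        ind = rng.integers(0, 2, size=200).astype(float)
        hr, _, _ = stats.cox_hr(times, events, ind)
        mod = hz.PHReg(times, ind[:, None], status=events.astype(int), ties="breslow")
        beta_breslow = float(mod.fit().params[0])
        assert math.log(hr) == pytest.approx(beta_breslow, abs=1e-6)

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(5)
        ind = np.repeat([0.0, 1.0], 1000)
        times = np.where(
            ind == 1, rng.exponential(1 / 2.7, 2000), rng.exponential(1.0, 2000)
        )
        hr, lo, hi = stats.cox_hr(times, np.ones(2000, dtype=bool), ind)
        assert hr == pytest.approx(2.7, rel=0.1)
        assert lo < 2.7 < hi


class TestInteraction:
    def test_strong_interaction_detected(self):
        """Ratio of HRs = 3 at n=2000: product-term p < 0.01 in >=90% of reps."""
        rng = np.random.default_rng(77)
        hits, n_rep = 0, 20
        for _ in range(n_rep):
            tmb = rng.integers(0, 2, size=2000).astype(float)
            ith = rng.integers(0, 2, size=2000).astype(float)
            hazard = np.exp(0.3 * tmb + 0.3 * ith + math.log(3.0) * tmb * ith)
            times = rng.exponential(1.0 / hazard)
            if stats.interaction_p(times, np.ones(2000, bool), tmb, ith) < 0.01:
                hits += 1
        assert hits >= 18

    def test_nested_groups_collinear_error(self, rng):
        times = rng.exponential(50, size=40) + 1
        events = np.ones(40, dtype=bool)
        tmb = np.repeat([0.0, 1.0], 20)
        with pytest.raises(ValueError, match="collinear|vary"):
            stats.interaction_p(times, events, tmb, tmb)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = stats.spearman([1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                                [2, 4, 6, 8, 10, 12, 14, 16, 18, 20])
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        rho, _ = stats.spearman(list(range(10)), list(range(10))[::-1])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_exact_p_matches_independent_permutation_count(self, rng):
        """n=8: exact p equals brute-force enumeration via scipy's rho."""
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = stats.spearman(x, y)
        obs = abs(sps.spearmanr(x, y).statistic)
        count = sum(
            abs(sps.spearmanr(x, perm).statistic) >= obs - 1e-12
            for perm in permutations(y)
        )
        assert p == pytest.approx(count / math.factorial(8), abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = stats.spearman(x, y)
        sp = sps.spearmanr(x, y)
        assert rho == pytest.approx(sp.statistic)
        assert p == pytest.approx(sp.pvalue)
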