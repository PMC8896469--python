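"""Exact-statistics tests: Fisher, conditional odds-ratio bounds, exact
binomial CIs/tests, rank-sum, proportion and omnibus tests.

Independent oracles: exact-fraction enumeration over the hypergeometric
support, full enumeration of rank assignments, closed-form polynomial root
for the odds-ratio bound, and scipy's reference implementations where they
exist (cross-checks only)."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as ss

from memds.stats import (
    GWAExpectation,
    Table2x2,
    binom_exact_ci,
    binom_exact_test,
    fisher_exact,
    fisher_or_bounds,
    multinomial_omnibus,
    multisample_proportion_test,
    wilcoxon_rank_sum,
)


def fisher_oracle(t: Table2x2, alternative="two_sided") -> Fraction:
    """Exact-rational enumeration over the support of cell a."""
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = {k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k)) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    pmf = {k: w / total for k, w in weights.items()}
    if alternative == "two_sided":
        return sum(p for p in pmf.values() if p <= pmf[t.a])
    if alternative == "greater":
        return sum(p for k, p in pmf.items() if k >= t.a)
    return sum(p for k, p in pmf.items() if k <= t.a)


class TestFisherExact:
    def test_hbs_case_table(self):
        # 3 of 7 African HBB cases carry de novo 20A->T, 0 of 15 others
        assert fisher_exact(Table2x2(3, 4, 0, 15)) == pytest.approx(35 / 1540)

    def test_empty_column(self):
        assert fisher_exact(Table2x2(0, 5, 0, 5)) == 1.0

    def test_diagonal_table(self):
        assert fisher_exact(Table2x2(2, 0, 0, 2)) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b + c + d == 0:
                continue
            t = Table2x2(int(a), int(b), int(c), int(d))
            assert fisher_exact(t, alternative) == pytest.approx(
                float(fisher_oracle(t, alternative)), rel=1e-9, abs=1e-12
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            ours = fisher_exact(Table2x2(a, b, c, d))
            ref = ss.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)


class TestFisherOrBounds:
    def test_one_sided_lower_bound_hbs(self):
        lo, hi = fisher_or_bounds(Table2x2(3, 4, 0, 15), 0.95, "greater")
        assert lo == pytest.approx(1.5077, rel=1e-3)
        assert hi == math.inf

    def test_one_sided_bound_solves_tail_polynomial(self):
        # closed-form check: lo solves 35 psi^3 = 0.05 (455 + 735 psi + 315 psi^2 + 35 psi^3)
        lo, _ = fisher_or_bounds(Table2x2(3, 4, 0, 15), 0.95, "greater")
        lhs = 35 * lo**3
        rhs = 0.05 * (455 + 735 * lo + 315 * lo**2 + 35 * lo**3)
        assert lhs == pytest.approx(rhs, rel=1e-5)

    def test_zero_cell_less_bound(self):
        lo, hi = fisher_or_bounds(Table2x2(0, 5, 3, 2), 0.95, "less")
        assert lo == 0.0
        assert hi < math.inf

    def test_symmetric_table_contains_one(self):
        lo, hi = fisher_or_bounds(Table2x2(1, 1, 1, 1))
        assert lo < 1 < hi

    def test_degenerate_margins(self):
        assert fisher_or_bounds(Table2x2(0, 0, 3, 4)) == (0.0, math.inf)

    def test_two_sided_matches_scipy_conditional(self):
        for rows in [(3, 4, 1, 15), (5, 2, 2, 9), (1, 9, 4, 4)]:
            a, b, c, d = rows
            ours = fisher_or_bounds(Table2x2(a, b, c, d), 0.95, "two_sided")
            ref = ss.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
            ci = ref.confidence_interval(0.95)
            assert ours[0] == pytest.approx(ci.low, rel=1e-4)
            assert ours[1] == pytest.approx(ci.high, rel=1e-4)


class TestBinomExact:
    def test_printed_cis(self):
        assert binom_exact_ci(9, 189_873_000) == pytest.approx((2.17e-8, 9.0e-8), rel=5e-3)
        assert binom_exact_ci(3, 332_960_000) == pytest.approx((1.86e-9, 2.63e-8), rel=5e-3)

    def test_small_sample_matches_scipy(self):
        for x, n in [(0, 10), (3, 10), (10, 10), (7, 50)]:
            lo, hi = binom_exact_ci(x, n)
            ref = ss.binomtest(x, n).proportion_ci(0.95, method="exact")
            assert (lo, hi) == pytest.approx((ref.low, ref.high), rel=1e-9)

    def test_gamma_path_continuous_with_beta_path(self):
        lo_a, hi_a = binom_exact_ci(5, 999_999)
        lo_b, hi_b = binom_exact_ci(5, 1_000_001)
        assert lo_a == pytest.approx(lo_b, rel=1e-4)
        assert hi_a == pytest.approx(hi_b, rel=1e-4)

    def test_exact_two_sided_example(self):
        assert binom_exact_test(1, 10, 0.5) == pytest.approx(22 / 1024)

    def test_matches_scipy_binomtest(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(5, 200))
            x = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert binom_exact_test(x, n, p0) == pytest.approx(
                ss.binomtest(x, n, p0).pvalue, rel=1e-9
            )

    def test_poisson_path_matches_exact(self):
        for x, n, p0 in [(9, 10**7, 1e-6), (0, 2 * 10**6, 2e-6), (25, 10**7, 1e-6)]:
            assert binom_exact_test(x, n, p0) == pytest.approx(
                ss.binomtest(x, n, p0).pvalue, rel=1e-4
            )

    def test_ci_test_duality_on_grid(self):
        """p0 is rejected at level alpha iff p0 lies outside the CI (up to
        Clopper-Pearson conservativeness, i.e. one-sided agreement)."""
        for x, n in [(2, 20), (7, 30), (0, 15)]:
            lo, hi = binom_exact_ci(x, n)
            for p0 in np.linspace(0.01, 0.99, 57):
                one_sided = 2 * min(
                    ss.binom.cdf(x, n, p0), ss.binom.sf(x - 1, n, p0)
                )
                if lo < p0 < hi:
                    assert one_sided > 0.05 - 1e-12
                elif one_sided < 0.05 - 1e-9:
                    assert not (lo <= p0 <= hi)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            binom_exact_test(1, 10, 0.0)


def ranksum_oracle(xs, ys, two_sided=True):
    """Full enumeration of group assignments with midranks."""
    pooled = list(xs) + list(ys)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    n1 = len(xs)
    mu = n1 * (len(pooled) + 1) / 2
    w_obs = sum(ranks[:n1])
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if two_sided and abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
        elif not two_sided and w >= w_obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_fully_separated_samples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 2], [1, 2, 2]) == 1.0

    def test_symmetry_under_swap(self):
        xs, ys = [1.2, 3.4, 2.2, 8.0], [0.5, 4.4, 9.1]
        assert wilcoxon_rank_sum(xs, ys) == pytest.approx(wilcoxon_rank_sum(ys, xs))

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            xs = rng.integers(0, 5, size=n1).tolist()
            ys = rng.integers(0, 5, size=n2).tolist()
            if len(set(xs + ys)) == 1:
                continue
            assert wilcoxon_rank_sum(xs, ys) == pytest.approx(ranksum_oracle(xs, ys))

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            xs = rng.normal(size=5).tolist()
            ys = rng.normal(size=6).tolist()
            ref = ss.mannwhitneyu(xs, ys, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_rank_sum(xs, ys) == pytest.approx(ref, rel=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(3)
        xs = rng.normal(0, 1, 40).tolist()
        ys = rng.normal(1, 1, 35).tolist()
        ref = ss.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic",
                              use_continuity=False).pvalue
        assert wilcoxon_rank_sum(xs, ys) == pytest.approx(ref, rel=1e-6)

    def test_type_i_error_by_enumeration(self):
        """Under a continuous null with n1=n2=5, the exact rejection rate at
        alpha=0.05 stays at or below 0.06 (computed over all assignments)."""
        values = list(range(10))
        reject = total = 0
        for idx in combinations(range(10), 5):
            xs = [values[i] for i in idx]
            ys = [values[i] for i in range(10) if i not in idx]
            total += 1
            if wilcoxon_rank_sum(xs, ys) <= 0.05:
                reject += 1
        assert reject / total <= 0.06


class TestMultisampleProportion:
    def test_equal_proportions(self):
        assert multisample_proportion_test([10, 10, 10], [1000, 1000, 1000]) > 0.9

    def test_monte_carlo_converges_to_trinomial_enumeration(self):
        x = [5, 0, 0]
        n = [100.0, 100.0, 100.0]
        # exact conditional tail: multinomial(5; 1/3,1/3,1/3) outcomes whose
        # chi-square statistic reaches the observed one
        from itertools import product as iproduct

        from memds.stats import _prop_chi2_stat

        obs_stat = _prop_chi2_stat(np.array(x, float), np.array(n))
        exact = 0.0
        for a in range(6):
            for b in range(6 - a):
                c = 5 - a - b
                stat = _prop_chi2_stat(np.array([a, b, c], float), np.array(n))
                if stat >= obs_stat - 1e-12:
                    exact += (
                        math.factorial(5)
                        / (math.factorial(a) * math.factorial(b) * math.factorial(c))
                        * (1 / 3) ** 5
                    )
        p = multisample_proportion_test(x, n, mode="monte_carlo", n_sim=200_000, rng=9)
        assert p == pytest.approx(exact, rel=0.1)

    def test_exposure_sensitivity(self):
        x = [8, 2]
        p_small = multisample_proportion_test(x, [100, 100])
        p_large = multisample_proportion_test(x, [1000, 1000])
        assert p_small != p_large

    def test_no_events(self):
        assert multisample_proportion_test([0, 0], [10, 10]) == 1.0

    def test_chi2_matches_reference_implementation(self):
        x = [12, 5, 20]
        n = [1000, 800, 1500]
        ref = ss.chi2_contingency(
            np.array([x, [ni - xi for xi, ni in zip(x, n)]]).T, correction=False
        ).pvalue
        assert multisample_proportion_test(x, n) == pytest.approx(ref, rel=1e-9)


class TestMultinomialOmnibus:
    EXPECTED = GWAExpectation({f"t{i}": 1.0 for i in range(12)})

    def test_observed_proportional_to_expected(self):
        obs = {f"t{i}": 10 for i in range(12)}
        assert multinomial_omnibus(obs, self.EXPECTED, n_sim=20_000, rng=0) > 0.9

    def test_concentrated_spectrum_rejected(self):
        obs = {f"t{i}": (45 if i == 0 else 0) for i in range(12)}
        assert multinomial_omnibus(obs, self.EXPECTED, n_sim=10**6, rng=0) < 1e-5

    def test_label_permutation_invariance(self):
        obs = {"t0": 6, "t1": 6, "t2": 2}
        exp = GWAExpectation({"t0": 1.0, "t1": 2.0, "t2": 0.5})
        # renaming types (consistently in observed and expected) preserves p
        ren = {"t0": "u2", "t1": "u0", "t2": "u1"}
        obs2 = {ren[k]: v for k, v in obs.items()}
        exp2 = GWAExpectation({ren[k]: v for k, v in exp.rates.items()})
        p1 = multinomial_omnibus(obs, exp, n_sim=200_000, rng=4)
        p2 = multinomial_omnibus(obs2, exp2, n_sim=200_000, rng=4)
        assert 0.01 < p1 < 0.99  # a moderate tail, so MC error is small
        assert p2 == pytest.approx(p1, rel=0.05)

    def test_missing_type_rejected(self):
        with pytest.raises(ValueError):
            multinomial_omnibus({"zzz": 3}, self.EXPECTED, n_sim=100)

    def test_renormalization_over_subset(self):
        probs = self.EXPECTED.renormalized(["t0", "t3"])
        assert probs == pytest.approx([0.5, 0.5])


class TestTypeIError:
    """Null rejection rates at alpha = 0.05 stay within the conservative
    bound 0.06 (exact tests are conservative, never anticonservative)."""

    def test_binomial_exact(self):
        n, p0 = 30, 0.3
        pvals = np.array([binom_exact_test(x, n, p0) for x in range(n + 1)])
        rng = np.random.default_rng(17)
        draws = rng.binomial(n, p0, size=10_000)
        assert (pvals[draws] <= 0.05).mean() <= 0.06

    def test_fisher_exact_conditional(self):
        r1, r2, c1 = 12, 10, 8
        support = range(max(0, c1 - r2), min(c1, r1) + 1)
        pvals = {a: fisher_exact(Table2x2(a, r1 - a, c1 - a, r2 - (c1 - a))) for a in support}
        rng = np.random.default_rng(29)
        draws = rng.hypergeometric(r1, r2, c1, size=10_000)
        rate = np.mean([pvals[int(a)] <= 0.05 for a in draws])
        assert rate <= 0.06
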