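import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from degdet.stats import (ContingencyTable2x2, DegenerateDataError, bh_adjust,
                          cohens_d, effect_sizes, fisher_exact, mcnemar_test,
                          poisson_rate_test, proportion_ci, rank_biserial,
                          rank_sum_test, ratio_effects, signed_rank_test,
                          spearman_corr)

# ---------------------------------------------------------------------------
# enumeration oracles


def oracle_rank_sum_p(x, y):
    """Two-sided exact p by enumerating all assignments of pooled values."""
    pooled = np.array(list(x) + list(y), dtype=float)
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(subset):
        xs = pooled[list(subset)]
        ys = np.delete(pooled, list(subset))
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_of(range(n1))
    mu = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - mu)
    us = [u_of(s) for s in itertools.combinations(idx, n1)]
    return sum(abs(u - mu) >= dev - 1e-9 for u in us) / len(us)


def oracle_signed_rank_p(deltas):
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.array([v for v in deltas if v != 0], dtype=float)
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev = abs(w_obs - total / 2)
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2) >= dev - 1e-9:
            count += 1
    return count / 2**n


def oracle_fisher_p(a, b, c, d):
    """Two-sided exact p by hypergeometric enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return comb(r1, aa, exact=True) * comb(r2, c1 - aa, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(aa) for aa in range(lo, hi + 1)
               if prob(aa) <= p_obs * (1 + 1e-9))


def oracle_mcnemar_p(b, c):
    """Two-sided exact binomial p over the discordant pairs."""
    n = b + c
    probs = [comb(n, k, exact=True) / 2**n for k in range(n + 1)]
    p_obs = probs[b]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------


class TestRankSum:
    def test_complete_separation_gives_unit_effect(self):
        comp = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert abs(comp.effect_value) == pytest.approx(1.0)

    def test_identical_samples_give_zero_effect(self):
        comp = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert comp.effect_value == pytest.approx(0.0)

    def test_small_sample_exact_p(self):
        comp = rank_sum_test([1, 2], [3])
        assert comp.p_raw == pytest.approx(2 / 3)

    def test_degenerate_identical_values(self):
        with pytest.raises(DegenerateDataError):
            rank_sum_test([5, 5, 5], [5, 5])

    def test_exact_matches_enumeration_on_small_instances(self, rng):
        """Agreement with full rank-assignment enumeration, total n <= 10."""
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
                x, y = vals[:n1], vals[n1:]
                comp = rank_sum_test(x, y)
                assert comp.p_raw == pytest.approx(oracle_rank_sum_p(x, y)), (x, y)

    def test_sign_convention(self):
        # x below y -> positive r under r = 1 - 2U/(n1 n2)
        comp = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert comp.effect_value == pytest.approx(1.0)


class TestSignedRank:
    def test_all_positive_five(self):
        comp = signed_rank_test([1, 2, 3, 4, 5])
        assert comp.p_raw == pytest.approx(2 / 32)
        assert comp.effect_value == pytest.approx(1.0)

    def test_symmetric_deltas_centered(self):
        comp = signed_rank_test([1, -1, 2, -2, 3, -3])
        assert comp.effect_value == pytest.approx(0.0)
        assert comp.p_raw == pytest.approx(1.0)

    def test_single_delta(self):
        assert signed_rank_test([2.0]).p_raw == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            signed_rank_test([0.0, 0.0])

    def test_exact_matches_sign_enumeration(self, rng):
        for n in range(1, 9):
            for _ in range(5):
                deltas = rng.integers(-5, 6, n).astype(float)
                if (deltas == 0).all():
                    continue
                comp = signed_rank_test(deltas)
                assert comp.p_raw == pytest.approx(oracle_signed_rank_p(deltas)), deltas


class TestFisher:
    def test_identical_rows_null(self):
        comp = fisher_exact(ContingencyTable2x2(10, 90, 10, 90))
        assert comp.p_raw == pytest.approx(1.0)
        assert comp.effect_value == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_table(self):
        comp = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert comp.p_raw == pytest.approx(2 / 252)

    def test_haldane_corrected_sample_or(self):
        comp = fisher_exact(ContingencyTable2x2(0, 10, 10, 0))
        expected = (0.5 * 0.5) / (10.5 * 10.5)
        assert comp.extra["sample_odds_ratio"] == pytest.approx(expected)
        assert comp.extra["haldane_corrected"]

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_matches_hypergeometric_enumeration(self):
        """All 2x2 tables with total n <= 10 agree with the enumeration oracle."""
        for total in range(1, 11):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        if (a + b == 0 and c + d == 0):
                            continue
                        comp = fisher_exact(ContingencyTable2x2(a, b, c, d))
                        assert comp.p_raw == pytest.approx(
                            oracle_fisher_p(a, b, c, d), abs=1e-10), (a, b, c, d)


class TestMcNemar:
    def test_symmetric_discordance(self):
        assert mcnemar_test(10, 10).p_raw == pytest.approx(1.0)

    def test_one_sided_discordance(self):
        assert mcnemar_test(5, 0).p_raw == pytest.approx(0.0625)

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(DegenerateDataError):
            mcnemar_test(0, 0)

    def test_matches_binomial_enumeration(self):
        for b in range(0, 11):
            for c in range(0, 11 - b):
                if b + c == 0:
                    continue
                comp = mcnemar_test(b, c)
                assert comp.p_raw == pytest.approx(oracle_mcnemar_p(b, c)), (b, c)


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.random(40)
        adj = np.array(bh_adjust(p))
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestProportionCi:
    # frozen from R prop.test(x, n)$conf.int (Wilson with continuity correction)
    R_VALUES = {
        (50, 100): (0.4038315304, 0.5961684696),
        (7, 19): (0.1723002082, 0.6136729256),
        (0, 10): (0.0, 0.3445372183),
        (10, 10): (0.6554627817, 1.0),
        (1, 1000): (0.0000522024, 0.0064687850),
    }

    @pytest.mark.parametrize("xn,expected", sorted(R_VALUES.items()))
    def test_matches_r_prop_test(self, xn, expected):
        lo, hi = proportion_ci(*xn)
        assert lo == pytest.approx(expected[0], abs=1e-8)
        assert hi == pytest.approx(expected[1], abs=1e-8)

    def test_boundary_clamps(self):
        assert proportion_ci(0, 10)[0] == 0.0
        assert proportion_ci(10, 10)[1] == 1.0

    def test_symmetric_at_half(self):
        lo, hi = proportion_ci(50, 100)
        assert lo + hi == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman_corr([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        assert spearman_corr([1, 2, 3], [2, 1, 3]).statistic == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    def test_exact_small_n_p_is_permutation_fraction(self):
        # perfect monotone triple: |rho| = 1 in 2 of the 6 rank permutations
        comp = spearman_corr([1, 2, 3], [10, 20, 30])
        assert comp.p_raw == pytest.approx(2 / 6)
        # |rho| >= 0.5 holds for every permutation of 3 ranks
        assert spearman_corr([1, 2, 3], [2, 1, 3]).p_raw == pytest.approx(1.0)


class TestPoissonRate:
    def test_equal_rates(self):
        comp = poisson_rate_test(10, 1000, 10, 1000)
        assert comp.p_raw == pytest.approx(1.0)
        assert comp.effect_value == pytest.approx(1.0)

    def test_zero_numerator(self):
        comp = poisson_rate_test(0, 1000, 20, 1000)
        assert comp.effect_value == 0.0
        assert comp.ci[0] == 0.0 and comp.ci[1] > 0

    def test_conditional_binomial_p(self):
        from scipy.stats import binomtest
        comp = poisson_rate_test(30, 1000, 10, 1000)
        assert comp.p_raw == pytest.approx(binomtest(30, 40, 0.5).pvalue)

    def test_both_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            poisson_rate_test(0, 10, 0, 10)

    def test_exposure_scales_rate_ratio(self):
        comp = poisson_rate_test(10, 100, 10, 1000)
        assert comp.effect_value == pytest.approx(10.0)


class TestEffectSizes:
    def test_cohens_d_zero_for_identical(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_cohens_d_location_shift(self, rng):
        x = rng.normal(0, 1, 500)
        y = x + 1.0  # identical sample SD; d = shift / sample SD exactly
        assert cohens_d(y, x) == pytest.approx(1.0 / x.std(ddof=1))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([2, 2, 2], [2, 2, 2])

    def test_risk_ratio_hand_example(self):
        eff = ratio_effects(ContingencyTable2x2(20, 80, 10, 90))
        assert eff["risk_ratio"] == pytest.approx(2.0)

    def test_bundle_contents(self):
        out = effect_sizes(x=[1, 2, 3, 4], y=[2, 3, 4, 5],
                           table=ContingencyTable2x2(20, 80, 10, 90))
        assert {"cohens_d", "rank_biserial", "risk_ratio", "odds_ratio"} <= set(out)
        with pytest.raises(ValueError):
            effect_sizes()

    def test_rank_biserial_formula(self):
        # x entirely below y: U1 = 0 -> r = 1
        assert rank_biserial([1, 2], [5, 6]) == pytest.approx(1.0)
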