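"""Dataset statistics: coverage/redundancy, normalized increases,
paired and Welch t tests against reference implementations."""

import numpy as np
import pytest
from scipy import stats as sps

from hdxdiff.stats import (
    compare_all_peptides,
    coverage_redundancy,
    jaccard_index,
    normalized_increase,
    paired_t_test,
    peptide_state_comparison,
    welch_t_test,
)
from hdxdiff.uptake import UptakeStat, replicate_stats
from oracles import oracle_coverage_redundancy, random_peptide_map


class TestCoverageRedundancy:
    def test_worked_example(self):
        rep = coverage_redundancy([(1, 10), (5, 15)], 20)
        assert rep.coverage_percent == pytest.approx(75.0)
        assert rep.mean_redundancy == pytest.approx(21 / 15)

    def test_no_peptides_flagged(self):
        rep = coverage_redundancy([], 20)
        assert rep.coverage_percent == 0.0
        assert rep.undefined_redundancy and np.isnan(rep.mean_redundancy)

    def test_full_single_peptide(self):
        rep = coverage_redundancy([(1, 20)], 20)
        assert (rep.coverage_percent, rep.mean_redundancy) == (100.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            length, peps = random_peptide_map(rng)
            rep = coverage_redundancy(peps, length)
            cov, red = oracle_coverage_redundancy(peps, length)
            assert rep.coverage_percent == pytest.approx(cov, abs=1e-12)
            if peps and not rep.undefined_redundancy:
                assert rep.mean_redundancy == pytest.approx(red, abs=1e-12)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            coverage_redundancy([(1, 2)], 0)


class TestNormalizedIncrease:
    def test_no_increase_is_zero(self):
        assert normalized_increase([2.0, 2.0], [2.0, 2.0]).value == 0.0

    def test_doubling_is_one(self):
        assert normalized_increase([1.0, 1.0], [2.0, 2.0]).value == pytest.approx(1.0)

    def test_arithmetic(self):
        assert normalized_increase([2.0] * 3, [2.5] * 3).value == pytest.approx(0.25)

    def test_replicate_pairing(self):
        res = normalized_increase([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.per_replicate == pytest.approx((0.5, 0.5, 0.5))
        assert res.sd == 0.0

    def test_nonpositive_denominator_excluded(self):
        res = normalized_increase([0.0, 0.0], [1.0, 1.0])
        assert res.excluded and np.isnan(res.value)


class TestPairedT:
    def test_identical_lists(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)
        assert res.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t_test([1, 2, 3], [2, 3, 4])
        assert res.degenerate and res.p == 0.0 and np.isinf(res.t)

    def test_matches_reference_on_example(self):
        a = [1.1, 2.0, 2.9, 4.2]
        b = [1.0, 1.8, 3.1, 3.9]
        res = paired_t_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == 3

    def test_matches_reference_on_random_fixtures(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = a + rng.normal(0.2, 0.5, size=n)
            res = paired_t_test(a, b)
            ref = sps.ttest_rel(a, b)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=8)
        fwd, rev = paired_t_test(a, b), paired_t_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_test([1, np.nan, 3], [1, 2, 3])


class TestWelch:
    def test_matches_reference_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(0, 1, size=int(rng.integers(3, 10)))
            y = rng.normal(0.5, 2, size=int(rng.integers(3, 10)))
            mine = welch_t_test(replicate_stats(x), replicate_stats(y))
            ref = sps.ttest_ind(y, x, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_stats_not_significant(self):
        s = UptakeStat(1.0, 0.1, 3)
        res = peptide_state_comparison(s, s)
        assert not res.significant

    def test_large_effect_significant(self):
        ref = UptakeStat(1.0, 0.1, 3)
        pert = UptakeStat(2.0, 0.1, 3)  # 10 pooled SDs apart
        res = peptide_state_comparison(ref, pert, alpha=0.05)
        assert res.significant
        # cross-check p against the reference implementation
        refp = sps.ttest_ind_from_stats(2.0, 0.1, 3, 1.0, 0.1, 3, equal_var=False).pvalue
        assert res.min_p == pytest.approx(refp, abs=1e-10)

    def test_zero_variance_equal_means_degenerate_not_significant(self):
        s = UptakeStat(1.0, 0.0, 3)
        res = peptide_state_comparison(s, s)
        assert not res.significant
        assert next(iter(res.per_time.values())).degenerate

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test(UptakeStat(1.0, 0.0, 1, True), UptakeStat(1.0, 0.1, 3))

    def test_per_time_and_overall_flags(self):
        ref = {1.0: UptakeStat(1.0, 0.1, 3), 10.0: UptakeStat(1.0, 0.1, 3)}
        pert = {1.0: UptakeStat(1.05, 0.1, 3), 10.0: UptakeStat(3.0, 0.1, 3)}
        res = peptide_state_comparison(ref, pert)
        assert res.significant and res.significant_times == (10.0,)


class TestCompareAllPeptides:
    def test_bh_correction_fields_present(self):
        stats = {
            (1, 10): {1.0: (UptakeStat(1.0, 0.1, 3), UptakeStat(1.1, 0.1, 3))},
            (5, 15): {1.0: (UptakeStat(1.0, 0.1, 3), UptakeStat(4.0, 0.1, 3))},
        }
        recs = compare_all_peptides(stats)
        assert {r["peptide"] for r in recs} == {(1, 10), (5, 15)}
        assert all("p_adjusted" in r for r in recs)
        strong = next(r for r in recs if r["peptide"] == (5, 15))
        assert strong["significant"]


class TestTypeIError:
    def test_null_rejection_rate_within_binomial_ci(self):
        """Uncorrected Welch calls on pure-noise replicate data hold the
        nominal level within the binomial 99% CI (10 replicates per
        state, where the Welch-Satterthwaite approximation is accurate)."""
        rng = np.random.default_rng(2024)
        alpha, n_tests = 0.05, 4000
        rejections = 0
        for _ in range(n_tests):
            ref = replicate_stats(rng.normal(1.0, 0.1, 10))
            pert = replicate_stats(rng.normal(1.0, 0.1, 10))
            if welch_t_test(ref, pert).p < alpha:
                rejections += 1
        lo, hi = sps.binom.interval(0.99, n_tests, alpha)
        assert lo <= rejections <= hi

    def test_triplicate_null_rate_never_anti_conservative(self):
        """With triplicates (the usual design) Welch is known to be
        slightly conservative; the null rejection rate must not exceed
        the upper binomial bound at the nominal level."""
        rng = np.random.default_rng(7)
        alpha, n_tests = 0.05, 4000
        rejections = sum(
            welch_t_test(replicate_stats(rng.normal(0, 1, 3)),
                         replicate_stats(rng.normal(0, 1, 3))).p < alpha
            for _ in range(n_tests)
        )
        _, hi = sps.binom.interval(0.99, n_tests, alpha)
        assert rejections <= hi


def test_jaccard_basics():
    assert jaccard_index({1, 2}, {2, 3}) == pytest.approx(1 / 3)
    assert jaccard_index(set(), set()) == 1.0
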