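"""Null simulation, Monte-Carlo P-values, BH calling and the bias QC."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mamscan.genotyping import LocusSummary, call_genotypes
from mamscan.hwe_screen import (
    HweTestResult,
    ScreenConfig,
    bh_threshold,
    het_call_probability,
    het_deficit_pvalue,
    locus_rng,
    reference_bias_qc,
    simulate_null_het_count,
    two_stage_screen,
    results_frame,
)
from mamscan.simulate import SimulationParams, simulate_methylcap

from conftest import make_table


def summary(p_hat, coverages, het_observed=0, chrom="1", pos=100):
    return LocusSummary(chrom=chrom, pos=pos, p_hat=p_hat,
                        het_observed=het_observed,
                        coverages=np.asarray(coverages, dtype=np.int64))


def exact_null_het_pmf(p_hat, coverages):
    """Exhaustive enumeration of the genotype x read outcome space.

    For each sample enumerate genotype in {AA, Aa, aa} and, for Aa, every
    ref-read count; record whether the sample is called heterozygous. The
    het-count distribution is the product over independent samples.
    """
    q = 1.0 - p_hat
    pmf = np.array([1.0])
    for c in coverages:
        p_het_called = 0.0
        for k in range(int(c) + 1):  # ref reads of a heterozygote
            if 0 < k < c:
                p_het_called += 2 * p_hat * q * stats.binom.pmf(k, c, 0.5)
        pmf = np.convolve(pmf, [1.0 - p_het_called, p_het_called])
    return pmf


class TestNullSimulation:
    def test_coverage_one_never_calls_het(self):
        s = summary(0.5, [1, 1, 1])
        rng = np.random.default_rng(0)
        assert all(simulate_null_het_count(s, rng) == 0 for _ in range(200))

    def test_coverage_two_closed_form(self):
        """P(het called) = 2pq (1 - 2 (1/2)^c) = 0.25 at p=0.5, c=2."""
        # enumeration of the 2-read outcome space agrees with the closed form
        assert exact_null_het_pmf(0.5, [2])[1] == pytest.approx(0.25)
        s = summary(0.5, [2])
        rng = np.random.default_rng(1)
        draws = [simulate_null_het_count(s, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(0.25, abs=0.005)

    def test_large_coverage_limit_is_2pq(self):
        assert het_call_probability(0.5, np.array([1000]))[0] == pytest.approx(0.5)

    def test_untestable_locus_raises(self):
        with pytest.raises(ValueError):
            simulate_null_het_count(summary(1.0, [5]), np.random.default_rng(0))


class TestHetDeficitPvalue:
    def test_all_het_gives_p_one(self):
        s = summary(0.5, [30] * 10, het_observed=10)
        p = het_deficit_pvalue(s, 1000, np.random.default_rng(0))
        assert p == pytest.approx(1.0, abs=1 / 1001)

    def test_zero_het_among_many_well_covered_samples_hits_floor(self):
        # P(null het count = 0) ~ 0.5^100: no replicate can reach 0
        s = summary(0.5, [30] * 100, het_observed=0)
        p = het_deficit_pvalue(s, 1000, np.random.default_rng(0))
        assert p == pytest.approx(1 / 1001)

    @pytest.mark.parametrize("p_hat,covs,het_obs", [
        (0.5, [1, 2, 3], 0),
        (0.5, [2, 2, 3, 3], 1),
        (0.3, [3, 3, 1], 0),
        (0.7, [2, 3, 3, 2], 2),
    ])
    def test_matches_exhaustive_enumeration_oracle(self, p_hat, covs, het_obs):
        """Monte-Carlo P within 3 standard errors of the exact tail."""
        B = 100_000
        pmf = exact_null_het_pmf(p_hat, covs)
        exact_tail = pmf[: het_obs + 1].sum()
        exact_p = (1 + B * exact_tail) / (1 + B)  # expectation of the estimator
        s = summary(p_hat, covs, het_observed=het_obs)
        p = het_deficit_pvalue(s, B, np.random.default_rng(11))
        se = np.sqrt(exact_tail * (1 - exact_tail) / B)
        assert abs(p - exact_p) <= 3 * se + 1e-12

    def test_coverage_one_locus_always_p_one(self):
        s = summary(0.5, [1] * 20, het_observed=0)
        assert het_deficit_pvalue(s, 2000, np.random.default_rng(3)) == 1.0


class TestTwoStageScreen:
    def test_gate_keeps_stage2_absent_for_large_p(self):
        table, _ = simulate_methylcap(
            SimulationParams(n_loci=20, n_samples=80, seed=2)
        )
        results, _ = two_stage_screen(table, ScreenConfig(b1=200, b2=500, seed=1))
        for r in results:
            if r.p_stage1 is not None and r.p_stage1 > 0.005:
                assert r.p_stage2 is None
                assert r.p_final == r.p_stage1
            if r.p_stage2 is not None:
                assert r.p_stage1 <= 0.005

    def test_reproducible_and_order_invariant(self):
        table, _ = simulate_methylcap(
            SimulationParams(n_loci=15, n_samples=60, seed=4)
        )
        res_a, _ = two_stage_screen(table, ScreenConfig(b1=300, b2=500, seed=9))
        perm = np.random.default_rng(0).permutation(table.n_loci)
        res_b, _ = two_stage_screen(
            table.subset_loci(perm), ScreenConfig(b1=300, b2=500, seed=9)
        )
        by_pos_a = {(r.chrom, r.pos): r.p_final for r in res_a}
        by_pos_b = {(r.chrom, r.pos): r.p_final for r in res_b}
        assert by_pos_a == by_pos_b

    def test_monoallelic_loci_reach_stage2_floor(self):
        params = SimulationParams(
            n_loci=30, n_samples=300, frac_monoallelic=1.0, seed=6
        )
        table, _ = simulate_methylcap(params)
        results, _ = two_stage_screen(
            table, ScreenConfig(b1=500, b2=10_000, seed=2)
        )
        floors = [r.p_final == pytest.approx(1 / 10_001) for r in results
                  if r.p_final is not None]
        assert np.mean(floors) >= 0.9

    def test_monotone_power_in_coverage_and_sample_count(self):
        """Rejection rate at monoallelic loci is non-decreasing along both
        axes of a (depth x samples) grid, up to small sampling noise."""
        rates = np.zeros((3, 3))
        for i, depth in enumerate((2.0, 5.0, 10.0)):
            for j, n_samples in enumerate((50, 150, 300)):
                params = SimulationParams(
                    n_loci=25, n_samples=n_samples, frac_monoallelic=1.0,
                    depth_mean=depth, seed=10 + i * 3 + j,
                )
                table, _ = simulate_methylcap(params)
                results, _ = two_stage_screen(
                    table, ScreenConfig(b1=400, b2=1000, seed=1)
                )
                p = np.array([r.p_final for r in results
                              if r.p_final is not None])
                rates[i, j] = (p <= 0.005).mean()
        assert (np.diff(rates, axis=0) >= -0.02 - 1e-9).all()
        assert (np.diff(rates, axis=1) >= -0.02 - 1e-9).all()


class TestBhThreshold:
    def test_hand_worked_step_function(self):
        crit, flags = bh_threshold(np.array([0.001, 0.02, 0.9]), 0.1)
        assert crit == pytest.approx(2 * 0.1 / 3)
        assert list(flags) == [True, True, False]

    def test_all_ones_rejects_nothing(self):
        crit, flags = bh_threshold(np.ones(10), 0.1)
        assert crit == 0.0 and not flags.any()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 1e-3, 20), rng.uniform(0, 1, 200)])
        crit, flags = bh_threshold(p, 0.05)
        expected, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(flags, expected)


class TestReferenceBiasQc:
    def _setup(self, ref_covs, alt_covs):
        n = len(ref_covs) + len(alt_covs)
        refs = list(ref_covs) + [0] * len(alt_covs)
        alts = [0] * len(ref_covs) + list(alt_covs)
        table = make_table([("1", 100, "A", "G", refs, alts)])
        gm = call_genotypes(table)
        res = [HweTestResult("1", 100, 0, n, 0.5, 0.001, None, significant=True)]
        return res, gm, table

    def test_identical_distributions_give_large_p(self):
        res, gm, table = self._setup([10] * 15, [10] * 15)
        qc = reference_bias_qc(res, gm, table)
        assert qc.assessable and qc.p_value == pytest.approx(1.0)

    def test_complete_separation_gives_small_p(self):
        res, gm, table = self._setup(list(range(10, 30)),
                                     [10 * c for c in range(10, 30)])
        qc = reference_bias_qc(res, gm, table)
        assert qc.p_value < 0.01

    def test_single_observation_per_class_exact_p_one(self):
        res, gm, table = self._setup([5], [7])
        qc = reference_bias_qc(res, gm, table)
        assert qc.p_value == pytest.approx(1.0)

    def test_one_class_empty_not_assessable(self):
        res, gm, table = self._setup([5, 6], [])
        qc = reference_bias_qc(res, gm, table)
        assert not qc.assessable and qc.reason is not None


class TestNullCalibration:
    def test_screen_is_calibrated_on_null_simulations(self):
        """Type-I error at nominal 0.05 within +/-0.02 and KS uniformity."""
        from mamscan.genotyping import correct_sequencing_errors, filter_loci

        params = SimulationParams(n_loci=500, n_samples=300,
                                  frac_monoallelic=0.0, seed=0)
        table, _ = simulate_methylcap(params)
        corrected = correct_sequencing_errors(filter_loci(table))
        results, _ = two_stage_screen(
            corrected, ScreenConfig(b1=1000, b2=20_000, seed=0)
        )
        p = np.array([r.p_final for r in results if r.p_final is not None])
        assert len(p) >= 450
        assert abs((p <= 0.05).mean() - 0.05) <= 0.02
        ks = stats.kstest(p, "uniform").statistic
        assert ks <= 1.628 / np.sqrt(len(p))  # 1% critical value
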