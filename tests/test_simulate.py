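"""Haplotype-pool construction and cohort simulation."""

import numpy as np
import pandas as pd
import pytest

from eqtlkit.datatypes import GenotypeMatrix
from eqtlkit.scan import rho_pvalue, spearman_rho
from eqtlkit.simulate import (
    EffectModel,
    HaplotypePool,
    InfeasibleLDError,
    QuotaError,
    make_haplotype_pool,
    simulate_case_control,
    simulate_expression,
    simulate_genotypes,
)

from conftest import make_snp_meta


class TestMakeHaplotypePool:
    def test_single_snp_pool(self):
        pool = make_haplotype_pool(1, [(1, 0.0)], [0.3])
        assert sorted(pool.frequencies) == pytest.approx([0.3, 0.7])
        assert len(pool.haplotypes) == 2

    def test_perfect_ld_forces_two_haplotypes(self):
        pool = make_haplotype_pool(2, [(2, 1.0)], [0.3, 0.3])
        assert len(pool.haplotypes) == 2
        assert sorted(pool.frequencies) == pytest.approx([0.3, 0.7])
        _, r2, dp = pool.exact_ld("rs1", "rs2")
        assert r2 == pytest.approx(1.0) and dp == pytest.approx(1.0)

    def test_requested_r2_is_exact_for_pair(self):
        pool = make_haplotype_pool(2, [(2, 0.4)], [0.31, 0.17])
        assert pool.mafs() == pytest.approx([0.31, 0.17], abs=1e-9)
        _, r2, _ = pool.exact_ld("rs1", "rs2")
        assert r2 == pytest.approx(0.4, abs=1e-6)

    def test_infeasible_maf_correlation_is_reported(self):
        # Dmax = min(0.31*0.83, 0.69*0.17) caps r2 at ~0.456 for these MAFs
        with pytest.raises(InfeasibleLDError):
            make_haplotype_pool(2, [(2, 0.5)], [0.31, 0.17])

    def test_blocks_meet_r2_floor_and_are_independent(self):
        mafs = [0.3, 0.35, 0.3, 0.3, 0.3, 0.3]
        pool = make_haplotype_pool(6, [(3, 0.5), (3, 0.8)], mafs)
        assert np.abs(pool.mafs() - mafs).max() < 1e-9
        ids = pool.snp_ids
        for block, floor in (((0, 1, 2), 0.5), ((3, 4, 5), 0.8)):
            for a in block:
                for b in block:
                    if a < b:
                        _, r2, _ = pool.exact_ld(ids[a], ids[b])
                        assert r2 >= floor - 1e-9
        _, r2_cross, _ = pool.exact_ld(ids[0], ids[3])
        assert r2_cross == pytest.approx(0.0, abs=1e-12)

    def test_frequencies_sum_to_one(self):
        pool = make_haplotype_pool(4, [(2, 0.9), (2, 0.5)], [0.3, 0.3, 0.3, 0.4])
        assert pool.frequencies.sum() == pytest.approx(1.0, abs=1e-9)


class TestSimulateGenotypes:
    def test_degenerate_single_haplotype_pool(self):
        meta = make_snp_meta(["rs1"], [("A", "G")])
        pool = HaplotypePool(["G"], np.array([1.0]), meta)  # major-only
        g = simulate_genotypes(pool, 5, seed=0)
        assert (g.dosages == 0).all()

    def test_allele_frequency_within_three_binomial_se(self):
        pool = make_haplotype_pool(1, [(1, 0.0)], [0.3])
        g = simulate_genotypes(pool, 10000, seed=11)
        freq = g.dosages.mean() / 2
        se = np.sqrt(0.3 * 0.7 / (2 * 10000))
        assert abs(freq - 0.3) < 3 * se

    def test_empirical_r2_converges_to_pool_r2(self, pool2):
        from eqtlkit.popgen import pairwise_ld

        g = simulate_genotypes(pool2, 5000, seed=5)
        _, exact_r2, _ = pool2.exact_ld("rs1", "rs2")
        assert pairwise_ld(g, "rs1", "rs2").r2 == pytest.approx(exact_r2, abs=0.05)

    def test_same_seed_reproduces_identical_matrix(self, pool2):
        a = simulate_genotypes(pool2, 50, seed=42)
        b = simulate_genotypes(pool2, 50, seed=42)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.sample_ids == b.sample_ids
        c = simulate_genotypes(pool2, 50, seed=43)
        assert not np.array_equal(a.dosages, c.dosages)


class TestSimulateExpression:
    def test_noiseless_additive_ratio_is_fold_squared(self, pool2):
        g = simulate_genotypes(pool2, 400, seed=1)
        e = simulate_expression(g, EffectModel("rs1", "additive", 1.8, 0.0), seed=2)
        d = g.dosage_vector("rs1")
        v = e.values[0]
        assert v[d == 2].mean() / v[d == 0].mean() == pytest.approx(3.24)
        assert v[d == 1].mean() / v[d == 0].mean() == pytest.approx(1.8)

    def test_noiseless_dominant_groups_collapse(self, pool2):
        g = simulate_genotypes(pool2, 400, seed=1)
        e = simulate_expression(g, EffectModel("rs1", "dominant", 1.6, 0.0), seed=2)
        d = g.dosage_vector("rs1")
        v = e.values[0]
        assert v[d == 1].mean() == pytest.approx(v[d == 2].mean())
        assert v[d == 1].mean() / v[d == 0].mean() == pytest.approx(1.6)

    def test_unknown_causal_snp_rejected(self, pool2):
        g = simulate_genotypes(pool2, 10, seed=1)
        with pytest.raises(KeyError):
            simulate_expression(g, EffectModel("rs_nope"), seed=0)

    def test_null_effect_keeps_nominal_false_positive_rate(self, pool2):
        # fold = 1: dosage and expression independent; alpha=0.05 test should
        # stay non-significant in >= 94% of 500 replicates
        not_sig = 0
        for rep in range(500):
            g = simulate_genotypes(pool2, 40, seed=1000 + rep)
            e = simulate_expression(g, EffectModel("rs1", "additive", 1.0, 0.3), seed=rep)
            d = g.dosage_vector("rs1")
            if len(np.unique(d)) < 2:
                not_sig += 1
                continue
            rho = spearman_rho(d, e.values[0])
            if rho_pvalue(rho, len(d)) >= 0.05:
                not_sig += 1
        assert not_sig >= 0.94 * 500

    def test_effect_size_recovery_additive(self, pool2):
        # log(mean ratio 2 vs 0) / 2 recovers log(per_allele_fold) within 10%
        logs = []
        for rep in range(50):
            g = simulate_genotypes(pool2, 500, seed=300 + rep)
            e = simulate_expression(g, EffectModel("rs1", "additive", 1.8, 0.3), seed=rep)
            d = g.dosage_vector("rs1")
            v = e.values[0]
            logs.append(np.log(v[d == 2].mean() / v[d == 0].mean()) / 2)
        assert np.mean(logs) == pytest.approx(np.log(1.8), rel=0.10)


class TestSimulateCaseControl:
    def test_null_odds_ratio_gives_equal_frequencies(self, pool2):
        g, ph = simulate_case_control(pool2, "AC", 1.0, 0.1, 1500, 1500, seed=9)
        d = g.dosage_vector("rs1")
        f_case = d[ph.status == 1].mean() / 2
        f_ctrl = d[ph.status == 0].mean() / 2
        se = np.sqrt(2 * 0.5 * 0.5 / (2 * 1500))
        assert abs(f_case - f_ctrl) < 4 * se

    def test_wildcard_risk_pattern_matches_allele(self, pool2):
        ind = pool2.match_indicator("A*")
        np.testing.assert_array_equal(ind, [1.0, 1.0, 0.0, 0.0])
        assert pool2.match_indicator("ZZ").sum() == 0
        with pytest.raises(ValueError, match="matches no pool haplotype"):
            simulate_case_control(pool2, "ZZ", 2.0, 0.1, 10, 10, seed=0)
        with pytest.raises(ValueError, match="length"):
            pool2.match_indicator("A")

    def test_determinism_and_quota_error(self, pool2):
        a = simulate_case_control(pool2, "AC", 2.0, 0.1, 100, 100, seed=3)
        b = simulate_case_control(pool2, "AC", 2.0, 0.1, 100, 100, seed=3)
        np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
        np.testing.assert_array_equal(a[1].status, b[1].status)
        with pytest.raises(QuotaError):
            simulate_case_control(
                pool2, "AC", 1.0, 0.001, 5000, 10, seed=3, max_draws=20000
            )

    def test_cases_enriched_for_risk_haplotype(self, pool2):
        g, ph = simulate_case_control(pool2, "AT", 3.0, 0.05, 1000, 1000, seed=7)
        # AT is the only haplotype carrying minor alleles at both SNPs
        both = (g.dosages >= 1).all(axis=1)
        assert both[ph.status == 1].mean() > both[ph.status == 0].mean()


def test_pool_validation_rejects_bad_frequencies():
    meta = make_snp_meta(["rs1"], [("A", "G")])
    with pytest.raises(ValueError):
        HaplotypePool(["A", "G"], np.array([0.6, 0.6]), meta)
    with pytest.raises(ValueError):
        HaplotypePool(["A", "GG"], np.array([0.5, 0.5]), meta)
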