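"""Spearman correlation, permutation thresholds and genotype-group summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from eqtlkit.datatypes import ExpressionMatrix
from eqtlkit.popgen import UndefinedStatisticError
from eqtlkit.scan import (
    ScanConfig,
    cis_scan,
    genotype_group_summary,
    kruskal_wallis,
    permutation_threshold,
    rho_pvalue,
    spearman_rho,
)
from eqtlkit.simulate import EffectModel, make_haplotype_pool, simulate_expression, simulate_genotypes

from conftest import geno_from_dosages


def expr_of(values, sample_ids, feature="GENE1"):
    return ExpressionMatrix([feature], sample_ids, np.asarray(values, dtype=float)[None, :])


class TestSpearmanRho:
    def test_perfect_monotone(self):
        assert spearman_rho([0, 1, 2], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_tied_example_matches_midrank_oracle(self):
        # mid-rank Pearson by hand: ranks x = (1.5,1.5,3.5,3.5,5.5,5.5),
        # ranks y = (6..1) -> rho = -16/sqrt(16*17.5)
        rho = spearman_rho([0, 0, 1, 1, 2, 2], [5, 4, 3, 2, 1, 0])
        assert rho == pytest.approx(-16 / np.sqrt(16 * 17.5), abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([0, 1, 2, 0, 1, 2], [1, 1, 1, 1, 1, 1])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman_rho([0, 1, np.nan], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 15).astype(float)
        y = rng.normal(size=15).round(1)  # ties likely
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            return
        rho = spearman_rho(x, y)
        assert spearman_rho(x, np.exp(y)) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(-x, y) == pytest.approx(-rho, abs=1e-12)


class TestRhoPvalue:
    def test_zero_rho_gives_one(self):
        assert rho_pvalue(0.0, 30) == 1.0

    def test_unit_rho_gives_smallest_positive(self):
        p = rho_pvalue(1.0, 10)
        assert 0 < p < 1e-300

    def test_matches_t_tail_quadrature_oracle(self):
        rho, n = 0.5, 30
        t_obs = rho * np.sqrt((n - 2) / (1 - rho**2))
        tail, _ = integrate.quad(lambda u: stats.t.pdf(u, n - 2), t_obs, np.inf)
        assert rho_pvalue(rho, n) == pytest.approx(2 * tail, abs=1e-10)

    def test_published_order_of_magnitude(self):
        # rho 0.731 in a 60-sample RNA-Seq cohort: p printed as 3.22E-11
        p = rho_pvalue(0.731, 60)
        assert 1e-12 < p < 1e-10

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rho_pvalue(0.5, 3)


@pytest.fixture(scope="module")
def cohort():
    pool = make_haplotype_pool(
        6, [(3, 0.7), (3, 0.6)], [0.3] * 6,
        positions=[29677984, 29700000, 29800000, 30000000, 31000000, 33485635],
    )
    geno = simulate_genotypes(pool, 120, seed=100)
    expr = simulate_expression(geno, EffectModel("rs2", "additive", 1.8, 0.3), seed=101)
    return geno, expr


class TestCisScan:
    def test_empty_region_gives_empty_list(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 1, 2, n_permutations=10, pt=0.05, seed=0)
        assert cis_scan(geno, expr, "GENE1", cfg) == []

    def test_missing_feature_rejected(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 1, 10**9, n_permutations=10, pt=0.05, seed=0)
        with pytest.raises(KeyError):
            cis_scan(geno, expr, "NOPE", cfg)

    def test_records_ordered_by_position_with_region_bounds(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 29677984, 31000000, n_permutations=50, pt=0.05, seed=1)
        recs = cis_scan(geno, expr, "GENE1", cfg)
        assert [r.snp_id for r in recs] == ["rs1", "rs2", "rs3", "rs4", "rs5"]
        assert all(a.position <= b.position for a, b in zip(recs, recs[1:]))

    def test_causal_snp_is_top_hit_at_strong_effect(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 1, 10**9, n_permutations=100, pt=0.01, seed=2)
        recs = cis_scan(geno, expr, "GENE1", cfg)
        top = max(recs, key=lambda r: abs(r.rho) if r.rho is not None else -1)
        assert top.snp_id == "rs2"
        assert top.significant

    def test_determinism_under_fixed_seed(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 1, 10**9, n_permutations=200, pt=0.01, seed=7)
        a = permutation_threshold(geno, expr, "GENE1", cfg)
        b = permutation_threshold(geno, expr, "GENE1", cfg)
        assert a.threshold_p == b.threshold_p
        np.testing.assert_array_equal(a.significant, b.significant)
        np.testing.assert_array_equal(a.null_min_p, b.null_min_p)

    def test_constant_expression_yields_no_significance(self, cohort):
        geno, _ = cohort
        expr = expr_of(np.ones(120), geno.sample_ids)
        cfg = ScanConfig("6", 1, 10**9, n_permutations=50, pt=0.05, seed=3)
        recs = cis_scan(geno, expr, "GENE1", cfg)
        assert recs and not any(r.significant for r in recs)
        assert all(r.rho is None for r in recs)

    def test_monomorphic_snp_reported_not_significant(self):
        dos = np.column_stack([np.zeros(30), np.tile([0, 1, 2], 10)])
        geno = geno_from_dosages(dos)
        rng = np.random.default_rng(4)
        expr = expr_of(rng.normal(size=30), geno.sample_ids)
        cfg = ScanConfig("6", 1, 10**9, n_permutations=50, pt=0.05, seed=4)
        recs = cis_scan(geno, expr, "GENE1", cfg)
        mono = next(r for r in recs if r.snp_id == "rs1")
        assert mono.rho is None and not mono.significant and mono.note

    def test_empirical_p_bounds_and_monotonicity(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 1, 10**9, n_permutations=200, pt=0.01, seed=5)
        res = permutation_threshold(geno, expr, "GENE1", cfg)
        ok = res.defined
        assert (res.p_empirical[ok] >= 1 / 201).all()
        assert (res.p_empirical[ok] <= 1.0).all()
        order = np.argsort(res.p_nominal[ok])
        assert (np.diff(res.p_empirical[ok][order]) >= 0).all()

    def test_pt_below_resolution_warns(self, cohort):
        geno, expr = cohort
        cfg = ScanConfig("6", 1, 10**9, n_permutations=20, pt=0.001, seed=6)
        with pytest.warns(UserWarning, match="below all null minima"):
            permutation_threshold(geno, expr, "GENE1", cfg)

    def test_pairwise_deletion_with_missing_genotypes(self, cohort):
        geno, expr = cohort
        dos = geno.dosages.copy()
        dos[:10, 1] = np.nan
        geno2 = type(geno)(list(geno.sample_ids), geno.snp_meta.copy(), dos)
        cfg = ScanConfig("6", 1, 10**9, n_permutations=100, pt=0.05, seed=8)
        recs = cis_scan(geno2, expr, "GENE1", cfg)
        rec = next(r for r in recs if r.snp_id == "rs2")
        assert rec.n_used == 110
        assert rec.rho is not None


class TestGroupSummaryAndKruskal:
    def test_fold_change_closed_form(self):
        d = np.array([0, 0, 2, 2, 1])
        e = np.array([10.0, 10.0, 2.0, 2.0, 5.0])
        s = genotype_group_summary(d, e)
        assert s.fold_change(0, 2) == pytest.approx(5.0)
        assert s.fold_change(2, 2) == 1.0
        assert s.groups[0]["median"] == 10.0

    def test_noiseless_additive_folds_exact(self, cohort):
        geno, _ = cohort
        e = simulate_expression(geno, EffectModel("rs2", "additive", 1.8, 0.0), seed=0)
        s = genotype_group_summary(geno.dosage_vector("rs2"), e.values[0])
        assert s.fold_change(2, 0) == pytest.approx(3.24)
        assert s.fold_change(2, 1) == pytest.approx(1.8)

    def test_empty_group_rejected(self):
        d = np.array([1, 1, 2, 2, 2])
        e = np.ones(5) * 3.0
        s = genotype_group_summary(d, e)
        with pytest.raises(ValueError, match="empty dosage group"):
            s.fold_change(2, 0)

    def test_genotype_labels_attached(self):
        g = geno_from_dosages([[0], [1], [2]])
        s = genotype_group_summary(
            g.dosage_vector("rs1"), np.array([1.0, 2.0, 3.0]), g.genotype_labels("rs1")
        )
        assert s.labels == {0: "GG", 1: "AG", 2: "AA"}

    def test_kruskal_wallis_worked_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2), abs=1e-12)

    def test_kruskal_two_groups_equals_squared_normal_mwu(self):
        rng = np.random.default_rng(12)
        a = rng.permutation(24)[:10].astype(float)  # distinct values: no ties
        b = np.setdiff1d(np.arange(24), a)[:8].astype(float)
        h, _ = kruskal_wallis([a, b])
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_identical_values_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
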