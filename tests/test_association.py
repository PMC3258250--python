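"""Allelic, logistic, conditioned and haplotype case-control association."""

import numpy as np
import pytest

from eqtlkit.association import (
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
    allelic_test,
    conditional_scan,
    haplotype_assoc,
    logistic_assoc,
)
from eqtlkit.datatypes import DataError, PhenotypeTable
from eqtlkit.simulate import make_haplotype_pool, simulate_case_control

from conftest import geno_from_dosages


def cohort_from_counts(case_dosages, control_dosages):
    """GenotypeMatrix + PhenotypeTable from explicit dosage lists."""
    dos = np.array(list(case_dosages) + list(control_dosages), dtype=float)
    if dos.ndim == 1:
        dos = dos[:, None]
    g = geno_from_dosages(dos)
    status = np.array([1] * len(case_dosages) + [0] * len(control_dosages))
    return g, PhenotypeTable(g.sample_ids, status)


class TestAllelicTest:
    def test_cross_product_odds_ratio(self):
        # cases: 30 risk / 70 other alleles; controls: 15 / 85
        g, ph = cohort_from_counts([2] * 15 + [0] * 35, [2, 1] * 5 + [1] * 5 + [0] * 35)
        # case minor alleles = 30 of 100; control = 10+5+5... construct simpler below
        rec = allelic_test(g, "rs1", ph)
        a = 30.0
        b = 70.0
        c = float(np.sum(g.dosages[ph.status == 0, 0]))
        d = 2 * 50 - c
        assert rec.or_allelic == pytest.approx((a * d) / (b * c))
        assert rec.f_a == pytest.approx(0.3)
        assert rec.ci95[0] < rec.or_allelic < rec.ci95[1]

    def test_printed_counts_example(self):
        g, ph = cohort_from_counts([1] * 30 + [0] * 20, [1] * 15 + [0] * 35)
        rec = allelic_test(g, "rs1", ph)
        assert rec.or_allelic == pytest.approx((30 * 85) / (70 * 15), abs=1e-12)
        assert round(rec.or_allelic, 4) == 2.4286

    def test_null_table_gives_or_one_p_one(self):
        g, ph = cohort_from_counts([2] * 5 + [0] * 5, [2] * 5 + [0] * 5)
        rec = allelic_test(g, "rs1", ph)
        assert rec.or_allelic == pytest.approx(1.0)
        assert rec.p == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        g, ph = cohort_from_counts([2] * 5 + [1] * 3, [0] * 8)
        rec = allelic_test(g, "rs1", ph)  # controls carry 0 minor alleles
        assert np.isfinite(rec.or_allelic) and rec.or_allelic > 1
        assert np.isfinite(rec.ci95[1])

    def test_monomorphic_and_single_class_rejected(self):
        g, ph = cohort_from_counts([0] * 5, [0] * 5)
        with pytest.raises(DataError):
            allelic_test(g, "rs1", ph)
        g2, _ = cohort_from_counts([0, 1, 2], [])
        ph2 = PhenotypeTable(g2.sample_ids, np.ones(3, dtype=int))
        with pytest.raises(DataError):
            allelic_test(g2, "rs1", ph2)


class TestLogisticAssoc:
    def test_conditioning_on_self_is_rank_deficient(self, pool2):
        g, ph = simulate_case_control(pool2, "AC", 2.0, 0.1, 200, 200, seed=1)
        with pytest.raises(RankDeficiencyError):
            logistic_assoc(g, "rs1", ph, covariate_snps=["rs1"])

    def test_saturated_binary_fit_reproduces_two_by_two_or(self):
        # dominant-collapsed 0/1 predictor: logistic OR equals the 2x2
        # cross-product exactly in the saturated model
        a, b, c, d = 40, 60, 25, 75  # carrier/non x case/control
        g, ph = cohort_from_counts([1] * a + [0] * b, [1] * c + [0] * d)
        terms = logistic_assoc(g, "rs1", ph)
        or_22 = (a * d) / (b * c)
        assert terms[1].odds_ratio == pytest.approx(or_22, rel=1e-6)

    def test_parameter_recovery_at_or_two(self, pool2):
        g, ph = simulate_case_control(pool2, "A*", 2.0, 0.1, 2000, 2000, seed=5)
        terms = logistic_assoc(g, "rs1", ph)
        assert 1.7 < terms[1].odds_ratio < 2.3
        assert terms[1].p < 1e-10

    def test_perfect_separation_detected(self):
        g, ph = cohort_from_counts([2] * 20, [0] * 20)
        with pytest.raises((SeparationError, ConvergenceError)):
            logistic_assoc(g, "rs1", ph)

    def test_min_class_guard(self):
        g, ph = cohort_from_counts([0, 1, 2], [0, 1, 2])
        with pytest.raises(DataError, match="per class"):
            logistic_assoc(g, "rs1", ph)


class TestConditionalScan:
    def test_irrelevant_covariate_leaves_p_similar(self):
        pool = make_haplotype_pool(2, [(1, 0.0), (1, 0.0)], [0.3, 0.3])
        diffs = []
        for rep in range(5):
            g, ph = simulate_case_control(pool, "A*", 2.0, 0.1, 1500, 1500, seed=50 + rep)
            uncond = logistic_assoc(g, "rs1", ph)[1].p
            cond = conditional_scan(g, ["rs1"], ph, "rs2")[0].p_cond
            diffs.append(abs(np.log10(cond) - np.log10(uncond)))
        assert np.median(diffs) < 0.5

    def test_self_condition_error_propagates(self, pool2):
        g, ph = simulate_case_control(pool2, "AC", 2.0, 0.1, 200, 200, seed=2)
        with pytest.raises(RankDeficiencyError):
            conditional_scan(g, ["rs1"], ph, "rs1")

    def test_record_fields_filled(self, pool2):
        g, ph = simulate_case_control(pool2, "A*", 2.0, 0.1, 500, 500, seed=3)
        recs = conditional_scan(g, ["rs2"], ph, "rs1")
        assert recs[0].p_cond is not None and recs[0].or_cond is not None
        assert recs[0].condition_snp == "rs1"


class TestHaplotypeAssoc:
    def test_frequency_floor_suppresses_rare_haplotype(self):
        import pandas as pd

        from eqtlkit.simulate import HaplotypePool

        meta = pd.DataFrame(
            {"chrom": "6", "pos": [1, 2], "allele1": ["A", "C"],
             "allele2": ["G", "T"], "minor": ["A", "C"]},
            index=pd.Index(["rs1", "rs2"], name="snp"),
        )
        pool = HaplotypePool(
            ["AC", "AT", "GC", "GT"], np.array([0.04, 0.26, 0.26, 0.44]), meta
        )
        g, ph = simulate_case_control(pool, "GT", 1.0, 0.1, 1500, 1500, seed=4)
        rows = haplotype_assoc(g, ["rs1", "rs2"], ph, freq_floor=0.05)
        haps = {r.haplotype for r in rows}
        assert "AC" not in haps  # pooled frequency ~0.04 stays below the floor
        assert {"AT", "GC", "GT"} <= haps

    def test_null_simulation_recovers_or_near_one(self, pool2):
        g, ph = simulate_case_control(pool2, "AC", 1.0, 0.1, 2000, 2000, seed=6)
        rows = haplotype_assoc(g, ["rs1", "rs2"], ph)
        for r in rows:
            assert 0.8 < r.odds_ratio < 1.25

    def test_frequencies_sum_to_one_per_class(self, pool2):
        g, ph = simulate_case_control(pool2, "AC", 2.0, 0.1, 800, 800, seed=7)
        rows = haplotype_assoc(g, ["rs1", "rs2"], ph, freq_floor=0.0)
        assert sum(r.f_a for r in rows) == pytest.approx(1.0, abs=1e-6)
        assert sum(r.f_u for r in rows) == pytest.approx(1.0, abs=1e-6)

    def test_k_bounds(self, pool2):
        g, ph = simulate_case_control(pool2, "AC", 1.0, 0.1, 50, 50, seed=8)
        with pytest.raises(ValueError):
            haplotype_assoc(g, ["rs1"], ph)
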