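"""Self-contained validation studies exercising the package end to end.

Each function builds its own synthetic inputs at documented study sizes, runs
the method under test, and returns summary numbers. They back both the test
suite and ``scripts/acceptance.py``, so the same computation produces the
asserted and the reported values. All randomness flows from the ``seed``
argument via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .association import allelic_test, haplotype_assoc, logistic_assoc
from .datatypes import ExpressionMatrix, GenotypeMatrix
from .popgen import em_haplotype_freqs, hwe_exact_test
from .scan import (
    ScanConfig,
    cis_scan,
    genotype_group_summary,
    kruskal_wallis,
    permutation_threshold,
    spearman_rho,
)
from .simulate import (
    EffectModel,
    HaplotypePool,
    make_haplotype_pool,
    simulate_case_control,
    simulate_expression,
    simulate_genotypes,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def spearman_oracle_comparison(seed: int, n_vectors: int = 1000) -> dict:
    """Max |rho_ours - rho_scipy| over random tied vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_vectors:
        n = int(rng.integers(8, 60))
        x = rng.integers(0, 3, n).astype(float)
        y = rng.normal(size=n).round(1)  # rounding forces ties
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            continue
        ours = spearman_rho(x, y)
        ref = stats.spearmanr(x, y).statistic
        worst = max(worst, abs(ours - ref))
        done += 1
    return {"max_abs_diff": worst, "n": n_vectors}


def _block_genotypes(n: int, n_blocks: int, block_len: int, r2: float,
                     maf: float, seed: int) -> GenotypeMatrix:
    """Genotypes for many SNPs as independent LD blocks stitched together."""
    seeds = _child_seeds(seed, n_blocks)
    parts, metas = [], []
    for b, s in enumerate(seeds):
        pool = make_haplotype_pool(
            block_len, [(block_len, r2)], [maf] * block_len,
            snp_ids=[f"rs{b * block_len + i + 1}" for i in range(block_len)],
            positions=[100000 * (b * block_len + i + 1) for i in range(block_len)],
        )
        g = simulate_genotypes(pool, n, seed=s)
        parts.append(g.dosages)
        metas.append(g.snp_meta)
    meta = pd.concat(metas)
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(samples, meta, np.hstack(parts))


def permutation_calibration(
    seed: int,
    n_genes: int = 200,
    n_snps: int = 50,
    n: int = 100,
    n_perm: int = 1000,
    pt: float = 0.05,
) -> dict:
    """Gene-level family-wise error of the permutation threshold under the null.

    Independent null genes (expression unrelated to genotype) are scanned
    against ``n_snps`` cis SNPs in LD blocks; returns the fraction of genes
    with at least one significant SNP at PT, which should match PT, and the
    95% binomial interval around PT for that many genes.
    """
    seeds = _child_seeds(seed, 3 * n_genes)
    false_positives = 0
    for i in range(n_genes):
        geno = _block_genotypes(n, n_snps // 5, 5, 0.6, 0.3, seeds[3 * i])
        rng = np.random.default_rng(seeds[3 * i + 1])
        expr = ExpressionMatrix(
            ["NULLGENE"], geno.sample_ids, rng.normal(size=n)[None, :]
        )
        cfg = ScanConfig("6", 1, 2**31 - 1, n_permutations=n_perm, pt=pt,
                         seed=seeds[3 * i + 2])
        res = permutation_threshold(geno, expr, "NULLGENE", cfg)
        if res.significant.any():
            false_positives += 1
    frac = false_positives / n_genes
    half = 1.96 * math.sqrt(pt * (1 - pt) / n_genes)
    return {"fraction": frac, "expected": pt, "ci_low": pt - half,
            "ci_high": pt + half, "n": n_genes}


def effect_recovery(
    seed: int,
    n: int = 500,
    n_replicates: int = 50,
    fold: float = 1.8,
    noise_sd: float = 0.3,
) -> dict:
    """Additive-effect recovery: fold-change estimation and top-hit rate.

    Expression is generated from one causal SNP inside a 12-SNP LD-block
    region; returns the mean estimated homozygote fold change (truth =
    fold**2) and the fraction of replicates where the causal SNP has the
    largest |rho| in the region.
    """
    pool = make_haplotype_pool(
        12, [(4, 0.8), (4, 0.6), (4, 0.7)], [0.3] * 12,
        positions=[100000 * (i + 1) for i in range(12)],
    )
    causal = "rs2"
    seeds = _child_seeds(seed, 2 * n_replicates)
    folds, top_hits = [], 0
    for i in range(n_replicates):
        geno = simulate_genotypes(pool, n, seed=seeds[2 * i])
        expr = simulate_expression(
            geno, EffectModel(causal, "additive", fold, noise_sd), seed=seeds[2 * i + 1]
        )
        summary = genotype_group_summary(geno.dosage_vector(causal), expr.values[0])
        folds.append(summary.fold_change(2, 0))
        cfg = ScanConfig("6", 1, 2**31 - 1, n_permutations=100, pt=0.01,
                         seed=seeds[2 * i + 1])
        recs = cis_scan(geno, expr, "GENE1", cfg)
        top = max(recs, key=lambda r: abs(r.rho) if r.rho is not None else -1.0)
        top_hits += top.snp_id == causal
    return {
        "mean_fold_2_vs_0": float(np.mean(folds)),
        "true_fold_2_vs_0": fold**2,
        "top_hit_rate": top_hits / n_replicates,
        "n": n_replicates,
    }


def _two_snp_pool(freqs: dict[str, float]) -> HaplotypePool:
    """Pool over two SNPs (minor alleles A and C) from haplotype frequencies."""
    meta = pd.DataFrame(
        {"chrom": "6", "pos": [32500000, 32600000], "allele1": ["A", "C"],
         "allele2": ["G", "T"], "minor": ["A", "C"]},
        index=pd.Index(["rs1", "rs2"], name="snp"),
    )
    haps = list(freqs)
    return HaplotypePool(haps, np.array([freqs[h] for h in haps]), meta)


def em_haplotype_recovery(seed: int, n: int = 2000) -> dict:
    """EM haplotype frequency recovery from a known two-SNP pool, plus the
    closed-form LD of the exact pool frequencies."""
    pool = _two_snp_pool({"AC": 0.4, "AT": 0.1, "GC": 0.3, "GT": 0.2})
    geno = simulate_genotypes(pool, n, seed=seed)
    table = em_haplotype_freqs(geno, ["rs1", "rs2"])
    truth = dict(zip(pool.haplotypes, pool.frequencies))
    est = table.as_dict()
    max_err = max(abs(est[h] - f) for h, f in truth.items())
    monotone = bool(np.all(np.diff(table.loglik_trace) >= -1e-9))
    d, r2, dp = pool.exact_ld("rs1", "rs2")
    return {
        "max_abs_error": float(max_err),
        "loglik_monotone": monotone,
        "pool_d": d,
        "pool_r2": r2,
        "pool_d_prime": dp,
        "n": n,
    }


def conditional_analysis_logic(
    seed: int,
    n_replicates: int = 100,
    n_cases: int = 2000,
    n_controls: int = 2000,
    odds_ratio: float = 2.0,
    proxy_r2: float = 0.8,
) -> dict:
    """Proxy-SNP conditioning: a SNP in LD with a causal risk SNP shows strong
    unconditional association that vanishes once the causal SNP is a covariate.

    Returns the fraction of replicates with unconditional proxy p < 1e-4 and
    the fraction with conditioned proxy p > 0.05.
    """
    pool = make_haplotype_pool(2, [(2, proxy_r2)], [0.3, 0.3])
    causal, proxy = "rs1", "rs2"
    risk_pattern = pool.snp_meta.loc[causal, "minor"] + "*"
    seeds = _child_seeds(seed, n_replicates)
    uncond_hits = cond_null = 0
    for s in seeds:
        geno, pheno = simulate_case_control(
            pool, risk_pattern, odds_ratio, 0.1, n_cases, n_controls, seed=s
        )
        if allelic_test(geno, proxy, pheno).p < 1e-4:
            uncond_hits += 1
        p_cond = logistic_assoc(geno, proxy, pheno, covariate_snps=[causal])[1].p
        if p_cond > 0.05:
            cond_null += 1
    return {
        "unconditional_power": uncond_hits / n_replicates,
        "conditional_null_rate": cond_null / n_replicates,
        "n": n_replicates,
    }


def haplotype_or_recovery(
    seed: int,
    n_replicates: int = 100,
    odds_ratio: float = 2.67,
    hap_freq: float = 0.15,
    n_cases: int = 2000,
    n_controls: int = 2000,
) -> dict:
    """Risk-haplotype odds-ratio recovery by case/control EM + 2x2 test."""
    pool = _two_snp_pool(
        {"AC": hap_freq, "AT": hap_freq, "GC": hap_freq, "GT": 1 - 3 * hap_freq}
    )
    seeds = _child_seeds(seed, n_replicates)
    ors = []
    for s in seeds:
        geno, pheno = simulate_case_control(
            pool, "AC", odds_ratio, 0.05, n_cases, n_controls, seed=s
        )
        rows = haplotype_assoc(geno, ["rs1", "rs2"], pheno, freq_floor=0.05)
        ors.append(next(r.odds_ratio for r in rows if r.haplotype == "AC"))
    ors = np.array(ors)
    return {
        "recovery_rate": float(np.mean((ors >= 2.2) & (ors <= 3.2))),
        "median_or": float(np.median(ors)),
        "true_or": odds_ratio,
        "n": n_replicates,
    }


def _hwe_direct_formula(n0: int, n1: int, n2: int) -> float:
    """Independent HWE oracle from exact integer combinatorics."""
    n = n0 + n1 + n2
    rare = 2 * min(n0, n2) + n1
    denom = math.comb(2 * n, rare)

    def prob(h: int) -> float:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        coef = math.factorial(n) // (
            math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c)
        )
        return coef * 2**h / denom

    obs = prob(n1)
    return sum(p for h in range(rare % 2, rare + 1, 2) if (p := prob(h)) <= obs * (1 + 1e-12))


def hwe_oracle_agreement(max_n: int = 30) -> dict:
    """Compare the recurrence-based HWE exact test against the direct-formula
    enumeration oracle for every genotype configuration with n <= max_n."""
    worst = 0.0
    count = 0
    for n in range(1, max_n + 1):
        for n0 in range(n + 1):
            for n1 in range(n - n0 + 1):
                n2 = n - n0 - n1
                worst = max(worst, abs(hwe_exact_test(n0, n1, n2) - _hwe_direct_formula(n0, n1, n2)))
                count += 1
    return {"max_abs_diff": worst, "n": count}


def kruskal_worked_example() -> dict:
    """Three ordered groups of ranks 1..9 give H = 7.2 exactly."""
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    return {"H": h, "p": p, "n": 9}
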