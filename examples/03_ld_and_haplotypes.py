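"""LD statistics, EM haplotype frequencies and Hardy-Weinberg testing.

Draws genotypes from a pool with known two-locus haplotype frequencies
(0.4 / 0.1 / 0.3 / 0.2) and shows that the EM estimates recover them, that
pairwise r2 / D' match the closed-form values from the exact pool
frequencies, and how the HWE exact test reads genotype counts.
"""

import numpy as np

from eqtlkit import (
    em_haplotype_freqs,
    hwe_exact_test,
    ld_from_haplotype_freqs,
    pairwise_ld,
    simulate_genotypes,
)
from eqtlkit.validation import _two_snp_pool

pool = _two_snp_pool({"AC": 0.4, "AT": 0.1, "GC": 0.3, "GT": 0.2})
geno = simulate_genotypes(pool, 2000, seed=21)

table = em_haplotype_freqs(geno, ["rs1", "rs2"])
print("haplotype  truth  EM estimate")
truth = dict(zip(pool.haplotypes, pool.frequencies))
for hap, f in zip(table.haplotypes, table.frequencies):
    print(f"{hap:9s} {truth.get(hap, 0.0):6.3f} {f:11.4f}")
print(f"EM: {table.n_iterations} iterations, converged={table.converged}, "
      f"log-likelihood {table.log_likelihood:.1f}")

d, r2, dp = ld_from_haplotype_freqs(0.4, 0.1, 0.3, 0.2)
est = pairwise_ld(geno, "rs1", "rs2")
print(f"\nclosed-form pool LD: D={d:.3f} r2={r2:.4f} D'={dp:.4f}")
print(f"EM estimate from n=2000: r2={est.r2:.4f} D'={est.d_prime:.4f}")

d_vec = geno.dosage_vector("rs1")
n0, n1, n2 = int((d_vec == 0).sum()), int((d_vec == 1).sum()), int((d_vec == 2).sum())
print(f"\nrs1 genotype counts ({n0}, {n1}, {n2}): "
      f"HWE exact p = {hwe_exact_test(n0, n1, n2):.3f}")
print(f"forced heterozygote deficit (50, 0, 50): "
      f"HWE exact p = {hwe_exact_test(50, 0, 50):.2e}")
# Random-mating simulation should give a non-significant HWE p, while the
# constructed deficit is astronomically unlikely under Hardy-Weinberg.
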