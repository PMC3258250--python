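"""Population-genetic statistics: allele frequencies, EM haplotype frequency
estimation from unphased genotypes, pairwise LD (r-squared and D-prime) and the
Hardy-Weinberg exact test.

The EM treats each multi-heterozygous genotype as a mixture over its compatible
haplotype pairs, weighting pairs by the product of current haplotype
frequencies (Hardy-Weinberg proportions within the E-step). Initialization is
the product of single-SNP allele frequencies, which makes the fit deterministic;
the log-likelihood is non-decreasing across iterations and is reported so that
suspicious fits can be spotted. Samples with any missing genotype in the SNP
set are dropped (complete-case).
"""

from __future__ import annotations

import dataclasses
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .datatypes import DataError, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (monomorphic SNP, all-missing, ...)."""


@dataclasses.dataclass
class LDStats:
    snp_i: str
    snp_j: str
    d: float
    r2: float
    d_prime: float
    n_used: int


@dataclasses.dataclass
class HaplotypeFreqTable:
    """EM-estimated haplotype frequencies over an ordered SNP set.

    ``haplotypes`` are allele strings (one letter per SNP, in ``snp_ids``
    order); frequencies sum to one over the 2^k candidate haplotypes.
    """

    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_used: int
    loglik_trace: list = dataclasses.field(default_factory=list)

    def as_dict(self) -> dict:
        return dict(zip(self.haplotypes, self.frequencies))


def allele_freq(geno: GenotypeMatrix, snp_id: str) -> float:
    """Minor-allele frequency: sum(dosage) / (2 * n non-missing)."""
    d = geno.dosage_vector(snp_id)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedStatisticError(f"SNP {snp_id}: all genotypes missing")
    return float(d.sum() / (2 * d.size))


def _compatible_pairs(geno_row: tuple, k: int) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs compatible with a dosage row.

    Haplotypes are indexed by their k-bit code (bit = 1 for the minor allele,
    SNP 0 = most significant bit).
    """
    het = [i for i in range(k) if geno_row[i] == 1]
    base = 0
    for i in range(k):
        if geno_row[i] == 2:
            base |= 1 << (k - 1 - i)
    if not het:
        return [(base, base)]
    pairs = []
    # fix the first het site's minor allele on haplotype A: each unordered
    # heterozygous pair enumerated exactly once
    rest = het[1:]
    first_bit = 1 << (k - 1 - het[0])
    for assign in product((0, 1), repeat=len(rest)):
        a = base | first_bit
        b = base
        for site, on_a in zip(rest, assign):
            bit = 1 << (k - 1 - site)
            if on_a:
                a |= bit
            else:
                b |= bit
        pairs.append((a, b))
    return pairs


def _hap_strings(snp_meta, snp_ids: Sequence[str], k: int) -> list[str]:
    minors, majors = [], []
    for s in snp_ids:
        row = snp_meta.loc[s]
        minors.append(row["minor"])
        majors.append(row["allele2"] if row["minor"] == row["allele1"] else row["allele1"])
    out = []
    for h in range(2**k):
        out.append(
            "".join(
                minors[i] if (h >> (k - 1 - i)) & 1 else majors[i] for i in range(k)
            )
        )
    return out


def em_haplotype_freqs(
    geno: GenotypeMatrix,
    snp_ids: Optional[Sequence[str]] = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> HaplotypeFreqTable:
    """EM haplotype frequency estimation for up to 8 SNPs.

    Convergence: max absolute frequency change < ``tol`` or ``max_iter``
    iterations. Raises on an empty complete-case set or k outside [1, 8].
    """
    snp_ids = list(snp_ids) if snp_ids is not None else geno.snp_ids
    k = len(snp_ids)
    if not 1 <= k <= 8:
        raise ValueError(f"EM supports 1..8 SNPs, got {k}")
    sub = geno.subset_snps(snp_ids)
    complete = ~np.isnan(sub.dosages).any(axis=1)
    dose = sub.dosages[complete].astype(int)
    n = dose.shape[0]
    if n == 0:
        raise DataError("no samples with complete genotypes at the SNP set")

    rows, counts = np.unique(dose, axis=0, return_counts=True)
    pair_sets = [_compatible_pairs(tuple(r), k) for r in rows]

    # init: product of single-SNP minor allele frequencies
    mafs = dose.mean(axis=0) / 2.0
    H = 2**k
    freqs = np.empty(H)
    for h in range(H):
        p = 1.0
        for i in range(k):
            p *= mafs[i] if (h >> (k - 1 - i)) & 1 else 1.0 - mafs[i]
        freqs[h] = p
    freqs = np.clip(freqs, 1e-300, None)
    freqs /= freqs.sum()

    loglik = -np.inf
    trace: list = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        new = np.zeros(H)
        ll = 0.0
        for pairs, c in zip(pair_sets, counts):
            w = np.array([freqs[a] * freqs[b] * (1.0 if a == b else 2.0) for a, b in pairs])
            tot = w.sum()
            ll += c * np.log(tot)
            w *= c / tot
            for (a, b), wi in zip(pairs, w):
                new[a] += wi
                new[b] += wi
        new /= 2.0 * n
        delta = np.abs(new - freqs).max()
        freqs, loglik = new, ll
        trace.append(float(ll))
        if delta < tol:
            converged = True
            break

    return HaplotypeFreqTable(
        snp_ids=snp_ids,
        haplotypes=_hap_strings(geno.snp_meta, snp_ids, k),
        frequencies=freqs,
        log_likelihood=float(loglik),
        n_iterations=n_iter,
        converged=converged,
        n_used=n,
        loglik_trace=trace,
    )


def ld_from_haplotype_freqs(
    p11: float, p10: float, p01: float, p00: float
) -> tuple[float, float, float]:
    """(D, r2, D') from two-locus haplotype frequencies.

    Index 1 marks the minor allele: p11 is the frequency of the haplotype
    carrying the minor allele at both SNPs. Frequencies must sum to 1.
    """
    tot = p11 + p10 + p01 + p00
    if not np.isclose(tot, 1.0, atol=1e-6):
        raise ValueError(f"haplotype frequencies sum to {tot}, expected 1")
    p1 = p11 + p10  # minor-allele freq at SNP i
    q1 = p11 + p01  # minor-allele freq at SNP j
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise UndefinedStatisticError("LD undefined for a monomorphic SNP")
    d = p11 - p1 * q1
    r2 = d * d / (p1 * (1 - p1) * q1 * (1 - q1))
    if d > 0:
        dmax = min(p1 * (1 - q1), (1 - p1) * q1)
    elif d < 0:
        dmax = min(p1 * q1, (1 - p1) * (1 - q1))
    else:
        return 0.0, 0.0, 0.0
    return float(d), float(r2), float(abs(d) / dmax)


def pairwise_ld(geno: GenotypeMatrix, snp_i: str, snp_j: str) -> LDStats:
    """r-squared and D-prime between two SNPs via two-locus EM haplotype
    frequencies on samples complete at both SNPs."""
    if snp_i == snp_j:
        d = geno.dosage_vector(snp_i)
        n = int((~np.isnan(d)).sum())
        return LDStats(snp_i, snp_j, float("nan"), 1.0, 1.0, n)
    table = em_haplotype_freqs(geno, [snp_i, snp_j])
    # haplotype order from _hap_strings: bit 1 = minor; index 3 = minor/minor
    f = table.frequencies
    try:
        d, r2, dp = ld_from_haplotype_freqs(f[3], f[2], f[1], f[0])
    except UndefinedStatisticError:
        raise UndefinedStatisticError(
            f"LD undefined: {snp_i} or {snp_j} monomorphic among complete pairs"
        ) from None
    return LDStats(snp_i, snp_j, d, r2, dp, table.n_used)


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact Hardy-Weinberg test from genotype counts (major hom, het, minor hom).

    Two-sided: sums the probabilities of all heterozygote counts, conditional
    on the allele counts, whose point probability does not exceed the
    observed configuration's. Returns p in (0, 1].
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    rare = 2 * min(n0, n2) + n1  # count of the rarer allele
    # probabilities over all het counts with the same parity as `rare`,
    # built by the standard ratio recurrence from the mid configuration
    hets = list(range(rare % 2, rare + 1, 2))
    probs = {h: 0.0 for h in hets}
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # going down in het count
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # going up
    h = mid
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    obs = probs[n1] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return float(min(p, 1.0))
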