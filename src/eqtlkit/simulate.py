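"""Synthetic genotype / expression / case-control cohort generation.

The generator emulates the data structure of dense candidate-region studies:
unrelated diploid samples drawn from an explicit haplotype pool (SNPs arranged
in LD blocks with chosen minor-allele frequencies and within-block r-squared),
cis expression effects that multiply a baseline per copy of the causal allele
(additive) or for any carrier (dominant) with lognormal noise, and case-control
cohorts where disease odds scale log-additively per copy of a risk haplotype.

Haplotype pools are exact discrete distributions, so LD and allele frequencies
of a pool can be computed in closed form and compared with estimates from
finite simulated cohorts. All randomness flows from an integer seed passed to
each operation; there is no global random state.
"""

from __future__ import annotations

import dataclasses
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from .popgen import ld_from_haplotype_freqs


class InfeasibleLDError(ValueError):
    """Requested (MAF, correlation) combination violates |D| <= Dmax."""


class QuotaError(RuntimeError):
    """Case/control quotas could not be filled within the attempt bound."""


_DEFAULT_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("T", "C"), ("G", "A"))


@dataclasses.dataclass
class HaplotypePool:
    """Exact haplotype distribution over k biallelic SNPs.

    ``haplotypes`` are allele strings (one letter per SNP); ``frequencies``
    are their probabilities (sum to 1). ``snp_meta`` follows the genotype
    matrix schema (chrom, pos, allele1, allele2, minor).
    """

    haplotypes: list[str]
    frequencies: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if (self.frequencies < 0).any():
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {self.frequencies.sum()}")
        k = len(self.snp_meta)
        if any(len(h) != k for h in self.haplotypes):
            raise ValueError("all haplotypes must cover every SNP")
        for i, (snp, row) in enumerate(self.snp_meta.iterrows()):
            pair = {row["allele1"], row["allele2"]}
            for h in self.haplotypes:
                if h[i] not in pair:
                    raise ValueError(f"haplotype allele {h[i]!r} not in pair of {snp}")

    @property
    def k(self) -> int:
        return len(self.snp_meta)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta.index)

    def minor_matrix(self) -> np.ndarray:
        """(n_haplotypes, k) 0/1 indicator of the minor allele."""
        minors = self.snp_meta["minor"].to_numpy()
        return np.array(
            [[1 if h[i] == minors[i] else 0 for i in range(self.k)] for h in self.haplotypes],
            dtype=float,
        )

    def mafs(self) -> np.ndarray:
        return self.frequencies @ self.minor_matrix()

    def pair_freqs(self, snp_i: str, snp_j: str) -> tuple[float, float, float, float]:
        """Exact (p11, p10, p01, p00) two-locus frequencies in minor coding."""
        i = self.snp_ids.index(snp_i)
        j = self.snp_ids.index(snp_j)
        m = self.minor_matrix()
        out = np.zeros(4)
        for f, a, b in zip(self.frequencies, m[:, i], m[:, j]):
            out[int(2 * a + b)] += f
        p00, p01, p10, p11 = out
        return p11, p10, p01, p00

    def exact_ld(self, snp_i: str, snp_j: str) -> tuple[float, float, float]:
        """(D, r2, D') from the pool's exact haplotype frequencies."""
        return ld_from_haplotype_freqs(*self.pair_freqs(snp_i, snp_j))

    def match_indicator(self, pattern: str) -> np.ndarray:
        """0/1 per pool haplotype: matches an allele string, '*' = any allele."""
        if len(pattern) != self.k:
            raise ValueError(f"pattern length {len(pattern)} != {self.k} SNPs")
        return np.array(
            [
                1.0 if all(p == "*" or p == h[i] for i, p in enumerate(pattern)) else 0.0
                for h in self.haplotypes
            ]
        )


@dataclasses.dataclass
class EffectModel:
    """Cis expression effect of one causal SNP.

    additive: expression multiplied by ``per_allele_fold`` per minor-allele
    copy; dominant: multiplied once for any carrier. Noise is additive
    Gaussian on the log scale (lognormal on the expression scale), keeping
    expression positive and effects multiplicative.
    """

    causal_snp: str
    mode: str = "additive"
    per_allele_fold: float = 1.8
    noise_sd: float = 0.3
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "dominant"):
            raise ValueError(f"mode must be additive or dominant, got {self.mode!r}")
        if self.per_allele_fold <= 0:
            raise ValueError("per_allele_fold must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def fold_factor(self, dosage: np.ndarray) -> np.ndarray:
        if self.mode == "additive":
            return self.per_allele_fold ** dosage
        return np.where(dosage >= 1, self.per_allele_fold, 1.0)


def _chain_block(
    mafs: Sequence[float], r_adj: float
) -> dict[tuple[int, ...], float]:
    """Joint distribution of a block as a two-state Markov chain.

    Adjacent SNPs get correlation ``r_adj``; binary Markov chains multiply
    correlations, so the pair at distance d has r = r_adj**d.
    """
    dist = {(1,): mafs[0], (0,): 1.0 - mafs[0]}
    for t in range(1, len(mafs)):
        p, q = mafs[t - 1], mafs[t]
        d = r_adj * np.sqrt(p * (1 - p) * q * (1 - q))
        dmax = min(p * (1 - q), (1 - p) * q)
        if d > dmax + 1e-12:
            raise InfeasibleLDError(
                f"block SNPs {t-1},{t}: requested correlation {r_adj:.4f} needs "
                f"D={d:.4f} > Dmax={dmax:.4f} for MAFs {p}, {q}"
            )
        p11 = p * q + d
        cond1 = p11 / p if p > 0 else q  # P(next minor | prev minor)
        cond0 = (q - p11) / (1 - p) if p < 1 else q
        new: dict[tuple[int, ...], float] = {}
        for hap, f in dist.items():
            c = cond1 if hap[-1] == 1 else cond0
            if c > 0:
                new[hap + (1,)] = new.get(hap + (1,), 0.0) + f * c
            if c < 1:
                new[hap + (0,)] = new.get(hap + (0,), 0.0) + f * (1 - c)
        dist = new
    return dist


def make_haplotype_pool(
    k: int,
    block_spec: Sequence[tuple[int, float]],
    target_mafs: Sequence[float],
    seed: Optional[int] = None,
    snp_ids: Optional[Sequence[str]] = None,
    chrom: str = "6",
    positions: Optional[Sequence[int]] = None,
    alleles: Optional[Sequence[tuple[str, str]]] = None,
) -> HaplotypePool:
    """Build an exact haplotype pool from LD-block specifications.

    Parameters
    ----------
    k : total SNP count; block lengths must sum to k.
    block_spec : list of (block_length, within_block_r2). Blocks are mutually
        independent; within a block of length L adjacent SNPs are chained with
        correlation ``r2 ** (1 / (2 (L - 1)))`` so that every within-block
        pair attains at least the requested r-squared.
    target_mafs : per-SNP minor-allele frequency, each in (0, 0.5].
    seed : accepted for interface uniformity; the construction is
        deterministic and does not consume randomness.
    alleles : optional (minor, major) letter pair per SNP.

    Raises
    ------
    InfeasibleLDError
        If a requested (MAF, correlation) pair violates |D| <= min(p1q2, q1p2).
    """
    target_mafs = list(target_mafs)
    if len(target_mafs) != k:
        raise ValueError(f"need {k} target MAFs, got {len(target_mafs)}")
    if any(not 0 < m <= 0.5 for m in target_mafs):
        raise ValueError("every target MAF must be in (0, 0.5]")
    if sum(length for length, _ in block_spec) != k:
        raise ValueError("block lengths must sum to k")
    if k > 16:
        raise ValueError("pool enumeration limited to k <= 16 SNPs")

    block_dists = []
    start = 0
    for length, r2 in block_spec:
        if not 0 <= r2 <= 1:
            raise ValueError(f"within-block r2 must be in [0, 1], got {r2}")
        mafs = target_mafs[start : start + length]
        if length == 1:
            block_dists.append({(1,): mafs[0], (0,): 1.0 - mafs[0]})
        else:
            r_adj = r2 ** (1.0 / (2.0 * (length - 1)))
            block_dists.append(_chain_block(mafs, r_adj))
        start += length

    # independent blocks -> product distribution
    haps: dict[tuple[int, ...], float] = {(): 1.0}
    for dist in block_dists:
        haps = {
            h + hb: f * fb for h, f in haps.items() for hb, fb in dist.items() if f * fb > 0
        }

    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(k)]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(k)]
    if alleles is None:
        alleles = [_DEFAULT_ALLELE_CYCLE[i % len(_DEFAULT_ALLELE_CYCLE)] for i in range(k)]
    meta = pd.DataFrame(
        {
            "chrom": str(chrom),
            "pos": list(positions),
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
            "minor": [a[0] for a in alleles],
        },
        index=pd.Index(list(snp_ids), name="snp"),
    )
    hap_keys = sorted(haps)
    strings = [
        "".join(alleles[i][0] if h[i] else alleles[i][1] for i in range(k)) for h in hap_keys
    ]
    pool = HaplotypePool(strings, np.array([haps[h] for h in hap_keys]), meta)

    got = pool.mafs()
    if np.abs(got - np.array(target_mafs)).max() > 1e-9:
        raise AssertionError("pool marginal MAFs drifted from targets")
    start = 0
    for length, r2 in block_spec:
        ids = pool.snp_ids[start : start + length]
        for a, b in product(range(length), repeat=2):
            if a < b and r2 > 0:
                _, got_r2, _ = pool.exact_ld(ids[a], ids[b])
                if got_r2 < r2 - 1e-9:
                    raise AssertionError(
                        f"within-block r2 {got_r2:.4f} below requested {r2} for {ids[a]},{ids[b]}"
                    )
        start += length
    return pool


def simulate_genotypes(pool: HaplotypePool, n: int, seed: int) -> GenotypeMatrix:
    """Draw n unrelated diploid samples: two independent pool haplotypes each."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(pool.haplotypes), size=(n, 2), p=pool.frequencies)
    m = pool.minor_matrix()
    dosages = m[draws[:, 0]] + m[draws[:, 1]]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, pool.snp_meta.copy(), dosages)


def simulate_expression(
    geno: GenotypeMatrix,
    model: EffectModel,
    seed: int,
    feature_id: str = "GENE1",
) -> ExpressionMatrix:
    """Expression per sample: baseline * fold_factor(dosage) * exp(noise).

    Missing dosages contribute no genetic effect (treated as zero copies).
    """
    dosage = geno.dosage_vector(model.causal_snp)
    dosage = np.nan_to_num(dosage, nan=0.0)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, model.noise_sd, size=geno.n_samples)
    values = model.baseline * model.fold_factor(dosage) * np.exp(eps)
    return ExpressionMatrix([feature_id], list(geno.sample_ids), values[None, :])


def simulate_case_control(
    pool: HaplotypePool,
    risk_haplotype: str,
    odds_ratio: float,
    baseline_prevalence: float,
    n_cases: int,
    n_controls: int,
    seed: int,
    max_draws: int = 10_000_000,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Rejection-sample a case-control cohort with haplotype-driven risk.

    Disease odds are multiplied by ``odds_ratio`` per copy of the risk
    haplotype (log-additive). ``risk_haplotype`` is an allele string over the
    pool's SNPs; '*' matches any allele, so risk can be attached to a single
    SNP allele rather than a full haplotype. Individuals are drawn from the
    pool and assigned case status from their risk-copy count, until both
    quotas are filled; raises QuotaError after ``max_draws`` attempts.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not 0 < baseline_prevalence < 1:
        raise ValueError("baseline_prevalence must be in (0, 1)")
    indicator = pool.match_indicator(risk_haplotype)
    if indicator.sum() == 0:
        raise ValueError(f"risk haplotype {risk_haplotype!r} matches no pool haplotype")
    rng = np.random.default_rng(seed)
    m = pool.minor_matrix()
    base_logit = np.log(baseline_prevalence / (1 - baseline_prevalence))
    log_or = np.log(odds_ratio)

    case_rows, control_rows = [], []
    drawn = 0
    batch = max(1024, 2 * (n_cases + n_controls))
    while (len(case_rows) < n_cases or len(control_rows) < n_controls) and drawn < max_draws:
        h = rng.choice(len(pool.haplotypes), size=(batch, 2), p=pool.frequencies)
        drawn += batch
        copies = indicator[h[:, 0]] + indicator[h[:, 1]]
        p_case = 1.0 / (1.0 + np.exp(-(base_logit + log_or * copies)))
        is_case = rng.random(batch) < p_case
        dosages = m[h[:, 0]] + m[h[:, 1]]
        for row, case in zip(dosages, is_case):
            if case and len(case_rows) < n_cases:
                case_rows.append(row)
            elif not case and len(control_rows) < n_controls:
                control_rows.append(row)
    if len(case_rows) < n_cases or len(control_rows) < n_controls:
        raise QuotaError(
            f"quotas unreachable after {drawn} draws "
            f"({len(case_rows)}/{n_cases} cases, {len(control_rows)}/{n_controls} controls)"
        )
    dosages = np.vstack(case_rows + control_rows)
    status = np.array([1] * n_cases + [0] * n_controls)
    sample_ids = [f"CC{i + 1:06d}" for i in range(n_cases + n_controls)]
    geno = GenotypeMatrix(sample_ids, pool.snp_meta.copy(), dosages.astype(float))
    return geno, PhenotypeTable(sample_ids, status)
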