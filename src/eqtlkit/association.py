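"""Case-control association: allelic 2x2 tests with odds ratios, additive
logistic regression, covariate-conditioned ("conditioned") association, and
EM-based haplotype association.

"Conditioned" association is covariate adjustment in an ordinary logistic
model — the test SNP's dosage plus the conditioning SNP's dosage as additive
terms — not a matched-set conditional likelihood. The haplotype test compares
EM-expected haplotype counts between cases and controls in a 2x2 chi-squared
table, reporting only haplotypes above a pooled frequency floor.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datatypes import DataError, GenotypeMatrix, PhenotypeTable
from .io import align_samples
from .popgen import em_haplotype_freqs

Z_95 = float(stats.norm.ppf(0.975))


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient (e.g. conditioning SNP collinear)."""


class SeparationError(RuntimeError):
    """Perfect separation: logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class AssociationRecord:
    """One row of a per-SNP case-control association table."""

    snp_id: str
    risk_allele: str
    f_a: float
    f_u: float
    or_allelic: float
    ci95: tuple[float, float]
    p: float
    p_cond: Optional[float] = None
    or_cond: Optional[float] = None
    condition_snp: Optional[str] = None


@dataclasses.dataclass
class HaplotypeAssociationRow:
    haplotype: str
    f_a: float
    f_u: float
    odds_ratio: float
    p: float
    pooled_freq: float


@dataclasses.dataclass
class LogisticTerm:
    term: str
    beta: float
    se: float
    odds_ratio: float
    p: float


def _split_counts(dosage: np.ndarray, status: np.ndarray):
    """Minor/major allele counts in cases and controls (pairwise deletion)."""
    ok = ~np.isnan(dosage)
    d, s = dosage[ok], status[ok]
    if len(np.unique(s)) < 2:
        raise DataError("both phenotype classes must be present")
    a = float(d[s == 1].sum())  # minor alleles in cases
    b = 2.0 * (s == 1).sum() - a
    c = float(d[s == 0].sum())
    e = 2.0 * (s == 0).sum() - c
    return a, b, c, e


def allelic_test(
    geno: GenotypeMatrix, snp_id: str, pheno: PhenotypeTable
) -> AssociationRecord:
    """Allelic 2x2 association of the minor allele with case status.

    OR is the cross product with Haldane-Anscombe +0.5 correction when any
    cell is zero; the 95% CI is exp(log OR +/- 1.96 * sqrt(sum 1/cell)); p is
    the chi-squared test on the uncorrected table.
    """
    g, ph = align_samples(geno, pheno)
    a, b, c, e = _split_counts(g.dosage_vector(snp_id), ph.status)
    if a + c == 0 or b + e == 0:
        raise DataError(f"SNP {snp_id} is monomorphic")
    if (a + b) == 0 or (c + e) == 0:
        raise DataError("both phenotype classes must have genotyped samples")
    f_a = a / (a + b)
    f_u = c / (c + e)
    cells = np.array([a, b, c, e])
    if (cells == 0).any():
        cells = cells + 0.5
    or_allelic = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = np.sqrt((1.0 / cells).sum())
    ci = (float(or_allelic * np.exp(-Z_95 * se)), float(or_allelic * np.exp(Z_95 * se)))
    chi2, p, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, e]]), correction=False
    )
    if chi2 == 0:
        p = 1.0
    row = g.snp_meta.loc[snp_id]
    return AssociationRecord(
        snp_id=snp_id,
        risk_allele=str(row["minor"]),
        f_a=float(f_a),
        f_u=float(f_u),
        or_allelic=float(or_allelic),
        ci95=ci,
        p=float(p),
    )


def logistic_assoc(
    geno: GenotypeMatrix,
    snp_id: str,
    pheno: PhenotypeTable,
    covariate_snps: Sequence[str] = (),
    min_per_class: int = 10,
) -> list[LogisticTerm]:
    """Additive-coding logistic regression of case status on SNP dosages.

    Fits status ~ intercept + dosage(snp) + dosage(covariates) by maximum
    likelihood (Newton, log-likelihood tolerance 1e-8, 100 iterations) and
    returns Wald statistics per term. Raises on rank deficiency, perfect
    separation, non-convergence, or fewer than ``min_per_class`` samples in
    either class.
    """
    g, ph = align_samples(geno, pheno)
    terms = [snp_id] + list(covariate_snps)
    cols = [g.dosage_vector(s) for s in terms]
    X = np.column_stack(cols)
    ok = ~np.isnan(X).any(axis=1)
    X, y = X[ok], ph.status[ok]
    if (y == 1).sum() < min_per_class or (y == 0).sum() < min_per_class:
        raise DataError(f"need >= {min_per_class} samples per class after deletion")
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank deficient for terms {['const'] + terms}"
        )
    try:
        fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise SeparationError(f"logistic fit failed: {e}") from None
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic regression did not converge in 100 iterations")
    if not np.isfinite(fit.bse).all():
        raise SeparationError("non-finite standard errors: quasi-separation")
    out = []
    for name, beta, se, p in zip(
        ["const"] + terms, fit.params, fit.bse, fit.pvalues
    ):
        out.append(
            LogisticTerm(
                term=name,
                beta=float(beta),
                se=float(se),
                odds_ratio=float(np.exp(beta)),
                p=float(p),
            )
        )
    return out


def conditional_scan(
    geno: GenotypeMatrix,
    snp_ids: Sequence[str],
    pheno: PhenotypeTable,
    condition_snp: str,
) -> list[AssociationRecord]:
    """Allelic association per SNP plus a conditioned logistic p-value.

    For each test SNP the logistic model includes ``condition_snp``'s dosage
    as a covariate; ``p_cond`` / ``or_cond`` come from the test SNP's Wald
    term. Errors from a degenerate fit (e.g. testing the conditioning SNP
    against itself) propagate.
    """
    records = []
    for snp in snp_ids:
        rec = allelic_test(geno, snp, pheno)
        terms = logistic_assoc(geno, snp, pheno, covariate_snps=[condition_snp])
        test_term = terms[1]
        rec.p_cond = test_term.p
        rec.or_cond = test_term.odds_ratio
        rec.condition_snp = condition_snp
        records.append(rec)
    return records


def haplotype_assoc(
    geno: GenotypeMatrix,
    snp_ids: Sequence[str],
    pheno: PhenotypeTable,
    freq_floor: float = 0.05,
) -> list[HaplotypeAssociationRow]:
    """Case-control haplotype association over 2..6 SNPs.

    Haplotype frequencies are EM-estimated separately in cases and controls;
    expected haplotype counts (2n * frequency) feed a 2x2 chi-squared test
    (haplotype vs all others, case vs control) and a cross-product OR with
    +0.5 correction on zero counts. Haplotypes with pooled frequency at or
    below ``freq_floor`` are suppressed (their mass still counts in the EM
    normalization). Rows are ordered by decreasing pooled frequency.
    """
    if not 2 <= len(snp_ids) <= 6:
        raise ValueError("haplotype association supports 2..6 SNPs")
    g, ph = align_samples(geno, pheno)
    case_ids = [s for s, st in zip(g.sample_ids, ph.status) if st == 1]
    ctrl_ids = [s for s, st in zip(g.sample_ids, ph.status) if st == 0]
    if not case_ids or not ctrl_ids:
        raise DataError("both phenotype classes must be present")
    t_case = em_haplotype_freqs(g.subset_samples(case_ids), snp_ids)
    t_ctrl = em_haplotype_freqs(g.subset_samples(ctrl_ids), snp_ids)
    n_case_ch = 2.0 * t_case.n_used
    n_ctrl_ch = 2.0 * t_ctrl.n_used

    rows = []
    for hap, f_a, f_u in zip(t_case.haplotypes, t_case.frequencies, t_ctrl.frequencies):
        pooled = (n_case_ch * f_a + n_ctrl_ch * f_u) / (n_case_ch + n_ctrl_ch)
        if pooled <= freq_floor:
            continue
        a = n_case_ch * f_a
        b = n_case_ch - a
        c = n_ctrl_ch * f_u
        d = n_ctrl_ch - c
        cells = np.array([a, b, c, d])
        or_cells = cells + 0.5 if np.any(cells < 0.5) else cells
        or_hap = (or_cells[0] * or_cells[3]) / (or_cells[1] * or_cells[2])
        exp_tot = cells.sum()
        row_tot = np.array([a + b, c + d])
        col_tot = np.array([a + c, b + d])
        expected = np.outer(row_tot, col_tot) / exp_tot
        observed = np.array([[a, b], [c, d]])
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.nansum((observed - expected) ** 2 / expected)
        p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
        rows.append(
            HaplotypeAssociationRow(
                haplotype=hap,
                f_a=float(f_a),
                f_u=float(f_u),
                odds_ratio=float(or_hap),
                p=p,
                pooled_freq=float(pooled),
            )
        )
    rows.sort(key=lambda r: -r.pooled_freq)
    return rows
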