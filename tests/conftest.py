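import numpy as np
import pandas as pd
import pytest

from eqtlkit.datatypes import GenotypeMatrix, PhenotypeTable
from eqtlkit.simulate import HaplotypePool


def make_snp_meta(snp_ids, alleles, chrom="6", positions=None):
    """snp_meta DataFrame; alleles = list of (minor, major)."""
    if positions is None:
        positions = [1000 * (i + 1) for i in range(len(snp_ids))]
    return pd.DataFrame(
        {
            "chrom": str(chrom),
            "pos": positions,
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
            "minor": [a[0] for a in alleles],
        },
        index=pd.Index(snp_ids, name="snp"),
    )


def geno_from_dosages(dosages, snp_ids=None, alleles=None, chrom="6", positions=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    meta = make_snp_meta(snp_ids, alleles, chrom, positions)
    samples = [f"S{i + 1:04d}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(samples, meta, dosages)


@pytest.fixture
def pool2():
    """Two-SNP pool with haplotype frequencies 0.4 / 0.1 / 0.3 / 0.2.

    SNP1 minor A (freq 0.5); SNP2 alleles C/T with C at 0.7, so minor is T.
    Haplotypes: AC 0.4, AT 0.1, GC 0.3, GT 0.2.
    """
    meta = pd.DataFrame(
        {
            "chrom": "6",
            "pos": [1000, 2000],
            "allele1": ["A", "T"],
            "allele2": ["G", "C"],
            "minor": ["A", "T"],
        },
        index=pd.Index(["rs1", "rs2"], name="snp"),
    )
    return HaplotypePool(
        ["AC", "AT", "GC", "GT"], np.array([0.4, 0.1, 0.3, 0.2]), meta
    )


@pytest.fixture
def phenotype_balanced():
    def _make(n_case, n_control):
        ids = [f"S{i + 1:04d}" for i in range(n_case + n_control)]
        return PhenotypeTable(ids, np.array([1] * n_case + [0] * n_control))

    return _make
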