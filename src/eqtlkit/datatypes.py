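"""Core in-memory containers: genotype, expression and phenotype matrices.

Genotypes are stored as minor-allele dosages (0/1/2, NaN = missing) in a
samples x SNPs float array, with per-SNP metadata (chromosome, 1-based
position, allele pair, minor allele) in a DataFrame indexed by SNP id.
Coordinates are 1-based and all region queries use closed intervals.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ("chrom", "pos", "allele1", "allele2", "minor")


class DataError(ValueError):
    """Base class for malformed or inconsistent input data."""


class DuplicateIdError(DataError):
    pass


class MalformedInputError(DataError):
    pass


class TriallelicSnpError(DataError):
    pass


class EmptyIntersectionError(DataError):
    pass


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise DuplicateIdError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with SNP metadata.

    Attributes
    ----------
    sample_ids : list of str
        Unique, order-significant sample identifiers.
    snp_meta : pandas.DataFrame
        Indexed by SNP id with columns ``chrom`` (str), ``pos`` (1-based int),
        ``allele1``/``allele2`` (the allele pair) and ``minor`` (which of the
        pair is counted by the dosage).
    dosages : numpy.ndarray
        float array of shape (n_samples, n_snps); entries in {0, 1, 2} or NaN.
    """

    sample_ids: list[str]
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(list(self.snp_meta.index), "SNP ids")
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise MalformedInputError(f"snp_meta missing columns {sorted(missing_cols)}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise MalformedInputError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_meta)} SNPs"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise MalformedInputError("dosages must be 0, 1, 2 or missing")
        if (self.snp_meta["pos"].astype(np.int64) < 0).any():
            raise MalformedInputError("SNP positions must be non-negative")
        bad = ~(
            (self.snp_meta["minor"] == self.snp_meta["allele1"])
            | (self.snp_meta["minor"] == self.snp_meta["allele2"])
        )
        if bad.any():
            raise MalformedInputError(
                f"minor allele not in allele pair for {list(self.snp_meta.index[bad])[:5]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta.index)

    def snp_index(self, snp_id: str) -> int:
        try:
            return int(self.snp_meta.index.get_loc(snp_id))
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_meta=self.snp_meta.iloc[idx].copy(),
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            snp_meta=self.snp_meta.copy(),
            dosages=self.dosages[idx, :].copy(),
        )

    def flip_minor(self, snp_id: str) -> "GenotypeMatrix":
        """Re-designate the other allele as minor; dosage d maps to 2 - d."""
        j = self.snp_index(snp_id)
        meta = self.snp_meta.copy()
        row = meta.iloc[j]
        other = row["allele2"] if row["minor"] == row["allele1"] else row["allele1"]
        meta.iat[j, meta.columns.get_loc("minor")] = other
        dos = self.dosages.copy()
        dos[:, j] = 2.0 - dos[:, j]
        return GenotypeMatrix(list(self.sample_ids), meta, dos)

    def genotype_labels(self, snp_id: str) -> np.ndarray:
        """Genotype strings (e.g. 'AG') per sample; missing -> ''."""
        j = self.snp_index(snp_id)
        row = self.snp_meta.iloc[j]
        minor = row["minor"]
        major = row["allele2"] if minor == row["allele1"] else row["allele1"]
        lut = {0.0: major + major, 1.0: "".join(sorted(minor + major)), 2.0: minor + minor}
        return np.array(
            ["" if np.isnan(d) else lut[d] for d in self.dosages[:, j]], dtype=object
        )


@dataclasses.dataclass
class ExpressionMatrix:
    """Features (genes / probes / transcripts) x samples abundance matrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise MalformedInputError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.values.size and np.isinf(self.values).any():
            raise MalformedInputError("expression values must be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_vector(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in expression matrix") from None
        return self.values[i, :]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx].copy(),
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
        )


@dataclasses.dataclass
class PhenotypeTable:
    """Case-control status per sample (control = 0, case = 1)."""

    sample_ids: list[str]
    status: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample ids")
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.sample_ids),):
            raise MalformedInputError("status length does not match sample ids")
        if self.status.size and not np.isin(self.status, (0, 1)).all():
            raise MalformedInputError("status must be 0 (control) or 1 (case)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PhenotypeTable(
            sample_ids=list(sample_ids),
            status=self.status[idx].copy(),
            covariates=None if self.covariates is None else self.covariates.iloc[idx].copy(),
        )
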