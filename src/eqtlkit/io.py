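"""Readers and writers for genotype, expression and phenotype files.

Supported formats
-----------------
* PLINK PED/MAP text pairs (``read_ped_map`` / ``write_ped_map``).
* Sample x SNP dosage TSV: first column ``sample``, remaining columns SNP ids,
  cells 0/1/2 or ``NA``.
* Feature x sample expression TSV: first column ``feature``, remaining columns
  sample ids.
* HapMap-style genotype text: header ``rs# alleles chrom pos ...`` followed by
  one two-letter genotype per sample column (``NN`` = missing).
* Two-column phenotype TSV (``sample``, ``status``).

The minor allele at each SNP is the lower-frequency allele in the loaded
cohort; frequency ties break to the lexicographically smaller allele. ``0 0``
(PED) and ``NN`` (HapMap) genotypes are missing. All writers emit
deterministic column order so identical data round-trips byte-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import (
    DuplicateIdError,
    EmptyIntersectionError,
    ExpressionMatrix,
    GenotypeMatrix,
    MalformedInputError,
    PhenotypeTable,
    TriallelicSnpError,
)

logger = logging.getLogger(__name__)

_HAPMAP_META_FIELDS = {
    "strand",
    "assembly#",
    "center",
    "protLSID",
    "assayLSID",
    "panelLSID",
    "QCcode",
}


def _minor_of(counts: dict) -> Tuple[str, str]:
    """(minor, major) from allele counts; tie -> lexicographically smaller minor."""
    alleles = sorted(counts)  # lexicographic, deterministic
    if len(alleles) == 1:
        # monomorphic in this cohort: the unobserved allele is unknown
        return "0", alleles[0]
    a, b = alleles
    if counts[a] < counts[b]:
        return a, b
    if counts[b] < counts[a]:
        return b, a
    return a, b  # tie: lexicographically smaller is minor


def _dosages_from_allele_pairs(
    pairs: np.ndarray, snp_ids: list, chroms: list, positions: list
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build snp_meta + dosage matrix from (n_samples, n_snps, 2) allele letters.

    '0' entries denote missing calls.
    """
    n, m, _ = pairs.shape
    dosages = np.full((n, m), np.nan)
    meta_rows = []
    for j in range(m):
        col = pairs[:, j, :]
        present = col[col != "0"]
        counts: dict = {}
        for a in present:
            counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise TriallelicSnpError(
                f"SNP {snp_ids[j]} has more than two alleles: {sorted(counts)}"
            )
        if counts:
            minor, major = _minor_of(counts)
        else:
            minor, major = "0", "0"
        a1, a2 = (minor, major) if minor != "0" else (major, "0")
        meta_rows.append(
            {"chrom": str(chroms[j]), "pos": int(positions[j]), "allele1": a1,
             "allele2": a2, "minor": minor if minor != "0" else a1}
        )
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        if minor == "0":
            dosages[called, j] = 0.0
        else:
            dosages[called, j] = (col[called] == minor).sum(axis=1)
    meta = pd.DataFrame(meta_rows, index=pd.Index(snp_ids, name="snp"))
    return meta, dosages


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a dosage matrix.

    MAP rows are ``chrom snp_id genetic_dist pos``; PED rows are six leading
    fields (FID IID PAT MAT SEX PHENO) then two allele columns per SNP.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 4:
            raise MalformedInputError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(f)}")
        map_rows.append((f[0], f[1], int(f[3])))
    snp_ids = [r[1] for r in map_rows]
    if len(set(snp_ids)) != len(snp_ids):
        raise DuplicateIdError(f"duplicate SNP ids in {map_path}")
    m = len(map_rows)

    sample_ids, rows = [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * m:
            raise MalformedInputError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} columns for {m} SNPs, got {len(f)}"
            )
        sample_ids.append(f[1])
        rows.append(np.array(f[6:], dtype=object).reshape(m, 2))
    pairs = (
        np.stack(rows, axis=0) if rows else np.empty((0, m, 2), dtype=object)
    )
    meta, dosages = _dosages_from_allele_pairs(
        pairs, snp_ids, [r[0] for r in map_rows], [r[2] for r in map_rows]
    )
    return GenotypeMatrix(sample_ids, meta, dosages)


def write_ped_map(geno: GenotypeMatrix, ped_path, map_path) -> None:
    map_lines = [
        f"{row.chrom}\t{snp}\t0\t{row.pos}"
        for snp, row in geno.snp_meta.iterrows()
    ]
    Path(map_path).write_text("\n".join(map_lines) + ("\n" if map_lines else ""))

    minors = geno.snp_meta["minor"].to_numpy()
    majors = np.where(
        geno.snp_meta["minor"] == geno.snp_meta["allele1"],
        geno.snp_meta["allele2"],
        geno.snp_meta["allele1"],
    )
    ped_lines = []
    for i, sid in enumerate(geno.sample_ids):
        fields = [sid, sid, "0", "0", "0", "-9"]
        for j in range(geno.n_snps):
            d = geno.dosages[i, j]
            if np.isnan(d):
                fields += ["0", "0"]
            elif d == 0:
                fields += [majors[j], majors[j]]
            elif d == 1:
                fields += [minors[j], majors[j]]
            else:
                fields += [minors[j], minors[j]]
        ped_lines.append(" ".join(fields))
    Path(ped_path).write_text("\n".join(ped_lines) + ("\n" if ped_lines else ""))


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a sample x SNP dosage TSV (header: ``sample`` then SNP ids).

    The format carries no SNP metadata, so placeholder metadata is attached:
    chromosome "0", position = column order (1-based), synthetic allele pair
    ("1" minor / "2" major).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "sample":
        raise MalformedInputError(f"{path}: first header column must be 'sample'")
    snp_ids = header[1:]
    if len(set(snp_ids)) != len(snp_ids):
        raise DuplicateIdError(f"duplicate SNP columns in {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    meta = pd.DataFrame(
        {
            "chrom": "0",
            "pos": np.arange(1, len(snp_ids) + 1),
            "allele1": "1",
            "allele2": "2",
            "minor": "1",
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    return GenotypeMatrix(list(df["sample"]), meta, dosages)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.snp_ids)
    df.insert(0, "sample", geno.sample_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = [row["sample"]] + [
                "NA" if np.isnan(v) else str(int(v)) for v in row.iloc[1:]
            ]
            fh.write("\t".join(cells) + "\n")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a feature x sample expression TSV (header: ``feature`` then sample ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "feature":
        raise MalformedInputError(f"{path}: first header column must be 'feature'")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise DuplicateIdError(f"duplicate sample columns in {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as e:
        raise MalformedInputError(f"{path}: non-numeric expression cell ({e})") from None
    return ExpressionMatrix(list(df["feature"]), sample_ids, values)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["feature"] + expr.sample_ids) + "\n")
        for i, fid in enumerate(expr.feature_ids):
            fh.write("\t".join([fid] + [repr(float(v)) for v in expr.values[i]]) + "\n")


def read_hapmap_genotypes(path) -> GenotypeMatrix:
    """Read the HapMap genotype text dialect.

    Header starts ``rs# alleles chrom pos`` optionally followed by standard
    metadata columns (strand, assembly#, center, ...); every remaining column
    is a sample. Genotypes are two-letter codes, ``NN`` = missing.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise MalformedInputError(f"{path}: empty file")
    header = lines[0].split()
    if header[:4] != ["rs#", "alleles", "chrom", "pos"]:
        raise MalformedInputError(
            f"{path}: header must start 'rs# alleles chrom pos', got {header[:4]}"
        )
    first_sample = 4
    while first_sample < len(header) and header[first_sample] in _HAPMAP_META_FIELDS:
        first_sample += 1
    sample_ids = header[first_sample:]
    snp_ids, chroms, positions, rows = [], [], [], []
    for ln, line in enumerate(lines[1:], 2):
        f = line.split()
        if len(f) != len(header):
            raise MalformedInputError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(f)}"
            )
        snp_ids.append(f[0])
        chroms.append(f[2].removeprefix("chr"))
        positions.append(int(f[3]))
        geno_codes = f[first_sample:]
        row = []
        for g in geno_codes:
            if len(g) != 2:
                raise MalformedInputError(f"{path}:{ln}: bad genotype code {g!r}")
            row.append(["0", "0"] if g.upper() == "NN" else [g[0], g[1]])
        rows.append(row)
    if len(set(snp_ids)) != len(snp_ids):
        raise DuplicateIdError(f"duplicate SNP ids in {path}")
    pairs = np.array(rows, dtype=object)  # (n_snps, n_samples, 2)
    pairs = (
        pairs.transpose(1, 0, 2)
        if pairs.size
        else np.empty((len(sample_ids), 0, 2), dtype=object)
    )
    meta, dosages = _dosages_from_allele_pairs(pairs, snp_ids, chroms, positions)
    return GenotypeMatrix(sample_ids, meta, dosages)


def read_phenotype_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if list(df.columns[:2]) != ["sample", "status"]:
        raise MalformedInputError(f"{path}: header must be 'sample<TAB>status'")
    return PhenotypeTable(list(df["sample"]), df["status"].to_numpy(dtype=int))


def write_phenotype_tsv(pheno: PhenotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstatus\n")
        for s, st in zip(pheno.sample_ids, pheno.status):
            fh.write(f"{s}\t{int(st)}\n")


def align_samples(
    geno: GenotypeMatrix,
    other: Union[ExpressionMatrix, PhenotypeTable],
):
    """Intersect and identically order samples of a genotype matrix and a
    companion table (expression or phenotype). Dropped counts are logged."""
    other_set = set(other.sample_ids)
    shared = [s for s in geno.sample_ids if s in other_set]
    if not shared:
        raise EmptyIntersectionError("no samples shared between genotype and companion table")
    dropped = (geno.n_samples - len(shared)) + (len(other.sample_ids) - len(shared))
    if dropped:
        logger.info("align_samples: kept %d shared samples, dropped %d", len(shared), dropped)
    return geno.subset_samples(shared), other.subset_samples(shared)


def restrict_region(
    geno: GenotypeMatrix, chromosome: str, start_bp: int, end_bp: int
) -> GenotypeMatrix:
    """SNPs with start_bp <= pos <= end_bp on the chromosome (1-based, closed)."""
    if start_bp > end_bp:
        raise ValueError("start_bp must be <= end_bp")
    chromosome = str(chromosome).removeprefix("chr")
    meta = geno.snp_meta
    keep = (meta["chrom"].astype(str) == chromosome) & (
        meta["pos"].astype(np.int64) >= start_bp
    ) & (meta["pos"].astype(np.int64) <= end_bp)
    return geno.subset_snps(list(meta.index[keep]))
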