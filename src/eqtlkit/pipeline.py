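"""Study orchestration: per-population cis-eQTL scans, cross-population
intersection of significant SNPs, GWAS-hit/eQTL overlap through LD, and the
case-control association stages — driven by one YAML config, with a manifest
recording seed, config hash and package version so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import conditional_scan, haplotype_assoc
from .datatypes import GenotypeMatrix
from .io import (
    read_dosage_tsv,
    read_expression_tsv,
    read_hapmap_genotypes,
    read_ped_map,
    read_phenotype_tsv,
)
from .popgen import UndefinedStatisticError, pairwise_ld
from .scan import EqtlRecord, ScanConfig, cis_scan

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PopulationBlock:
    name: str
    genotypes: str
    expression: str


@dataclasses.dataclass
class AssociationBlock:
    genotypes: str
    phenotypes: str
    snps: list[str]
    condition_snp: Optional[str] = None
    haplotype_snps: Optional[list[str]] = None
    freq_floor: float = 0.05


@dataclasses.dataclass
class StudyConfig:
    populations: list[PopulationBlock]
    features: list[str]
    scan: ScanConfig
    gwas_hits: Optional[str] = None
    ld_overlap_threshold: float = 0.5
    gwas_p_threshold: float = 1e-7
    association: Optional[AssociationBlock] = None

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        region = raw.get("region", {})
        scan_raw = raw.get("scan", {})
        scan = ScanConfig(
            chromosome=str(region.get("chromosome", "6")),
            start=int(region.get("start", 1)),
            end=int(region.get("end", 2**31 - 1)),
            n_permutations=int(scan_raw.get("n_permutations", 10000)),
            pt=float(scan_raw.get("pt", 0.0001)),
            seed=int(scan_raw.get("seed", 0)),
        )
        pops = [PopulationBlock(**p) for p in raw["populations"]]
        assoc = None
        if "association" in raw:
            assoc = AssociationBlock(**raw["association"])
        overlap = raw.get("ld_overlap", {})
        return cls(
            populations=pops,
            features=list(raw["features"]),
            scan=scan,
            gwas_hits=raw.get("gwas_hits"),
            ld_overlap_threshold=float(overlap.get("r2_threshold", 0.5)),
            gwas_p_threshold=float(overlap.get("p_threshold", 1e-7)),
            association=assoc,
        )


def load_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: .ped (+ sibling .map), .tsv dosage, else HapMap text."""
    p = Path(path)
    if p.suffix == ".ped":
        return read_ped_map(p, p.with_suffix(".map"))
    if p.suffix == ".tsv":
        return read_dosage_tsv(p)
    return read_hapmap_genotypes(p)


def eqtl_records_frame(records: Sequence[EqtlRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "snp": r.snp_id,
                "position": r.position,
                "feature": r.feature_id,
                "n": r.n_used,
                "rho": "NA" if r.rho is None else f"{r.rho:.6g}",
                "p_nominal": "NA" if r.p_nominal is None else f"{r.p_nominal:.6g}",
                "p_empirical": "NA" if r.p_empirical is None else f"{r.p_empirical:.6g}",
                "significant": int(r.significant),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp", "position", "feature", "n", "rho", "p_nominal",
                 "p_empirical", "significant"],
    )


def intersect_top_eqtls(per_population: Sequence[Sequence[EqtlRecord]]) -> list[str]:
    """SNP ids flagged significant in every population, position-sorted."""
    if not per_population:
        raise ValueError("need at least one population")
    sig_sets = [
        {r.snp_id for r in records if r.significant} for records in per_population
    ]
    shared = set.intersection(*sig_sets)
    positions = {
        r.snp_id: r.position for records in per_population for r in records
    }
    return sorted(shared, key=lambda s: (positions[s], s))


def gwas_eqtl_overlap(
    eqtl_records: Sequence[EqtlRecord],
    gwas_hits: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_threshold: float = 0.5,
    gwas_p_threshold: float = 1e-7,
) -> pd.DataFrame:
    """Cross significant eQTLs with GWAS hits through LD.

    A row is emitted for every (GWAS SNP with p < gwas_p_threshold, significant
    eQTL SNP) pair that is the same SNP or has r-squared >= r2_threshold on the
    shared genotype panel. SNPs absent from the panel are skipped with a
    warning in the log.
    """
    sig = [r for r in eqtl_records if r.significant]
    hits = gwas_hits[gwas_hits["p"].astype(float) < gwas_p_threshold]
    known = set(geno.snp_ids)
    rows = []
    for _, hit in hits.iterrows():
        gsnp = str(hit["snp"])
        if gsnp not in known:
            logger.warning("GWAS SNP %s absent from genotype panel; skipped", gsnp)
            continue
        for rec in sig:
            if rec.snp_id not in known:
                logger.warning("eQTL SNP %s absent from genotype panel; skipped", rec.snp_id)
                continue
            if gsnp == rec.snp_id:
                r2 = 1.0
            else:
                try:
                    r2 = pairwise_ld(geno, gsnp, rec.snp_id).r2
                except UndefinedStatisticError:
                    continue
            if r2 >= r2_threshold:
                rows.append(
                    {"gwas_snp": gsnp, "eqtl_snp": rec.snp_id,
                     "r2": f"{r2:.6g}", "gene": rec.feature_id}
                )
    df = pd.DataFrame(rows, columns=["gwas_snp", "eqtl_snp", "r2", "gene"])
    df = df.drop_duplicates(ignore_index=True)
    logger.info(
        "gwas_eqtl_overlap: %d distinct eQTLs, %d distinct GWAS SNPs",
        df["eqtl_snp"].nunique(), df["gwas_snp"].nunique(),
    )
    return df


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_study(config: StudyConfig, out_dir) -> Path:
    """Run the full study flow and write TSV reports plus a manifest.

    Outputs: ``eqtl_<population>.tsv`` per population, ``intersection.tsv``
    (SNPs significant everywhere), ``gwas_overlap.tsv`` when GWAS hits are
    configured, ``assoc.tsv`` / ``hap_assoc.tsv`` when the association block
    is configured, and ``manifest.txt``. Identical config + seed reproduce
    identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_pop: list[list[EqtlRecord]] = []
    all_records: list[EqtlRecord] = []
    panel: Optional[GenotypeMatrix] = None
    for pop in config.populations:
        try:
            geno = load_genotypes(pop.genotypes)
            expr = read_expression_tsv(pop.expression)
            records: list[EqtlRecord] = []
            for feat in config.features:
                records.extend(cis_scan(geno, expr, feat, config.scan))
        except Exception as e:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(f"eqtl_scan[{pop.name}]", e) from e
        per_pop.append(records)
        all_records.extend(records)
        panel = geno if panel is None else panel
        _write_tsv(eqtl_records_frame(records), out / f"eqtl_{pop.name}.tsv")

    try:
        shared = intersect_top_eqtls(per_pop)
    except Exception as e:
        raise StageError("intersect_top_eqtls", e) from e
    _write_tsv(pd.DataFrame({"snp": shared}), out / "intersection.tsv")

    if config.gwas_hits is not None and panel is not None:
        try:
            hits = pd.read_csv(config.gwas_hits, sep="\t")
            overlap = gwas_eqtl_overlap(
                all_records, hits, panel,
                r2_threshold=config.ld_overlap_threshold,
                gwas_p_threshold=config.gwas_p_threshold,
            )
        except Exception as e:
            raise StageError("gwas_eqtl_overlap", e) from e
        _write_tsv(overlap, out / "gwas_overlap.tsv")

    if config.association is not None:
        blk = config.association
        try:
            cc_geno = load_genotypes(blk.genotypes)
            pheno = read_phenotype_tsv(blk.phenotypes)
            test_snps = [s for s in blk.snps if s != blk.condition_snp]
            if blk.condition_snp:
                records = conditional_scan(cc_geno, test_snps, pheno, blk.condition_snp)
            else:
                from .association import allelic_test

                records = [allelic_test(cc_geno, s, pheno) for s in test_snps]
            rows = [
                {
                    "snp": r.snp_id,
                    "risk_allele": r.risk_allele,
                    "F_A": f"{r.f_a:.6g}",
                    "F_U": f"{r.f_u:.6g}",
                    "OR": f"{r.or_allelic:.6g}",
                    "CI95_low": f"{r.ci95[0]:.6g}",
                    "CI95_high": f"{r.ci95[1]:.6g}",
                    "P": f"{r.p:.6g}",
                    "P_cond": "NA" if r.p_cond is None else f"{r.p_cond:.6g}",
                    "OR_cond": "NA" if r.or_cond is None else f"{r.or_cond:.6g}",
                }
                for r in records
            ]
            _write_tsv(pd.DataFrame(rows), out / "assoc.tsv")
            if blk.haplotype_snps:
                hap_rows = haplotype_assoc(
                    cc_geno, blk.haplotype_snps, pheno, freq_floor=blk.freq_floor
                )
                _write_tsv(
                    pd.DataFrame(
                        [
                            {
                                "haplotype": h.haplotype,
                                "F_A": f"{h.f_a:.6g}",
                                "F_U": f"{h.f_u:.6g}",
                                "OR": f"{h.odds_ratio:.6g}",
                                "P": f"{h.p:.6g}",
                            }
                            for h in hap_rows
                        ],
                        columns=["haplotype", "F_A", "F_U", "OR", "P"],
                    ),
                    out / "hap_assoc.tsv",
                )
        except StageError:
            raise
        except Exception as e:
            raise StageError("association", e) from e

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.txt").write_text(
        f"eqtlkit_version\t{__version__}\n"
        f"seed\t{config.scan.seed}\n"
        f"config_sha256\t{cfg_hash}\n"
        f"n_populations\t{len(config.populations)}\n"
        f"n_permutations\t{config.scan.n_permutations}\n"
        f"pt\t{config.scan.pt}\n"
    )
    return out
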