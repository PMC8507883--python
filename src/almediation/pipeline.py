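"""End-to-end orchestration: QC -> phenotype derivation -> scan -> mediation.

``run_pipeline`` executes the stages on files or in-memory objects and writes
every result table plus a machine-readable run manifest (seed, thresholds,
exclusion counts, versions) from which the QC flow is reconstructible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .io import (
    config_hash,
    read_phenotypes,
    read_vcf,
    write_json,
    write_table,
)
from .mediate import mediate_snps, mediation_table
from .phenotype import additive_code, derive_phenotypes
from .qc import QCThresholds, run_qc
from .scan import ScanConfig, genome_scan, genomic_lambda, manhattan_table, qq_table
from .types import GenotypeMatrix

log = logging.getLogger("almediation")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    genotypes: str | None = None
    phenotypes: str | None = None
    out_dir: str = "results"
    qc: QCThresholds = field(default_factory=QCThresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    mediation_snps: tuple[str, ...] = ()
    n_boot: int = 3000
    level: float = 0.95
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(
    cfg: RunConfig,
    genotypes: GenotypeMatrix | None = None,
    phenotypes=None,
) -> dict:
    """Execute the pipeline and return the run manifest.

    Inputs may be passed in memory or read from ``cfg.genotypes`` (VCF) and
    ``cfg.phenotypes`` (TSV).  Outputs land in ``cfg.out_dir``: QC report
    (JSON), association scan, QQ/Manhattan tables, mediation table (TSV) and
    the manifest (JSON).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.to_dict())

    if genotypes is None:
        if cfg.genotypes is None:
            raise ValueError("no genotype input provided")
        genotypes = read_vcf(cfg.genotypes)
    if phenotypes is None:
        if cfg.phenotypes is None:
            raise ValueError("no phenotype input provided")
        phenotypes = read_phenotypes(cfg.phenotypes)

    log.info("input: %d samples x %d variants", genotypes.n_samples, genotypes.n_variants)

    # 1. QC
    filtered, report = run_qc(genotypes, cfg.qc)
    write_json(report.to_dict(), out / "qc_report.json", seed=cfg.seed, cfg_hash=chash)
    for rule, ids in report.excluded_samples_by_rule.items():
        log.info("QC %s: %d samples excluded", rule, len(ids))
    for rule, ids in report.excluded_variants_by_rule.items():
        log.info("QC %s: %d variants excluded", rule, len(ids))
    (out / "excluded_samples.txt").write_text(
        "".join(
            f"{sid}\t{rule}\n"
            for rule, ids in report.excluded_samples_by_rule.items()
            for sid in ids
        )
    )
    (out / "excluded_variants.txt").write_text(
        "".join(
            f"{vid}\t{rule}\n"
            for rule, ids in report.excluded_variants_by_rule.items()
            for vid in ids
        )
    )

    # 2. phenotype derivation + minor-allele coding
    pheno = derive_phenotypes(phenotypes)
    pheno = pheno[pheno["sample_id"].isin(filtered.sample_ids)].reset_index(drop=True)
    coded, coding_record = additive_code(filtered)
    write_table(coding_record, out / "allele_coding.tsv", seed=cfg.seed, cfg_hash=chash)

    # 3. association scan
    records = genome_scan(coded, pheno, cfg.scan)
    write_table(records, out / "association.tsv", seed=cfg.seed, cfg_hash=chash)
    qq, n_skipped = qq_table(records["P"])
    write_table(qq, out / "qq.tsv", seed=cfg.seed, cfg_hash=chash)
    write_table(
        manhattan_table(records), out / "manhattan.tsv", seed=cfg.seed, cfg_hash=chash
    )
    lam = genomic_lambda(records["P"])
    log.info("scan: %d variants, lambda=%.3f", len(records), lam)

    # 4. mediation on the configured SNPs
    med_df = None
    if cfg.mediation_snps:
        results = mediate_snps(
            coded,
            pheno,
            cfg.mediation_snps,
            n_boot=cfg.n_boot,
            level=cfg.level,
            seed=cfg.seed,
        )
        med_df = mediation_table(results)
        write_table(med_df, out / "mediation.tsv", seed=cfg.seed, cfg_hash=chash)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": chash,
        "config": cfg.to_dict(),
        "qc": report.to_dict(),
        "scan": {
            "n_records": int(len(records)),
            "bonferroni_threshold": records.attrs["bonferroni_threshold"],
            "bonferroni_display": records.attrs["bonferroni_display"],
            "suggestive_p": records.attrs["suggestive_p"],
            "genomic_lambda": lam,
            "n_unestimable": int(n_skipped),
            "tier_counts": records["TIER"].value_counts().to_dict(),
        },
        "mediation": None if med_df is None else med_df.to_dict(orient="records"),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
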