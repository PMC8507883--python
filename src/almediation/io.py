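"""File interfaces: VCF and dosage-TSV genotypes, phenotype tables, reports.

Every text writer stamps a header comment with the seed and a config hash so
a run is reproducible from its outputs alone.  Readers validate rather than
coerce: malformed records raise with as much location information as the
format allows.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import MISSING, PHENOTYPE_COLUMNS, GenotypeMatrix

_GT_MAP = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(seed=None, cfg_hash=None) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash={cfg_hash}")
    return lines


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(g: GenotypeMatrix, path, seed=None, cfg_hash=None) -> None:
    """Write diploid GT calls to an uncompressed VCF (``./.`` for missing)."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_meta("source", "almediation")
    if seed is not None:
        header.add_meta("almediation_seed", str(seed))
    if cfg_hash is not None:
        header.add_meta("almediation_config_hash", str(cfg_hash))
    header.formats.add("GT", 1, "String", "Genotype")
    for chrom in dict.fromkeys(g.variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    for s in g.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, var in g.variants.iterrows():
            rec = out.new_record(
                contig=str(var["chrom"]),
                start=int(var["pos"]) - 1,  # pysam start is 0-based
                stop=int(var["pos"]),
                alleles=(str(var["allele1"]), str(var["allele2"])),
                id=str(var["id"]),
            )
            for i, s in enumerate(g.sample_ids):
                rec.samples[s]["GT"] = _GT_MAP[int(g.calls[i, j])]
            out.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into alternate-allele counts.

    ``./.`` maps to the missing sentinel; multi-allelic records and duplicate
    variant ids are rejected.
    """
    path = str(path)
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        calls_rows, meta = [], []
        seen_ids = set()
        for k, rec in enumerate(vf):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {k + 1} ({rec.chrom}:{rec.pos}): exactly one ALT "
                    "allele required (multi-allelic records are not supported)"
                )
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            if vid in seen_ids:
                raise ValueError(f"duplicate variant id {vid!r} at record {k + 1}")
            seen_ids.add(vid)
            row = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[i] = MISSING
                else:
                    if any(a not in (0, 1) for a in gt):
                        raise ValueError(
                            f"record {k + 1}: allele index out of range in GT {gt}"
                        )
                    row[i] = sum(gt)
            calls_rows.append(row)
            meta.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # pysam .pos is 1-based
                    "id": vid,
                    "allele1": rec.ref,
                    "allele2": rec.alts[0],
                }
            )
    if not meta:
        raise ValueError(f"no variant records in {path}")
    calls = np.column_stack(calls_rows) if calls_rows else np.empty((len(samples), 0))
    return GenotypeMatrix(calls.astype(np.int8), samples, pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# dosage TSV
# ---------------------------------------------------------------------------


def write_dosage_tsv(g: GenotypeMatrix, calls_path, variants_path, seed=None, cfg_hash=None) -> None:
    """Samples x variants additive dosage TSV plus a variant table."""
    df = pd.DataFrame(g.calls, index=g.sample_ids, columns=g.variants["id"])
    df = df.replace(MISSING, pd.NA)
    with open(calls_path, "w") as fh:
        for line in _header_comment(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label="sample_id", na_rep="NA")
    with open(variants_path, "w") as fh:
        for line in _header_comment(seed, cfg_hash):
            fh.write(line + "\n")
        g.variants.to_csv(fh, sep="\t", index=False)


def read_dosage_tsv(calls_path, variants_path) -> GenotypeMatrix:
    """Read the dosage TSV pair back into a genotype matrix."""
    df = pd.read_csv(calls_path, sep="\t", comment="#", index_col="sample_id")
    variants = pd.read_csv(
        variants_path, sep="\t", comment="#", dtype={"chrom": str}
    )
    bad = ~df.isin([0, 1, 2]) & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"invalid dosage value {df.iat[i, j]!r} for sample {df.index[i]!r}, "
            f"variant {df.columns[j]!r}"
        )
    calls = df.fillna(MISSING).to_numpy(dtype=np.int8)
    if list(df.columns) != list(variants["id"].astype(str)):
        raise ValueError("dosage columns do not match the variant table ids")
    return GenotypeMatrix(calls, [str(s) for s in df.index], variants)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def write_phenotypes(pheno: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Phenotype/covariate TSV with unit-documenting header comments."""
    with open(path, "w") as fh:
        fh.write("# phenotype table: al_ugL = plasma aluminum (ug/L), ")
        fh.write("creatinine_mgdl = serum creatinine (mg/dL), age in years,\n")
        fh.write("# sex in {M,F}, smoke/drink as 0/1 flags; derived columns ")
        fh.write("ln_al (natural log) and egfr (MDRD, mL/min/1.73m2) if present\n")
        for line in _header_comment(seed, cfg_hash):
            fh.write(line + "\n")
        pheno.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype TSV.

    Requires the canonical columns; non-positive aluminum or creatinine are
    row-level validation errors, not silent NaNs.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "sex": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    for col in ("al_ugL", "creatinine_mgdl", "age"):
        vals = pd.to_numeric(df[col], errors="raise")
        bad = vals.le(0) | vals.isna()
        if bad.any():
            row = df.loc[bad, "sample_id"].iloc[0]
            raise ValueError(f"non-positive or missing {col} for sample {row!r}")
    bad_sex = ~df["sex"].str.upper().isin(["M", "F"])
    if bad_sex.any():
        row = df.loc[bad_sex, "sample_id"].iloc[0]
        raise ValueError(f"sex must be 'M' or 'F'; offending sample {row!r}")
    return df


# ---------------------------------------------------------------------------
# reports / tables
# ---------------------------------------------------------------------------


def write_json(obj, path, seed=None, cfg_hash=None) -> None:
    payload = dict(obj)
    if seed is not None:
        payload.setdefault("seed", seed)
    if cfg_hash is not None:
        payload.setdefault("config_hash", cfg_hash)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Generic TSV writer with the seed/config-hash header stamp."""
    with open(path, "w") as fh:
        for line in _header_comment(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
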