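"""Genome scan of ln(plasma Al) on the QC'd cohort.

Additive-model OLS per SNP adjusted for sex, age, smoking and drinking, with
the family-wise (Bonferroni) and suggestive thresholds, QQ construction and
the genomic-inflation factor.  Writes association/QQ/Manhattan tables under
results/scan/.
"""

from pathlib import Path

from almediation import (
    ScanConfig,
    additive_code,
    genome_scan,
    genomic_lambda,
    manhattan_table,
    qq_table,
)
from almediation.io import read_phenotypes, read_vcf, write_table
from almediation.phenotype import derive_phenotypes

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    genotypes = read_vcf(ROOT / "qc" / "filtered.vcf")
    pheno = derive_phenotypes(read_phenotypes(ROOT / "cohort" / "phenotypes.tsv"))
    coded, coding = additive_code(genotypes)
    records = genome_scan(coded, pheno, ScanConfig(model="adjusted"))

    out = ROOT / "scan"
    out.mkdir(parents=True, exist_ok=True)
    write_table(records, out / "association.tsv")
    write_table(coding, out / "allele_coding.tsv")
    qq, n_skipped = qq_table(records["P"])
    write_table(qq, out / "qq.tsv")
    write_table(manhattan_table(records), out / "manhattan.tsv")

    lam = genomic_lambda(records["P"])
    print(
        f"scanned {len(records)} variants; Bonferroni threshold "
        f"{records.attrs['bonferroni_threshold']:.3g} "
        f"(displayed {records.attrs['bonferroni_display']}), "
        f"suggestive {records.attrs['suggestive_p']:.0e}"
    )
    print(f"genomic inflation lambda = {lam:.3f} ({n_skipped} unestimable records)")
    hits = records[records["TIER"] != "none"].sort_values("P")
    print(f"{len(hits)} variants at suggestive level or beyond:")
    for _, row in hits.head(10).iterrows():
        print(
            f"  {row['SNP']} chr{row['CHR']}:{row['BP']} beta={row['BETA']:+.3f} "
            f"p={row['P']:.2e} [{row['TIER']}]"
        )
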