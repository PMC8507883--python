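"""Mediation of the top LD-block: SNP -> ln(Al) -> eGFR.

Takes the scan's top suggestive hits (the planted LD block), fits the three
mediation models per SNP and bootstraps percentile CIs for the indirect
effect with 3000 replications.  Writes the mediation table under
results/mediation/.
"""

from pathlib import Path

import pandas as pd

from almediation import additive_code, mediate_snps, mediation_table
from almediation.io import read_phenotypes, read_vcf, read_table, write_table
from almediation.phenotype import derive_phenotypes

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260928

if __name__ == "__main__":
    genotypes = read_vcf(ROOT / "qc" / "filtered.vcf")
    pheno = derive_phenotypes(read_phenotypes(ROOT / "cohort" / "phenotypes.tsv"))
    records = read_table(ROOT / "scan" / "association.tsv")
    hits = records[records["TIER"] != "none"].sort_values("P")["SNP"].head(3).tolist()
    if not hits:
        raise SystemExit("no suggestive hits to mediate; run 03 first")

    coded, _ = additive_code(genotypes)
    results = mediate_snps(coded, pheno, hits, n_boot=3000, seed=SEED)
    table = mediation_table(results)
    out = ROOT / "mediation"
    out.mkdir(parents=True, exist_ok=True)
    write_table(table, out / "mediation.tsv", seed=SEED)

    pd.set_option("display.width", 160)
    for _, row in table.iterrows():
        print(
            f"{row['snp']}: a-path {row['a1']:+.3f} "
            f"[{row['a1_ci_lo']:+.3f}, {row['a1_ci_hi']:+.3f}], "
            f"b-path {row['rm']:+.3f} [{row['rm_ci_lo']:+.3f}, {row['rm_ci_hi']:+.3f}]"
        )
        print(
            f"  indirect {row['indirect']:+.3f} "
            f"[{row['ind_ci_lo']:+.3f}, {row['ind_ci_hi']:+.3f}], "
            f"direct {row['direct']:+.3f} "
            f"[{row['dir_ci_lo']:+.3f}, {row['dir_ci_hi']:+.3f}]  ({row['baron_code']})"
        )
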