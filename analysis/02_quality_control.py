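"""Quality-control the simulated cohort and audit against the planted truth.

Runs the staged QC chain (sample call rate -> heterozygosity -> variant call
rate -> HWE exact test -> IBD) on results/cohort/genotypes.vcf and reports
how each planted violation was caught.  Writes the filtered VCF and the QC
report JSON under results/qc/.
"""

import json
from pathlib import Path

from almediation import run_qc
from almediation.io import read_vcf, write_json, write_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    genotypes = read_vcf(ROOT / "cohort" / "genotypes.vcf")
    truth = json.loads((ROOT / "cohort" / "planted_truth.json").read_text())
    filtered, report = run_qc(genotypes)
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    write_json(report.to_dict(), out / "qc_report.json")
    write_vcf(filtered, out / "filtered.vcf")

    print(
        f"retained {report.n_retained_samples}/{report.n_input_samples} samples, "
        f"{report.n_retained_variants}/{report.n_input_variants} variants; "
        f"genotyping rate {report.total_genotyping_rate:.4%}"
    )
    for rule, ids in report.excluded_samples_by_rule.items():
        print(f"  samples excluded by {rule}: {len(ids)}")
    for rule, ids in report.excluded_variants_by_rule.items():
        print(f"  variants excluded by {rule}: {len(ids)}")
    het = set(report.excluded_samples_by_rule["heterozygosity"])
    print(
        "planted contamination caught:",
        f"{len(het & set(truth['contaminated_samples']))}/{len(truth['contaminated_samples'])}",
    )
    hwe = set(report.excluded_variants_by_rule["hwe"])
    print(
        "planted HWE violators caught:",
        f"{len(hwe & set(truth['hwe_violating_variants']))}/{len(truth['hwe_violating_variants'])}",
    )
    assert report.counts_conserve(), "QC accounting must conserve counts"
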