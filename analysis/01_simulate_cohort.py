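"""Generate the working synthetic cohort.

A biobank-style cohort of 1000 adults and 6000 SNPs: one causal variant in a
three-SNP LD block raising plasma aluminum (a-path 0.3 ln-units per minor
allele) which in turn raises eGFR in this healthy range (b-path 5 units per
ln-unit), plus planted QC violations so the downstream stages have real work
to do.  Writes VCF, phenotype TSV and the planted-truth JSON under
results/cohort/.
"""

from pathlib import Path

from almediation import SimulationConfig, simulate_cohort
from almediation.io import config_hash, write_json, write_phenotypes, write_vcf

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

# marker count sized so method-of-moments IBD noise stays well below the
# 0.1875 relatedness threshold across ~500k sample pairs even with the
# dense block LD (see docs/methods.md)
config = SimulationConfig(
    n_samples=1000,
    n_snps=6000,
    maf=(0.05, 0.5),
    ld_copy_prob=0.85,
    block_size=3,
    causal_snp_index=3000,  # opens an LD block: SNPs 3000-3002 travel together
    a_path=0.3,
    b_path=5.0,
    direct_path=0.0,
    missing_rate=0.002,
    n_contaminated=4,
    n_duplicate_pairs=1,
    n_hwe_violating_snps=6,
    n_low_call_rate_variants=60,
    seed=SEED,
)

if __name__ == "__main__":
    cohort = simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    write_vcf(cohort.genotypes, OUT / "genotypes.vcf", seed=SEED, cfg_hash=chash)
    write_phenotypes(cohort.phenotypes, OUT / "phenotypes.tsv", seed=SEED, cfg_hash=chash)
    write_json(cohort.truth, OUT / "planted_truth.json", seed=SEED, cfg_hash=chash)
    ph = cohort.phenotypes
    print(
        f"cohort: {cohort.genotypes.n_samples} samples x "
        f"{cohort.genotypes.n_variants} variants -> {OUT}"
    )
    print(
        f"marginals: Al {ph['al_ugL'].mean():.2f} ug/L, eGFR {ph['egfr'].mean():.1f}, "
        f"{(ph['sex'] == 'M').mean():.1%} male, {ph['smoke'].mean():.1%} smokers"
    )
    print(f"causal SNP: {cohort.truth['causal_snp']} (a={config.a_path}, b={config.b_path})")
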