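"""Seeded synthetic cohort generator.

Emulates the statistical structure of a population-biobank aluminum study:
Hardy-Weinberg genotypes with optional copy-based LD blocks, covariate
marginals matching the study population (age uniform 30-70, ~55.7% male,
34.2% ever-smokers, 7.9% current drinkers), a lognormal plasma-aluminum
mediator with mean ~1.13 μg/L, an eGFR outcome with mean ~99.5 and SD ~22
whose serum creatinine is back-computed through the inverse MDRD equation,
and planted QC violations (missingness, contamination, relatedness,
HWE-violating variants) with a machine-readable truth record.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phenotype import creatinine_from_egfr
from .types import MISSING, ConfigurationError, GenotypeMatrix

_AUTOSOMES = [str(c) for c in range(1, 23)]
_BASES = np.array(list("ACGT"))

#: inbreeding coefficient used for planted HWE-violating variants
#: (strong homozygote excess, detectable by the exact test at modest n)
HWE_VIOLATION_F = 0.8
#: forced minor-allele frequency of planted HWE-violating variants
HWE_VIOLATION_MAF = 0.3
#: heterozygote probability of contaminated samples
CONTAMINATION_HET_PROB = 0.8


@dataclass
class CovariateEffects:
    """Covariate coefficients in the mediator and outcome models.

    The study reports no covariate effect sizes; these defaults are modest,
    epidemiologically plausible values (age centred at 50 years).  Units:
    ln(μg/L) per unit for the mediator, mL/min/1.73 m^2 per unit for eGFR.
    """

    male_on_lnal: float = 0.10
    age_on_lnal: float = 0.003
    smoke_on_lnal: float = 0.08
    drink_on_lnal: float = 0.05
    male_on_egfr: float = 0.0
    age_on_egfr: float = -0.45
    smoke_on_egfr: float = -1.0
    drink_on_egfr: float = 0.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_samples: int = 500
    n_snps: int = 2000
    #: scalar MAF or (low, high) sampling range, each in (0, 0.5]
    maf: float | tuple[float, float] = (0.05, 0.5)
    ld_copy_prob: float = 0.0
    block_size: int = 1
    causal_snp_index: int | None = None
    a_path: float = 0.3
    b_path: float = 5.0
    direct_path: float = 0.0
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    sigma_m: float = 0.62
    sigma_y: float = 20.0
    missing_rate: float = 0.002
    n_contaminated: int = 0
    n_duplicate_pairs: int = 0
    n_first_degree_pairs: int = 0
    n_hwe_violating_snps: int = 0
    n_low_call_rate_variants: int = 0
    low_call_rate: float = 0.80
    #: population marginals (study Table-1-like defaults)
    prop_male: float = 0.557
    prop_smoke: float = 0.342
    prop_drink: float = 0.079
    age_range: tuple[float, float] = (30.0, 70.0)
    target_mean_al: float = 1.13
    target_mean_egfr: float = 99.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.maf_range()
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf must lie in (0, 0.5], got {self.maf}")
        if not 0 <= self.ld_copy_prob < 1:
            raise ConfigurationError("ld_copy_prob must be in [0, 1)")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        for name in ("missing_rate", "prop_male", "prop_smoke", "prop_drink"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.low_call_rate < 1:
            raise ConfigurationError("low_call_rate must be in [0, 1)")
        if self.sigma_m <= 0 or self.sigma_y <= 0:
            raise ConfigurationError("sigma_m and sigma_y must be positive")
        if self.causal_snp_index is not None and not (
            0 <= self.causal_snp_index < self.n_snps
        ):
            raise ConfigurationError(
                f"causal_snp_index {self.causal_snp_index} out of range [0, {self.n_snps})"
            )
        planted = (
            self.n_contaminated
            + 2 * self.n_duplicate_pairs
            + 2 * self.n_first_degree_pairs
        )
        if planted > self.n_samples:
            raise ConfigurationError(
                f"{planted} samples carry planted violations but only "
                f"{self.n_samples} samples exist"
            )
        if self.n_hwe_violating_snps + self.n_low_call_rate_variants > self.n_snps:
            raise ConfigurationError("more planted variant violations than variants")

    def maf_range(self) -> tuple[float, float]:
        if isinstance(self.maf, (int, float)):
            return float(self.maf), float(self.maf)
        lo, hi = self.maf
        return float(lo), float(hi)

    def hwe_violating_indices(self) -> np.ndarray:
        """Planted HWE violators occupy the tail variant positions."""
        return np.arange(self.n_snps - self.n_hwe_violating_snps, self.n_snps)

    def low_call_rate_indices(self) -> np.ndarray:
        """Planted low-call-rate variants precede the HWE violators."""
        stop = self.n_snps - self.n_hwe_violating_snps
        return np.arange(stop - self.n_low_call_rate_variants, stop)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per generation stage."""
    key = zlib.crc32(stream.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def _variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_snps
    n_chrom = min(len(_AUTOSOMES), m)
    chrom_idx = np.minimum((np.arange(m) * n_chrom) // m, n_chrom - 1)
    pos = np.empty(m, dtype=np.int64)
    for c in range(n_chrom):
        mask = chrom_idx == c
        pos[mask] = (np.arange(mask.sum()) + 1) * 5000
    ref = rng.choice(4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    return pd.DataFrame(
        {
            "chrom": [_AUTOSOMES[c] for c in chrom_idx],
            "pos": pos,
            "id": [f"snp{j + 1:06d}" for j in range(m)],
            "allele1": _BASES[ref],
            "allele2": _BASES[alt],
        }
    )


def generate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes with optional copy-based LD blocks.

    Each variant's calls count the ``allele2`` allele whose frequency is the
    configured MAF; within an LD block each sample copies the previous
    variant's genotype with probability ``ld_copy_prob``.  Planted
    HWE-violating variants (tail positions, see
    :meth:`SimulationConfig.hwe_violating_indices`) are drawn with a strong
    homozygote excess (inbreeding coefficient 0.8) instead.
    """
    config.validate()
    rng = _rng(config, "genotypes")
    n, m = config.n_samples, config.n_snps
    lo, hi = config.maf_range()
    q = rng.uniform(lo, hi, size=m) if lo < hi else np.full(m, lo)
    if config.block_size > 1 and config.ld_copy_prob > 0:
        # every SNP in an LD block shares the block's allele frequency;
        # otherwise the copy process mixes genotypes drawn at different
        # frequencies, which is a Wahlund-style HWE violation in itself
        starts = (np.arange(m) // config.block_size) * config.block_size
        q = q[starts]
    hwe_bad = config.hwe_violating_indices()
    q[hwe_bad] = HWE_VIOLATION_MAF

    calls = np.empty((n, m), dtype=np.int8)
    hwe_bad_set = set(hwe_bad.tolist())
    for j in range(m):
        if j in hwe_bad_set:
            qq = q[j]
            f = HWE_VIOLATION_F
            probs = [
                (1 - qq) ** 2 + f * qq * (1 - qq),
                2 * qq * (1 - qq) * (1 - f),
                qq**2 + f * qq * (1 - qq),
            ]
            calls[:, j] = rng.choice(3, size=n, p=probs)
        else:
            calls[:, j] = rng.binomial(2, q[j], size=n)
        in_block = config.block_size > 1 and (j % config.block_size) != 0
        if in_block and config.ld_copy_prob > 0 and j not in hwe_bad_set:
            copy = rng.random(n) < config.ld_copy_prob
            calls[copy, j] = calls[copy, j - 1]

    variants = _variant_table(config, rng)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(calls, sample_ids, variants)


def generate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Sample demographics: age uniform on [30, 70], Bernoulli sex/smoke/drink."""
    config.validate()
    rng = _rng(config, "covariates")
    n = config.n_samples
    lo, hi = config.age_range
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n)],
            "age": rng.uniform(lo, hi, size=n),
            "sex": np.where(rng.random(n) < config.prop_male, "M", "F"),
            "smoke": (rng.random(n) < config.prop_smoke).astype(int),
            "drink": (rng.random(n) < config.prop_drink).astype(int),
        }
    )


def _covariate_terms(cov: pd.DataFrame, eff: CovariateEffects):
    male = (cov["sex"].to_numpy() == "M").astype(float)
    age_c = cov["age"].to_numpy() - 50.0
    smoke = cov["smoke"].to_numpy().astype(float)
    drink = cov["drink"].to_numpy().astype(float)
    on_m = (
        eff.male_on_lnal * male
        + eff.age_on_lnal * age_c
        + eff.smoke_on_lnal * smoke
        + eff.drink_on_lnal * drink
    )
    on_y = (
        eff.male_on_egfr * male
        + eff.age_on_egfr * age_c
        + eff.smoke_on_egfr * smoke
        + eff.drink_on_egfr * drink
    )
    return on_m, on_y


def generate_phenotypes(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate plasma Al and eGFR from the structural mediation model.

    ln(Al) = a0 + a_path*G + covariates + N(0, sigma_m);
    eGFR  = r0 + b_path*ln(Al) + direct_path*G + covariates + N(0, sigma_y),
    redrawn while non-positive.  Intercepts are solved analytically so that
    the cohort means hit the configured targets (Al ~1.13 μg/L as the mean of
    a lognormal, eGFR ~99.5).  Serum creatinine is back-computed by inverting
    the MDRD equation so the pipeline can re-derive eGFR from raw columns.
    """
    config.validate()
    rng = _rng(config, "phenotypes")
    n = config.n_samples
    if genotypes.n_samples != n or len(covariates) != n:
        raise ConfigurationError("genotype/covariate dimensions disagree with config")

    if config.causal_snp_index is not None:
        gvec = genotypes.calls[:, config.causal_snp_index].astype(float)
        if np.any(gvec == MISSING):
            raise ConfigurationError("causal SNP must be fully observed")
    else:
        gvec = np.zeros(n)

    eff_m, eff_y = _covariate_terms(covariates, config.covariate_effects)

    # solve the intercept so E[Al] = E[exp(a0 + lp + noise)] hits the target:
    # a0 = ln(target) - sigma^2/2 - ln(mean(exp(lp))), which absorbs the
    # Jensen inflation from genotype/covariate variance on the log scale
    lp = config.a_path * gvec + eff_m
    a0 = (
        math.log(config.target_mean_al)
        - config.sigma_m**2 / 2.0
        - math.log(float(np.mean(np.exp(lp))))
    )
    ln_al = a0 + lp + rng.normal(0.0, config.sigma_m, n)
    al = np.exp(ln_al)

    r0 = (
        config.target_mean_egfr
        - config.b_path * ln_al.mean()
        - config.direct_path * gvec.mean()
        - eff_y.mean()
    )
    loc = r0 + config.b_path * ln_al + config.direct_path * gvec + eff_y
    egfr = loc + rng.normal(0.0, config.sigma_y, n)
    # truncate at > 0 by redraw (no point mass at zero)
    bad = egfr <= 0
    while bad.any():
        egfr[bad] = loc[bad] + rng.normal(0.0, config.sigma_y, int(bad.sum()))
        bad = egfr <= 0

    female = covariates["sex"].to_numpy() == "F"
    creat = creatinine_from_egfr(egfr, covariates["age"].to_numpy(), female)

    pheno = covariates.copy()
    pheno["al_ugL"] = al
    pheno["ln_al"] = ln_al
    pheno["creatinine_mgdl"] = creat
    pheno["egfr"] = egfr
    return pheno[
        [
            "sample_id",
            "al_ugL",
            "creatinine_mgdl",
            "age",
            "sex",
            "smoke",
            "drink",
            "ln_al",
            "egfr",
        ]
    ]


def inject_qc_violations(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[GenotypeMatrix, dict]:
    """Plant missingness, contamination and relatedness; return planted truth.

    Contaminated samples are redrawn with heterozygote probability 0.8
    (mimicking DNA mixture); duplicate pairs copy a sample's genotypes;
    first-degree pairs share exactly one transmitted allele per variant.
    Planted low-call-rate variants get an exact ``1 - low_call_rate`` fraction
    of calls set missing; global missingness is Bernoulli per call.  The truth
    record lists every planted violation for validator tests.
    """
    config.validate()
    rng = _rng(config, "violations")
    g = genotypes.copy()
    n, m = g.n_samples, g.n_variants
    ids = np.asarray(g.sample_ids)

    n_special = (
        config.n_contaminated
        + 2 * config.n_duplicate_pairs
        + 2 * config.n_first_degree_pairs
    )
    special = rng.choice(n, size=n_special, replace=False) if n_special else np.array([], int)
    k = config.n_contaminated
    contaminated = special[:k]
    dup_pairs = special[k : k + 2 * config.n_duplicate_pairs].reshape(-1, 2)
    fd_pairs = special[
        k + 2 * config.n_duplicate_pairs : k
        + 2 * config.n_duplicate_pairs
        + 2 * config.n_first_degree_pairs
    ].reshape(-1, 2)

    nonmissing = g.calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            nonmissing.sum(axis=0) > 0,
            np.where(nonmissing, g.calls, 0).sum(axis=0)
            / np.maximum(2 * nonmissing.sum(axis=0), 1),
            0.0,
        )

    # contamination: excess heterozygosity, homozygotes split by allele freq
    for i in contaminated:
        u = rng.random(m)
        het = u < CONTAMINATION_HET_PROB
        hom_alt = (~het) & (rng.random(m) < freq)
        g.calls[i] = np.where(het, 1, np.where(hom_alt, 2, 0)).astype(np.int8)

    # duplicates: exact genotype copy
    for src, dst in dup_pairs:
        g.calls[dst] = g.calls[src]

    # first degree: one allele transmitted from the parent, one from the population
    for src, dst in fd_pairs:
        transmitted = (rng.random(m) < g.calls[src] / 2.0).astype(np.int8)
        other = (rng.random(m) < freq).astype(np.int8)
        g.calls[dst] = transmitted + other

    # planted low-call-rate variants: exact missing count for guaranteed recovery
    lcr = config.low_call_rate_indices()
    n_miss = int(math.ceil((1.0 - config.low_call_rate) * n))
    for j in lcr:
        rows = rng.choice(n, size=n_miss, replace=False)
        g.calls[rows, j] = MISSING

    # global per-call missingness
    if config.missing_rate > 0:
        drop = rng.random((n, m)) < config.missing_rate
        g.calls[drop] = MISSING

    truth = {
        "contaminated_samples": ids[contaminated].tolist(),
        "duplicate_pairs": [[ids[a], ids[b]] for a, b in dup_pairs],
        "first_degree_pairs": [[ids[a], ids[b]] for a, b in fd_pairs],
        "low_call_rate_variants": g.variants.loc[lcr, "id"].tolist(),
        "hwe_violating_variants": g.variants.loc[
            config.hwe_violating_indices(), "id"
        ].tolist(),
        "causal_snp": (
            None
            if config.causal_snp_index is None
            else g.variants.loc[config.causal_snp_index, "id"]
        ),
        "a_path": config.a_path,
        "b_path": config.b_path,
        "direct_path": config.direct_path,
        "seed": config.seed,
    }
    return g, truth


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full generation pass: genotypes -> covariates -> phenotypes -> violations."""
    config.validate()
    clean = generate_genotypes(config)
    covariates = generate_covariates(config)
    phenotypes = generate_phenotypes(clean, covariates, config)
    genotypes, truth = inject_qc_violations(clean, config)
    return SimulatedCohort(genotypes, phenotypes, truth, config)
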