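"""Genotype quality control: call rates, heterozygosity, HWE, relatedness.

The chain mirrors the standard PLINK-style flow: sample call rate ->
heterozygosity outliers -> variant call rate -> Hardy-Weinberg exact test ->
identity-by-descent (IBD) relatedness, each stage applied to the survivors of
the previous one, with an auditable per-rule report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .types import (
    MISSING,
    DegenerateInputError,
    GenotypeMatrix,
)

# ---------------------------------------------------------------------------
# thresholds / report containers
# ---------------------------------------------------------------------------


@dataclass
class QCThresholds:
    """Exclusion thresholds for each QC rule.

    Defaults: samples and variants dropped above 5% missingness, samples more
    than 3 SD from the mean heterozygosity rate, variants with HWE exact
    p < 1e-6, and one member of every pair with PI_HAT > 0.1875 (closer than
    second-degree relatives).
    """

    max_sample_missing: float = 0.05
    max_variant_missing: float = 0.05
    het_sd_bound: float = 3.0
    hwe_alpha: float = 1e-6
    ibd_max: float = 0.1875
    #: prune variants in strong LD before estimating IBD (off by default;
    #: recommended when the marker panel carries dense LD, since correlated
    #: markers inflate the variance of the method-of-moments estimator)
    ibd_ld_prune: bool = False
    ibd_ld_r2_max: float = 0.2
    ibd_ld_window: int = 50
    #: chromosomes excluded from heterozygosity and HWE computation
    exclude_chroms: tuple[str, ...] = ("Y",)

    def validate(self) -> None:
        for name in ("max_sample_missing", "max_variant_missing"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.het_sd_bound <= 0:
            raise ValueError("het_sd_bound must be positive")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in (0, 1)")
        if not 0 <= self.ibd_max <= 1:
            raise ValueError("ibd_max must be in [0, 1]")


@dataclass
class QCReport:
    """Per-rule exclusions and retained dimensions for one QC run."""

    excluded_samples_by_rule: dict[str, list[str]] = field(default_factory=dict)
    excluded_variants_by_rule: dict[str, list[str]] = field(default_factory=dict)
    n_input_samples: int = 0
    n_input_variants: int = 0
    n_retained_samples: int = 0
    n_retained_variants: int = 0
    total_genotyping_rate: float = float("nan")
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_excluded_samples(self) -> int:
        return sum(len(v) for v in self.excluded_samples_by_rule.values())

    @property
    def n_excluded_variants(self) -> int:
        return sum(len(v) for v in self.excluded_variants_by_rule.values())

    def counts_conserve(self) -> bool:
        """Input dims == retained + per-rule exclusions, no double counting."""
        sample_ids = [s for v in self.excluded_samples_by_rule.values() for s in v]
        variant_ids = [s for v in self.excluded_variants_by_rule.values() for s in v]
        return (
            len(sample_ids) == len(set(sample_ids))
            and len(variant_ids) == len(set(variant_ids))
            and self.n_input_samples == self.n_retained_samples + len(sample_ids)
            and self.n_input_variants == self.n_retained_variants + len(variant_ids)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


# ---------------------------------------------------------------------------
# per-rule statistics
# ---------------------------------------------------------------------------


def sample_call_rates(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample."""
    if g.n_variants == 0:
        raise DegenerateInputError("cannot compute sample call rates with 0 variants")
    return 1.0 - g.missing_mask().mean(axis=1)


def variant_call_rates(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per variant."""
    if g.n_samples == 0:
        raise DegenerateInputError("cannot compute variant call rates with 0 samples")
    return 1.0 - g.missing_mask().mean(axis=0)


def sample_heterozygosity(g: GenotypeMatrix, variant_mask=None) -> pd.DataFrame:
    """Per-sample heterozygosity statistics.

    het_rate = (N - O) / N with N the non-missing and O the homozygous call
    count; samples with N = 0 get NaN (unevaluable).
    """
    calls = g.calls if variant_mask is None else g.calls[:, variant_mask]
    nonmissing = calls != MISSING
    n = nonmissing.sum(axis=1)
    n_hom = ((calls == 0) | (calls == 2)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n > 0, (n - n_hom) / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "n_nonmissing": n,
            "n_homozygous": n_hom,
            "het_rate": het,
            "call_rate": nonmissing.mean(axis=1),
        }
    )


def heterozygosity_outliers(
    g: GenotypeMatrix, bound: float = 3.0, variant_mask=None
) -> tuple[list[str], pd.DataFrame]:
    """Samples whose het rate lies more than ``bound`` SDs from the mean.

    Unevaluable samples (all calls missing) are flagged as outliers rather
    than silently kept.  With zero SD across samples nothing is excluded.
    """
    if g.n_samples < 3:
        raise DegenerateInputError("heterozygosity outlier detection needs >= 3 samples")
    stats = sample_heterozygosity(g, variant_mask=variant_mask)
    het = stats["het_rate"].to_numpy()
    evaluable = ~np.isnan(het)
    excluded = [sid for sid, ok in zip(g.sample_ids, evaluable) if not ok]
    if evaluable.sum() >= 2 and np.isfinite(bound):
        mean = het[evaluable].mean()
        sd = het[evaluable].std(ddof=1)
        if sd > 0:
            out = evaluable & (np.abs(het - mean) > bound * sd)
            excluded += [sid for sid, o in zip(g.sample_ids, out) if o]
    return excluded, stats


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic variant.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one
    (the classic two-sided exact test; no mid-p correction).  Monomorphic
    variants return 1.0.
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n_hom1, n_het, n_hom2 = (int(c) for c in counts)
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype call required")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0
    # all attainable heterozygote counts share the parity of the rare-allele count
    h = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    hom_rare = (rare - h) // 2
    hom_common = n - h - hom_rare
    # log P(h) up to a constant: multinomial coefficient times 2^h
    logp = (
        h * math.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(h + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(h, n_het)]
    # tolerance guards against float noise in the <= comparison
    total = np.exp(logp[logp <= p_obs + 1e-12]).sum()
    return float(min(1.0, total))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """HWE exact p per variant, from the non-missing genotype counts."""
    out = np.empty(g.n_variants)
    for j in range(g.n_variants):
        col = g.calls[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        out[j] = 1.0 if n0 + n1 + n2 == 0 else hwe_exact_p(n0, n1, n2)
    return out


# ---------------------------------------------------------------------------
# identity by descent
# ---------------------------------------------------------------------------

#: below this many informative variants, IBD estimates are flagged unstable
MIN_INFORMATIVE_IBD = 50


def ld_prune_indices(
    g: GenotypeMatrix, r2_max: float = 0.2, window: int = 50
) -> np.ndarray:
    """Greedy window-based LD pruning: indices of an approximately
    independent variant subset.

    Walks variants in order per chromosome and keeps a variant only if its
    squared genotype correlation with every kept variant inside the trailing
    window stays at or below ``r2_max``.  Missing calls are mean-imputed for
    the correlation only.
    """
    calls = g.calls.astype(np.float64)
    miss = calls < 0
    with np.errstate(invalid="ignore"):
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, calls).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
    calls = np.where(miss, col_mean, calls)
    sd = calls.std(axis=0)
    chroms = g.variants["chrom"].astype(str).to_numpy()
    kept: list[int] = []
    kept_in_chrom: list[int] = []
    last_chrom = None
    for j in range(g.n_variants):
        if chroms[j] != last_chrom:
            kept_in_chrom = []
            last_chrom = chroms[j]
        if sd[j] == 0:
            continue
        ok = True
        for k in kept_in_chrom[-window:]:
            r = np.corrcoef(calls[:, j], calls[:, k])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
            kept_in_chrom.append(j)
    return np.asarray(kept, dtype=int)


def ibd_pi_hat(g: GenotypeMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Method-of-moments PI_HAT for every sample pair.

    Estimates P(IBD=0/1/2) from genome-wide identity-by-state (IBS) counts and
    in-sample allele frequencies, bounds the probabilities into [0, 1] and
    renormalises; PI_HAT = P(IBD=2) + P(IBD=1)/2.  Expected IBS counts for a
    pair with missing data are scaled by the pair's fraction of valid calls.
    Returns the pair table and any warnings.
    """
    if g.n_samples < 2:
        raise DegenerateInputError("IBD needs at least two samples")
    warnings: list[str] = []
    calls = g.calls
    valid = calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            valid.sum(axis=0) > 0,
            np.where(calls == MISSING, 0, calls).sum(axis=0)
            / np.maximum(2 * valid.sum(axis=0), 1),
            np.nan,
        )
    informative = np.isfinite(freq) & (freq > 0) & (freq < 1)
    m = int(informative.sum())
    if m < MIN_INFORMATIVE_IBD:
        warnings.append(
            f"only {m} informative variants for IBD; estimates are unstable"
        )
    if m == 0:
        raise DegenerateInputError("no informative (polymorphic) variants for IBD")
    sub = calls[:, informative]
    v = valid[:, informative].astype(np.float32)
    h0 = (sub == 0).astype(np.float32)
    h1 = (sub == 1).astype(np.float32)
    h2 = (sub == 2).astype(np.float32)
    n_ibs2 = h0 @ h0.T + h1 @ h1.T + h2 @ h2.T
    n_ibs0 = h0 @ h2.T + h2 @ h0.T
    n_valid = v @ v.T
    n_ibs1 = n_valid - n_ibs0 - n_ibs2

    p = freq[informative]
    q = 1.0 - p
    s0_ibd0 = float((2 * p**2 * q**2).sum())
    s1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    s2_ibd0 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    s1_ibd1 = float((2 * p**2 * q + 2 * p * q**2).sum())
    s2_ibd1 = float((p**3 + q**3 + p**2 * q + p * q**2).sum())

    iu, ju = np.triu_indices(g.n_samples, k=1)
    f = n_valid[iu, ju] / m
    ok = f > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(ok, n_ibs0[iu, ju] / (s0_ibd0 * np.maximum(f, 1e-300)), np.nan)
        p1 = np.where(
            ok,
            (n_ibs1[iu, ju] - p0 * s1_ibd0 * f) / (s1_ibd1 * np.maximum(f, 1e-300)),
            np.nan,
        )
        p2 = np.where(
            ok,
            (n_ibs2[iu, ju] - p0 * s2_ibd0 * f - p1 * s2_ibd1 * f)
            / (m * np.maximum(f, 1e-300)),
            np.nan,
        )
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    total = p0 + p1 + p2
    with np.errstate(invalid="ignore"):
        p0, p1, p2 = p0 / total, p1 / total, p2 / total
    pi_hat = p2 + 0.5 * p1
    ids = np.asarray(g.sample_ids)
    pairs = pd.DataFrame(
        {
            "sample_i": ids[iu],
            "sample_j": ids[ju],
            "n_valid": n_valid[iu, ju].astype(int),
            "p_ibd0": p0,
            "p_ibd1": p1,
            "p_ibd2": p2,
            "pi_hat": pi_hat,
        }
    )
    return pairs, warnings


# ---------------------------------------------------------------------------
# the staged pipeline
# ---------------------------------------------------------------------------


def run_qc(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full QC chain and return the filtered matrix plus report.

    Stage order: sample call rate -> heterozygosity outliers -> variant call
    rate -> HWE exact test -> IBD (drop one member of each related pair, the
    one with the lower call rate, ties resolved by dropping the higher sample
    index).  Heterozygosity statistics are computed over samples that passed
    the call-rate filter; heterozygosity and HWE skip excluded chromosomes
    (Y by default).
    """
    t = thresholds or QCThresholds()
    t.validate()
    report = QCReport(
        n_input_samples=g.n_samples, n_input_variants=g.n_variants, thresholds=t
    )
    current = g

    def _check_nonempty(stage: str) -> None:
        if current.n_samples == 0 or current.n_variants == 0:
            raise DegenerateInputError(
                f"QC stage '{stage}' removed everything; nothing left to filter"
            )

    # 1. sample call rate
    scr = sample_call_rates(current)
    keep = (1.0 - scr) <= t.max_sample_missing
    report.excluded_samples_by_rule["sample_call_rate"] = [
        s for s, k in zip(current.sample_ids, keep) if not k
    ]
    current = current.subset(sample_idx=np.flatnonzero(keep))
    _check_nonempty("sample_call_rate")

    # 2. heterozygosity outliers (autosomes + X; Y excluded)
    chrom_ok = ~current.variants["chrom"].astype(str).isin(t.exclude_chroms)
    excl_het, _ = heterozygosity_outliers(
        current, bound=t.het_sd_bound, variant_mask=chrom_ok.to_numpy()
    )
    report.excluded_samples_by_rule["heterozygosity"] = list(excl_het)
    keep = ~np.isin(current.sample_ids, excl_het)
    current = current.subset(sample_idx=np.flatnonzero(keep))
    _check_nonempty("heterozygosity")

    # 3. variant call rate
    vcr = variant_call_rates(current)
    keep_v = (1.0 - vcr) <= t.max_variant_missing
    report.excluded_variants_by_rule["variant_call_rate"] = list(
        current.variants.loc[~keep_v, "id"]
    )
    current = current.subset(variant_idx=np.flatnonzero(keep_v))
    _check_nonempty("variant_call_rate")

    # 4. HWE exact test (excluded chromosomes are never dropped by this rule)
    pvals = hwe_pvalues(current)
    chrom_ok = ~current.variants["chrom"].astype(str).isin(t.exclude_chroms)
    keep_v = ~((pvals < t.hwe_alpha) & chrom_ok.to_numpy())
    report.excluded_variants_by_rule["hwe"] = list(current.variants.loc[~keep_v, "id"])
    current = current.subset(variant_idx=np.flatnonzero(keep_v))
    _check_nonempty("hwe")

    # 5. IBD (optionally on an LD-pruned marker subset)
    if t.ibd_ld_prune:
        kept = ld_prune_indices(current, t.ibd_ld_r2_max, t.ibd_ld_window)
        pairs, warns = ibd_pi_hat(current.subset(variant_idx=kept))
        report.warnings.append(
            f"IBD estimated on {kept.size} LD-pruned variants "
            f"(r2 <= {t.ibd_ld_r2_max}, window {t.ibd_ld_window})"
        )
    else:
        pairs, warns = ibd_pi_hat(current)
    report.warnings.extend(warns)
    flagged = pairs.loc[pairs["pi_hat"] > t.ibd_max]
    dropped: set[str] = set()
    call_rate = dict(zip(current.sample_ids, sample_call_rates(current)))
    index_of = {s: i for i, s in enumerate(current.sample_ids)}
    for _, row in flagged.sort_values(["sample_i", "sample_j"]).iterrows():
        a, b = row["sample_i"], row["sample_j"]
        if a in dropped or b in dropped:
            continue
        if call_rate[a] < call_rate[b]:
            dropped.add(a)
        elif call_rate[b] < call_rate[a]:
            dropped.add(b)
        else:
            dropped.add(a if index_of[a] > index_of[b] else b)
    report.excluded_samples_by_rule["ibd"] = sorted(dropped, key=index_of.get)
    keep = ~np.isin(current.sample_ids, list(dropped))
    current = current.subset(sample_idx=np.flatnonzero(keep))
    _check_nonempty("ibd")

    report.n_retained_samples = current.n_samples
    report.n_retained_variants = current.n_variants
    report.total_genotyping_rate = float(1.0 - current.missing_mask().mean())
    return current, report
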