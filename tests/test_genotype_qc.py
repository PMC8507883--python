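"""QC chain: call rates, heterozygosity, HWE exact test, IBD, staged filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from almediation import (
    MISSING,
    GenotypeMatrix,
    QCThresholds,
    SimulationConfig,
    heterozygosity_outliers,
    hwe_exact_p,
    ibd_pi_hat,
    run_qc,
    sample_call_rates,
    simulate_cohort,
)
from almediation.qc import sample_heterozygosity, variant_call_rates
from almediation.types import DegenerateInputError

from conftest import hwe_enumeration_oracle


def _matrix(calls, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1),
            "id": [f"v{j}" for j in range(m)],
            "allele1": ["A"] * m,
            "allele2": ["C"] * m,
        }
    )
    return GenotypeMatrix(calls, [f"s{i}" for i in range(n)], variants)


# ---------------------------------------------------------------------------
# call rates
# ---------------------------------------------------------------------------


def test_sample_call_rates_direct_cases():
    calls = np.zeros((2, 100), dtype=np.int8)
    calls[1, :10] = MISSING
    g = _matrix(calls)
    rates = sample_call_rates(g)
    assert rates[0] == 1.0
    assert rates[1] == 0.90


def test_call_rates_with_zero_variants_is_degenerate():
    g = _matrix(np.zeros((3, 1), dtype=np.int8)).subset(variant_idx=[])
    with pytest.raises(DegenerateInputError):
        sample_call_rates(g)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


def test_het_rate_is_one_minus_homozygous_fraction():
    # 100 non-missing calls, 70 homozygous -> het rate 0.30
    calls = np.concatenate([np.zeros(40), np.full(30, 2), np.ones(30)])
    g = _matrix(np.vstack([calls, calls, calls]))
    stats = sample_heterozygosity(g)
    assert np.allclose(stats["het_rate"], 0.30)
    assert (stats["n_nonmissing"] == 100).all()
    assert (stats["n_homozygous"] == 70).all()


def test_identical_het_rates_exclude_nobody():
    calls = np.tile(np.concatenate([np.ones(30), np.zeros(70)]), (5, 1))
    excluded, _ = heterozygosity_outliers(_matrix(calls))
    assert excluded == []


def test_fully_missing_sample_is_flagged_not_kept():
    rng = np.random.default_rng(0)
    calls = rng.binomial(2, 0.3, size=(6, 50)).astype(np.int8)
    calls[2] = MISSING
    excluded, _ = heterozygosity_outliers(_matrix(calls))
    assert "s2" in excluded


def test_planted_contaminated_samples_are_the_het_outliers():
    cfg = SimulationConfig(
        n_samples=150, n_snps=2000, maf=0.3, n_contaminated=3,
        missing_rate=0.0, seed=41,
    )
    c = simulate_cohort(cfg)
    excluded, _ = heterozygosity_outliers(c.genotypes)
    assert sorted(excluded) == sorted(c.truth["contaminated_samples"])


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------


def test_hwe_monomorphic_variant_has_p_one():
    assert hwe_exact_p(0, 0, 50) == 1.0
    assert hwe_exact_p(50, 0, 0) == 1.0


def test_hwe_matches_exact_enumeration_on_depleted_heterozygotes():
    # (5, 0, 5): all-homozygote split, enumeration over het counts 0..10
    assert hwe_exact_p(5, 0, 5) == pytest.approx(hwe_enumeration_oracle(5, 0, 5), abs=1e-12)


@pytest.mark.parametrize(
    "counts", [(3, 4, 3), (1, 8, 1), (7, 1, 2), (0, 5, 5), (2, 2, 2), (10, 2, 0)]
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_p(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-12
    )


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_p(-1, 2, 3)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    n0=st.integers(0, 40), n1=st.integers(0, 40), n2=st.integers(0, 40)
)
def test_hwe_p_is_a_probability(n0, n1, n2):
    if n0 + n1 + n2 == 0:
        return
    p = hwe_exact_p(n0, n1, n2)
    assert 0 < p <= 1.0


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ibd_cohort():
    cfg = SimulationConfig(
        n_samples=60, n_snps=10000, maf=0.3, missing_rate=0.0,
        n_duplicate_pairs=1, n_first_degree_pairs=1, seed=47,
    )
    return simulate_cohort(cfg)


def _pair_pi_hat(pairs, a, b):
    row = pairs[
        ((pairs["sample_i"] == a) & (pairs["sample_j"] == b))
        | ((pairs["sample_i"] == b) & (pairs["sample_j"] == a))
    ]
    return float(row["pi_hat"].iloc[0])


def test_duplicate_pair_pi_hat_near_one(ibd_cohort):
    pairs, _ = ibd_pi_hat(ibd_cohort.genotypes)
    a, b = ibd_cohort.truth["duplicate_pairs"][0]
    assert _pair_pi_hat(pairs, a, b) > 0.95


def test_first_degree_pair_shares_half_the_genome(ibd_cohort):
    pairs, _ = ibd_pi_hat(ibd_cohort.genotypes)
    a, b = ibd_cohort.truth["first_degree_pairs"][0]
    assert _pair_pi_hat(pairs, a, b) == pytest.approx(0.5, abs=0.1)


def test_unrelated_pairs_have_near_zero_pi_hat(ibd_cohort):
    pairs, _ = ibd_pi_hat(ibd_cohort.genotypes)
    related = {frozenset(p) for p in ibd_cohort.truth["duplicate_pairs"]}
    related |= {frozenset(p) for p in ibd_cohort.truth["first_degree_pairs"]}
    unrelated = pairs[
        [frozenset((i, j)) not in related for i, j in zip(pairs["sample_i"], pairs["sample_j"])]
    ]
    # any given unrelated pair sits within noise of zero; across ~1800 pairs
    # the mean is tiny and extremes stay far below the relatedness threshold
    assert abs(unrelated["pi_hat"].iloc[0]) < 0.05
    assert unrelated["pi_hat"].abs().mean() < 0.02
    assert unrelated["pi_hat"].abs().max() < 0.1875


def test_ld_pruning_returns_weakly_correlated_subset():
    cfg = SimulationConfig(
        n_samples=400, n_snps=90, ld_copy_prob=0.9, block_size=3,
        missing_rate=0.0, seed=83,
    )
    c = simulate_cohort(cfg)
    from almediation.qc import ld_prune_indices

    kept = ld_prune_indices(c.genotypes, r2_max=0.2, window=50)
    assert 0 < kept.size < 90  # dense blocks must lose members
    calls = c.genotypes.calls[:, kept].astype(float)
    same_chrom = c.genotypes.variants.loc[kept, "chrom"].to_numpy()
    corr = np.corrcoef(calls.T)
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            if same_chrom[a] == same_chrom[b]:
                assert corr[a, b] ** 2 <= 0.2 + 1e-9


def test_few_informative_variants_warns():
    rng = np.random.default_rng(1)
    g = _matrix(rng.binomial(2, 0.4, size=(10, 20)).astype(np.int8))
    _, warnings = ibd_pi_hat(g)
    assert warnings and "unstable" in warnings[0]


# ---------------------------------------------------------------------------
# the staged pipeline
# ---------------------------------------------------------------------------


def test_clean_cohort_loses_nothing_to_hard_rules():
    """Without planted violations, the deterministic rules exclude nothing.

    The heterozygosity rule is a +-3 SD trim, so a small chance level of
    exclusions is statistically inevitable even in a clean cohort.
    """
    cfg = SimulationConfig(n_samples=200, n_snps=3000, missing_rate=0.0, seed=53)
    c = simulate_cohort(cfg)
    filtered, report = run_qc(c.genotypes)
    assert report.excluded_samples_by_rule["sample_call_rate"] == []
    assert report.excluded_variants_by_rule["variant_call_rate"] == []
    assert report.excluded_variants_by_rule["hwe"] == []
    assert report.excluded_samples_by_rule["ibd"] == []
    assert len(report.excluded_samples_by_rule["heterozygosity"]) <= 3
    assert report.counts_conserve()
    assert report.total_genotyping_rate == 1.0


def test_planted_violations_recovered_exactly():
    cfg = SimulationConfig(
        n_samples=300, n_snps=4000, missing_rate=0.0, seed=5,
        n_contaminated=6, n_duplicate_pairs=2,
        n_hwe_violating_snps=10, n_low_call_rate_variants=300,
    )
    c = simulate_cohort(cfg)
    filtered, report = run_qc(c.genotypes)
    t = c.truth
    assert sorted(report.excluded_samples_by_rule["heterozygosity"]) == sorted(
        t["contaminated_samples"]
    )
    assert sorted(report.excluded_variants_by_rule["variant_call_rate"]) == sorted(
        t["low_call_rate_variants"]
    )
    assert sorted(report.excluded_variants_by_rule["hwe"]) == sorted(
        t["hwe_violating_variants"]
    )
    dropped = report.excluded_samples_by_rule["ibd"]
    pairs = [set(p) for p in t["duplicate_pairs"]]
    assert len(dropped) == len(pairs)
    assert all(any(d in p for p in pairs) for d in dropped)
    assert report.counts_conserve()


def test_report_arithmetic_mirrors_sequential_exclusion():
    """input variants = retained + sum of per-rule exclusions."""
    cfg = SimulationConfig(
        n_samples=150, n_snps=1000, missing_rate=0.0, seed=59,
        n_hwe_violating_snps=5, n_low_call_rate_variants=30,
    )
    c = simulate_cohort(cfg)
    _, report = run_qc(c.genotypes)
    assert (
        report.n_input_variants
        == report.n_retained_variants + report.n_excluded_variants
    )
    assert (
        report.n_input_samples == report.n_retained_samples + report.n_excluded_samples
    )


def test_qc_idempotent_with_het_stage_disabled():
    """Re-running QC on its own output excludes nothing further.

    The heterozygosity trim re-estimates mean/SD on its input, so idempotence
    is asserted with that stage effectively disabled (infinite SD bound).
    """
    cfg = SimulationConfig(
        n_samples=200, n_snps=3000, missing_rate=0.01, seed=61,
        n_duplicate_pairs=1, n_low_call_rate_variants=20,
    )
    c = simulate_cohort(cfg)
    t = QCThresholds(het_sd_bound=np.inf)
    once, rep1 = run_qc(c.genotypes, t)
    twice, rep2 = run_qc(once, t)
    assert rep2.n_excluded_samples == 0
    assert rep2.n_excluded_variants == 0
    assert np.array_equal(once.calls, twice.calls)


def test_y_chromosome_never_excluded_by_hwe():
    rng = np.random.default_rng(2)
    # 30 all-heterozygote variants: flagrant HWE violation
    calls = np.ones((60, 30), dtype=np.int8)
    variants = pd.DataFrame(
        {
            "chrom": ["Y"] * 15 + ["1"] * 15,
            "pos": np.arange(1, 31),
            "id": [f"v{j}" for j in range(30)],
            "allele1": ["A"] * 30,
            "allele2": ["C"] * 30,
        }
    )
    g = GenotypeMatrix(calls, [f"s{i}" for i in range(60)], variants)
    # disable het/ibd sensitivity to isolate the HWE rule
    _, report = run_qc(g, QCThresholds(het_sd_bound=np.inf, ibd_max=1.0))
    excluded = set(report.excluded_variants_by_rule["hwe"])
    assert excluded == {f"v{j}" for j in range(15, 30)}


def test_empty_result_names_the_failing_stage():
    calls = np.full((4, 10), MISSING, dtype=np.int8)
    calls[:, 0] = 1
    g = _matrix(calls)
    with pytest.raises(DegenerateInputError, match="sample_call_rate"):
        run_qc(g)
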