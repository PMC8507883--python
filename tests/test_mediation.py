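"""Mediation: path fitting, product of coefficients, bootstrap CIs, Baron."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from almediation import (
    SimulationConfig,
    baron_criteria,
    bootstrap_mediation,
    fit_paths,
    indirect_effect,
    mediate_snps,
    mediation_table,
    simulate_cohort,
)
from almediation.types import DegenerateInputError, EstimationError

from conftest import mediation_arrays


# ---------------------------------------------------------------------------
# product of coefficients
# ---------------------------------------------------------------------------


def test_indirect_effect_is_the_exact_product():
    assert indirect_effect(0.311, 4.639) == pytest.approx(1.442729, abs=1e-9)
    assert indirect_effect(0.0, 123.4) == 0.0
    assert indirect_effect(0.287, 5.124) == pytest.approx(1.470588, abs=1e-6)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    a1=st.floats(-10, 10, allow_nan=False),
    rm=st.floats(-10, 10, allow_nan=False),
    k=st.floats(-5, 5, allow_nan=False),
)
def test_indirect_effect_bilinear(a1, rm, k):
    assert indirect_effect(k * a1, rm) == pytest.approx(
        k * indirect_effect(a1, rm), rel=1e-12, abs=1e-12
    )


# ---------------------------------------------------------------------------
# path fitting
# ---------------------------------------------------------------------------


def test_null_a_path_estimate_small_with_ci_covering_zero(null_cohort):
    x, m, y, covars = mediation_arrays(null_cohort, 0)
    paths = fit_paths(x, m, y, covars)
    se = paths.mediator_fit.se_of("x")
    assert abs(paths.a1) < 3 * se


def test_total_effect_decomposes_into_direct_plus_indirect(causal_cohort):
    """With identical covariate sets, total = direct + a1*rm exactly."""
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    paths = fit_paths(x, m, y, covars)
    assert paths.total_b1 == pytest.approx(paths.rx + paths.a1 * paths.rm, abs=1e-8)


def test_decomposition_fails_gracefully_without_shared_covariates(causal_cohort):
    # the identity is a property of nested models, not of the estimator:
    # it still holds with no covariates at all
    x, m, y, _ = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    paths = fit_paths(x, m, y, covars=None)
    assert paths.total_b1 == pytest.approx(paths.rx + paths.a1 * paths.rm, abs=1e-8)


def test_singular_design_names_the_model(causal_cohort):
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    dup = [covars[0], covars[0]]  # perfectly collinear covariates
    with pytest.raises(EstimationError, match="model"):
        fit_paths(x, m, y, dup)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_same_seed_reproduces_cis(causal_cohort):
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    r1 = bootstrap_mediation(x, m, y, covars, n_boot=300, seed=5)
    r2 = bootstrap_mediation(x, m, y, covars, n_boot=300, seed=5)
    assert r1.ci_indirect == r2.ci_indirect
    assert r1.ci_direct == r2.ci_direct


def test_wider_level_ci_contains_narrower(causal_cohort):
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    r95 = bootstrap_mediation(x, m, y, covars, n_boot=400, level=0.95, seed=8)
    r99 = bootstrap_mediation(x, m, y, covars, n_boot=400, level=0.99, seed=8)
    assert r99.ci_indirect[0] <= r95.ci_indirect[0]
    assert r99.ci_indirect[1] >= r95.ci_indirect[1]


def test_point_estimate_inside_bootstrap_range(causal_cohort):
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    r = bootstrap_mediation(x, m, y, covars, n_boot=400, seed=9)
    draws = r.bootstrap_indirect
    assert draws.min() <= r.indirect_effect <= draws.max()
    assert r.ci_indirect[0] < r.ci_indirect[1]


def test_excessive_failed_replicates_is_a_hard_error():
    rng = np.random.default_rng(4)
    n = 15
    x = np.zeros(n)
    x[0] = 1.0  # single carrier: often absent from a resample
    m = rng.normal(size=n)
    y = rng.normal(size=n)
    with pytest.raises(DegenerateInputError, match="singular"):
        bootstrap_mediation(x, m, y, n_boot=200, seed=0)


def test_planted_effect_yields_significant_indirect_ci(causal_cohort):
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    r = bootstrap_mediation(x, m, y, covars, n_boot=1000, seed=10)
    lo, hi = r.ci_indirect
    assert lo > 0  # true indirect = 0.3 * 5 = 1.5
    assert lo < 1.5 < hi


# ---------------------------------------------------------------------------
# Baron / MacKinnon classification
# ---------------------------------------------------------------------------


def test_strong_paths_classified_full_baron():
    cfg = SimulationConfig(
        n_samples=5000, n_snps=1, maf=0.3, causal_snp_index=0,
        a_path=0.4, b_path=8.0, direct_path=3.0, missing_rate=0.0, seed=31,
    )
    c = simulate_cohort(cfg)
    x, m, y, covars = mediation_arrays(c, 0)
    b = baron_criteria(fit_paths(x, m, y, covars))
    assert b.total_effect and b.exposure_mediator and b.mediator_outcome
    assert b.code == "full_baron"


def test_indirect_only_pattern_classified_mackinnon(causal_cohort):
    """No direct path and a modest total effect, but strong a- and b-paths:
    mediation evidence via the MacKinnon relaxation."""
    x, m, y, covars = mediation_arrays(causal_cohort, causal_cohort.config.causal_snp_index)
    b = baron_criteria(fit_paths(x, m, y, covars))
    assert b.exposure_mediator and b.mediator_outcome
    if not b.total_effect:
        assert b.code == "mackinnon_only"
    else:
        assert b.code == "full_baron"


def test_all_null_classified_no_mediation(null_cohort):
    x, m, y, covars = mediation_arrays(null_cohort, 3)
    b = baron_criteria(fit_paths(x, m, y, covars))
    assert b.code in ("no_mediation_evidence",)


# ---------------------------------------------------------------------------
# multi-SNP driver
# ---------------------------------------------------------------------------


def test_mediate_snps_one_result_per_requested_snp(causal_cohort):
    ids = list(causal_cohort.genotypes.variants["id"].iloc[[0, 30, 31]])
    results = mediate_snps(
        causal_cohort.genotypes, causal_cohort.phenotypes, ids, n_boot=200, seed=2
    )
    assert [r.variant_id for r in results] == ids
    table = mediation_table(results)
    assert len(table) == 3
    assert set(table["baron_code"]).issubset(
        {"full_baron", "mackinnon_only", "no_mediation_evidence"}
    )


def test_mediate_snps_order_independent_per_snp_streams(causal_cohort):
    ids = list(causal_cohort.genotypes.variants["id"].iloc[[0, 30]])
    fwd = mediate_snps(causal_cohort.genotypes, causal_cohort.phenotypes, ids, n_boot=200, seed=2)
    rev = mediate_snps(causal_cohort.genotypes, causal_cohort.phenotypes, ids[::-1], n_boot=200, seed=2)
    assert fwd[0].ci_indirect == rev[1].ci_indirect
    assert fwd[1].ci_indirect == rev[0].ci_indirect


def test_unknown_snp_id_lists_available(causal_cohort):
    with pytest.raises(KeyError, match="available"):
        mediate_snps(causal_cohort.genotypes, causal_cohort.phenotypes, ["rs_nope"], n_boot=200)


def test_monomorphic_snp_is_an_estimation_error(causal_cohort):
    g = causal_cohort.genotypes.copy()
    g.calls[:, 0] = 0
    with pytest.raises(EstimationError, match="constant"):
        mediate_snps(g, causal_cohort.phenotypes, [g.variants["id"].iloc[0]], n_boot=200)


def test_three_ld_block_snps_all_show_mediation(causal_cohort):
    """The causal SNP and its two block neighbours (one LD block) all yield
    indirect CIs excluding zero, mirroring a multi-hit block."""
    idx = causal_cohort.config.causal_snp_index
    ids = list(causal_cohort.genotypes.variants["id"].iloc[[idx, idx + 1, idx + 2]])
    results = mediate_snps(
        causal_cohort.genotypes, causal_cohort.phenotypes, ids, n_boot=500, seed=3
    )
    for r in results:
        assert r.ci_indirect[0] > 0
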