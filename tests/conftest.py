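"""Shared fixtures: small seeded cohorts generated at test time."""

import numpy as np
import pytest

from almediation import SimulationConfig, simulate_cohort
from almediation.scan import covariate_design


@pytest.fixture(scope="session")
def causal_cohort():
    """Moderate cohort with a planted causal SNP in a small LD block."""
    cfg = SimulationConfig(
        n_samples=500,
        n_snps=60,
        maf=0.3,
        ld_copy_prob=0.9,
        block_size=3,
        causal_snp_index=30,
        a_path=0.3,
        b_path=5.0,
        direct_path=0.0,
        missing_rate=0.0,
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic effect on the mediator or outcome."""
    cfg = SimulationConfig(
        n_samples=400,
        n_snps=40,
        maf=0.25,
        causal_snp_index=None,
        missing_rate=0.0,
        seed=202,
    )
    return simulate_cohort(cfg)


def mediation_arrays(cohort, snp_index):
    """Convenience: (x, m, y, covariate columns) for one cohort SNP."""
    ph = cohort.phenotypes
    covars, _ = covariate_design(ph)
    x = cohort.genotypes.calls[:, snp_index].astype(float)
    return x, ph["ln_al"].to_numpy(), ph["egfr"].to_numpy(), covars


def ols_normal_equations_oracle(X, y):
    """Independent closed-form least-squares solver (explicit normal equations).

    Returns (beta, se, t, p) computed via (X'X)^-1 X'y — a different numerical
    route from the engine's SVD-based solver.
    """
    from scipy import stats

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Exact-rational brute-force HWE test.

    Enumerates every heterozygote configuration attainable from the observed
    allele counts, weights it by the exact multinomial probability (integer
    arithmetic via fractions), and sums the weights not exceeding the observed
    configuration's.
    """
    from fractions import Fraction
    from math import comb

    n = n_hom1 + n_het + n_hom2
    a = 2 * n_hom1 + n_het
    rare = min(a, 2 * n - a)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        weights[h] = comb(n, hom_r) * comb(n - hom_r, h) * 2**h
    total = sum(weights.values())
    obs = weights[n_het]
    p = Fraction(sum(w for w in weights.values() if w <= obs), total)
    return float(p)
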