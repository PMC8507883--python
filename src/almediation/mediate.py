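"""SNP -> ln(Al) -> eGFR mediation analysis.

Three linear models per SNP X with mediator M = ln(Al) and outcome Y = eGFR:

    total:    Y = b + b1*X + covariates          (total effect b1)
    mediator: M = a + a1*X [+ covariates]        (a-path a1)
    outcome:  Y = r + rx*X + rm*M + covariates   (direct rx, b-path rm)

The indirect effect is the product of coefficients a1*rm, its uncertainty a
percentile bootstrap over case resampling (default 3000 replications, 95%
level).  Mediation evidence is classified by the Baron-Kenny criteria with
the MacKinnon relaxation (mediation without a significant total effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import OLSFit, design_with_intercept, fit_ols
from .scan import DEFAULT_COVARIATES, covariate_design
from .types import MISSING, DegenerateInputError, EstimationError, GenotypeMatrix

#: hard error above this fraction of failed bootstrap replicates
MAX_FAILED_REP_FRACTION = 0.05


@dataclass
class MediationPaths:
    """Fitted coefficients of the three mediation models."""

    total_fit: OLSFit
    mediator_fit: OLSFit
    outcome_fit: OLSFit

    @property
    def total_b1(self) -> float:
        return self.total_fit.coef("x")

    @property
    def a1(self) -> float:
        return self.mediator_fit.coef("x")

    @property
    def rm(self) -> float:
        return self.outcome_fit.coef("m")

    @property
    def rx(self) -> float:
        return self.outcome_fit.coef("x")

    @property
    def indirect(self) -> float:
        return indirect_effect(self.a1, self.rm)


@dataclass
class BaronResult:
    """Criterion flags (X->Y, X->M, M->Y|X) and a narrative code."""

    total_effect: bool
    exposure_mediator: bool
    mediator_outcome: bool
    code: str


@dataclass
class MediationResult:
    variant_id: str
    paths: MediationPaths
    indirect_effect: float
    ci_indirect: tuple[float, float]
    ci_direct: tuple[float, float]
    ci_a1: tuple[float, float]
    ci_rm: tuple[float, float]
    n_boot: int
    level: float
    seed: int | None
    n_failed_reps: int
    baron: BaronResult
    n_obs: int = 0
    bootstrap_indirect: np.ndarray | None = field(default=None, repr=False)


def indirect_effect(a1: float, rm: float) -> float:
    """Product-of-coefficients mediated effect (eGFR units per minor allele)."""
    return float(a1) * float(rm)


def _complete_cases(x, m, y, covars):
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    covars = [np.asarray(c, dtype=float) for c in (covars or [])]
    keep = (x != MISSING) & np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    for c in covars:
        keep &= np.isfinite(c)
    return x[keep], m[keep], y[keep], [c[keep] for c in covars]


def _designs(x, m, y, covars, covariates_in_mediator=True):
    cov_names = [f"c{i}" for i in range(len(covars))]
    d_total = design_with_intercept(x, *covars)
    d_med = design_with_intercept(x, *(covars if covariates_in_mediator else []))
    d_out = design_with_intercept(x, m, *covars)
    names_total = ["intercept", "x"] + cov_names
    names_med = ["intercept", "x"] + (cov_names if covariates_in_mediator else [])
    names_out = ["intercept", "x", "m"] + cov_names
    return (d_total, names_total), (d_med, names_med), (d_out, names_out)


def fit_paths(x, m, y, covars=None, covariates_in_mediator: bool = True) -> MediationPaths:
    """Fit the total, mediator and outcome models on joint complete cases.

    Covariates enter all three models by default; pass
    ``covariates_in_mediator=False`` for the bare exposure->mediator model.
    With identical covariate sets the classic decomposition
    total = direct + indirect holds exactly.
    """
    x, m, y, covars = _complete_cases(x, m, y, covars)
    (dt, nt), (dm, nm), (do, no) = _designs(x, m, y, covars, covariates_in_mediator)
    total = fit_ols(dt, y, names=nt, model_label="total-effect model")
    mediator = fit_ols(dm, m, names=nm, model_label="mediator model")
    outcome = fit_ols(do, y, names=no, model_label="outcome model")
    return MediationPaths(total, mediator, outcome)


def baron_criteria(paths: MediationPaths, alpha: float = 0.05) -> BaronResult:
    """Classify mediation evidence from the three path t-tests.

    'full_baron' when all three classic criteria hold; 'mackinnon_only' when
    the total effect is not significant but both the exposure->mediator and
    mediator->outcome paths are; 'no_mediation_evidence' otherwise.
    """
    f1 = paths.total_fit.pvalue("x") < alpha
    f2 = paths.mediator_fit.pvalue("x") < alpha
    f3 = paths.outcome_fit.pvalue("m") < alpha
    if f1 and f2 and f3:
        code = "full_baron"
    elif f2 and f3:
        code = "mackinnon_only"
    else:
        code = "no_mediation_evidence"
    return BaronResult(f1, f2, f3, code)


def _batched_coefs(design: np.ndarray, response: np.ndarray, idx: np.ndarray):
    """Solve OLS normal equations for every bootstrap replicate at once.

    Returns (coefs, failed): replicates whose design is singular (e.g. a
    constant resampled genotype) get NaN coefficients and a failure flag.
    """
    d = design[idx]  # (B, n, p)
    r = response[idx]  # (B, n)
    xtx = np.einsum("bni,bnj->bij", d, d)
    xty = np.einsum("bni,bn->bi", d, r)
    coefs = np.full(xty.shape, np.nan)
    failed = np.zeros(len(idx), dtype=bool)
    # exact singularity check via column variance of non-intercept columns
    col_var = d.var(axis=1)  # (B, p)
    failed |= (col_var[:, 1:] <= 0).any(axis=1)
    ok = ~failed
    if ok.any():
        try:
            coefs[ok] = np.linalg.solve(xtx[ok], xty[ok][..., None])[..., 0]
        except np.linalg.LinAlgError:
            for b in np.flatnonzero(ok):
                try:
                    coefs[b] = np.linalg.solve(xtx[b], xty[b])
                except np.linalg.LinAlgError:
                    failed[b] = True
    bad = ~np.isfinite(coefs).all(axis=1)
    failed |= bad
    coefs[failed] = np.nan
    return coefs, failed


def bootstrap_mediation(
    x,
    m,
    y,
    covars=None,
    n_boot: int = 3000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    covariates_in_mediator: bool = True,
    variant_id: str = "",
    alpha: float = 0.05,
    chunk_size: int = 1000,
) -> MediationResult:
    """Percentile-bootstrap mediation for one SNP.

    Individuals (rows) are resampled with replacement; the mediator and
    outcome models are refit per replicate and the indirect (a1*rm), direct
    (rx), a1 and rm draws collected.  CIs are empirical percentiles at
    (1-level)/2 and 1-(1-level)/2 with linear interpolation.  Replicates with
    singular designs are counted and excluded; more than 5% failures is a
    hard error.  Seeded and reproducible.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x, m, y, covars = _complete_cases(x, m, y, covars)
    n = len(x)
    if n == 0:
        raise DegenerateInputError("no complete cases")
    if np.all(x == x[0]):
        raise EstimationError(
            f"genotype is constant (MAF 0) for variant {variant_id or '<unnamed>'}"
        )
    paths = fit_paths(x, m, y, covars, covariates_in_mediator)
    baron = baron_criteria(paths, alpha=alpha)

    if rng is None:
        rng = np.random.default_rng(seed)
    (_, _), (d_med, names_med), (d_out, names_out) = _designs(
        x, m, y, covars, covariates_in_mediator
    )
    ix_a1 = names_med.index("x")
    ix_rx = names_out.index("x")
    ix_rm = names_out.index("m")

    a1_draws = np.empty(n_boot)
    rx_draws = np.empty(n_boot)
    rm_draws = np.empty(n_boot)
    failed = np.zeros(n_boot, dtype=bool)
    for start in range(0, n_boot, chunk_size):
        stop = min(start + chunk_size, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        med_coefs, med_fail = _batched_coefs(d_med, m, idx)
        out_coefs, out_fail = _batched_coefs(d_out, y, idx)
        a1_draws[start:stop] = med_coefs[:, ix_a1]
        rx_draws[start:stop] = out_coefs[:, ix_rx]
        rm_draws[start:stop] = out_coefs[:, ix_rm]
        failed[start:stop] = med_fail | out_fail

    n_failed = int(failed.sum())
    if n_failed > MAX_FAILED_REP_FRACTION * n_boot:
        raise DegenerateInputError(
            f"{n_failed}/{n_boot} bootstrap replicates had singular designs; "
            "data too degenerate for a meaningful percentile CI"
        )
    ok = ~failed
    indirect_draws = a1_draws[ok] * rm_draws[ok]
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2

    def ci(draws):
        q = np.quantile(draws, [lo, hi], method="linear")
        return float(q[0]), float(q[1])

    return MediationResult(
        variant_id=variant_id,
        paths=paths,
        indirect_effect=paths.indirect,
        ci_indirect=ci(indirect_draws),
        ci_direct=ci(rx_draws[ok]),
        ci_a1=ci(a1_draws[ok]),
        ci_rm=ci(rm_draws[ok]),
        n_boot=n_boot,
        level=level,
        seed=seed,
        n_failed_reps=n_failed,
        baron=baron,
        n_obs=n,
        bootstrap_indirect=indirect_draws,
    )


def mediate_snps(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_ids,
    covariates=DEFAULT_COVARIATES,
    n_boot: int = 3000,
    level: float = 0.95,
    seed: int = 0,
    covariates_in_mediator: bool = True,
) -> list[MediationResult]:
    """Run the bootstrap mediation for each requested SNP id.

    Each SNP draws its bootstrap resamples from an independent substream keyed
    by the variant's column index, so results do not depend on processing
    order.  Unknown ids raise with the available ids listed.
    """
    pheno_idx = pheno.set_index("sample_id")
    missing_ids = [s for s in g.sample_ids if s not in pheno_idx.index]
    if missing_ids:
        raise KeyError(f"genotype samples absent from phenotypes: {missing_ids[:5]}")
    aligned = pheno_idx.loc[g.sample_ids].reset_index()
    m_col = aligned["ln_al"].to_numpy(dtype=float)
    y_col = aligned["egfr"].to_numpy(dtype=float)
    covars, _ = covariate_design(aligned, covariates)

    results = []
    for snp in snp_ids:
        j = g.variant_index(snp)
        x = g.calls[:, j].astype(float)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
        results.append(
            bootstrap_mediation(
                x,
                m_col,
                y_col,
                covars,
                n_boot=n_boot,
                level=level,
                seed=seed,
                rng=rng,
                covariates_in_mediator=covariates_in_mediator,
                variant_id=snp,
            )
        )
    return results


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Flat summary table (one row per SNP) of paths, effects and CIs."""
    rows = []
    for r in results:
        p = r.paths
        rows.append(
            {
                "snp": r.variant_id,
                "n": r.n_obs,
                "a1": p.a1,
                "a1_se": p.mediator_fit.se_of("x"),
                "a1_ci_lo": r.ci_a1[0],
                "a1_ci_hi": r.ci_a1[1],
                "rm": p.rm,
                "rm_se": p.outcome_fit.se_of("m"),
                "rm_ci_lo": r.ci_rm[0],
                "rm_ci_hi": r.ci_rm[1],
                "indirect": r.indirect_effect,
                "ind_ci_lo": r.ci_indirect[0],
                "ind_ci_hi": r.ci_indirect[1],
                "direct": p.rx,
                "dir_ci_lo": r.ci_direct[0],
                "dir_ci_hi": r.ci_direct[1],
                "total": p.total_b1,
                "n_boot": r.n_boot,
                "level": r.level,
                "seed": r.seed,
                "n_failed_reps": r.n_failed_reps,
                "baron_code": r.baron.code,
            }
        )
    return pd.DataFrame(rows)
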