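"""Per-SNP additive-model genome scan of ln(plasma Al).

One ordinary-least-squares fit per variant (minor-allele dosage 0/1/2 plus an
intercept and, in the adjusted model, sex/age/smoke/drink), with Bonferroni
and suggestive significance tiers and Manhattan/QQ table construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import design_with_intercept, fit_ols
from .types import MISSING, EstimationError, GenotypeMatrix, chrom_sort_key

DEFAULT_COVARIATES = ("sex", "age", "smoke", "drink")

#: null median of the 1-df chi-square, denominator of the inflation factor
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class ScanConfig:
    """Scan settings: crude vs covariate-adjusted model and thresholds."""

    model: str = "adjusted"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    suggestive_p: float = 1e-6
    exclude_chroms: tuple[str, ...] = ("Y",)

    def validate(self) -> None:
        if self.model not in ("crude", "adjusted"):
            raise ValueError("model must be 'crude' or 'adjusted'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.suggestive_p < 1:
            raise ValueError("suggestive_p must be in (0, 1)")

    def active_covariates(self) -> tuple[str, ...]:
        return self.covariates if self.model == "adjusted" else ()


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (exact value, not the display rounding)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def format_threshold(p: float) -> str:
    """Render a threshold at one significant figure, e.g. 7.74e-08 -> '8e-08'."""
    return f"{p:.0e}"


def covariate_design(pheno: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Numeric covariate columns: sex becomes a male indicator."""
    cols, names = [], []
    for c in covariates:
        if c == "sex":
            cols.append((pheno["sex"].astype(str).str.upper() == "M").to_numpy(float))
        else:
            cols.append(pheno[c].to_numpy(dtype=float))
        names.append("male" if c == "sex" else c)
    return cols, names


def fit_additive_regression(y, g, covars=None) -> dict:
    """OLS of the phenotype on one SNP's dosage (plus covariates).

    Complete-case per SNP: rows with a missing genotype or non-finite
    phenotype/covariates are dropped.  A constant genotype or singular design
    yields an unestimable record (NaN statistics) instead of an exception.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    covars = [np.asarray(c, dtype=float) for c in (covars or [])]
    keep = (g != MISSING) & np.isfinite(y)
    for c in covars:
        keep &= np.isfinite(c)
    n_used = int(keep.sum())
    record = {
        "beta": np.nan,
        "se": np.nan,
        "tstat": np.nan,
        "p": np.nan,
        "n_used": n_used,
        "estimable": False,
    }
    n_coef = 2 + len(covars)
    if n_used < n_coef + 2 or np.all(g[keep] == g[keep][0] if n_used else True):
        return record
    X = design_with_intercept(g[keep], *[c[keep] for c in covars])
    try:
        fit = fit_ols(X, y[keep], names=["intercept", "snp"] + [f"c{i}" for i in range(len(covars))])
    except EstimationError:
        return record
    record.update(
        beta=fit.coef("snp"),
        se=fit.se_of("snp"),
        tstat=float(fit.tstat[1]),
        p=fit.pvalue("snp"),
        estimable=True,
    )
    return record


def _tier(p: float, significant: float, suggestive: float) -> str:
    if not np.isfinite(p):
        return "unestimable"
    if p < significant:
        return "significant"
    if p < suggestive:
        return "suggestive"
    return "none"


def genome_scan(
    g: GenotypeMatrix, pheno: pd.DataFrame, cfg: ScanConfig | None = None
) -> pd.DataFrame:
    """One association record per variant, PLINK-style columns.

    The phenotype table must contain every genotype sample id (joined on
    ``sample_id``); output is sorted by (chrom, pos) and carries significance
    tiers from the exact Bonferroni threshold (strict inequality) and the
    suggestive threshold.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    pheno_idx = pheno.set_index("sample_id")
    missing_ids = [s for s in g.sample_ids if s not in pheno_idx.index]
    if missing_ids:
        raise KeyError(
            f"{len(missing_ids)} genotype samples absent from the phenotype "
            f"table, e.g. {missing_ids[:5]}"
        )
    aligned = pheno_idx.loc[g.sample_ids]
    if "ln_al" not in aligned.columns:
        raise KeyError("phenotype table lacks derived column 'ln_al'")
    y = aligned["ln_al"].to_numpy(dtype=float)
    covars, _ = covariate_design(aligned.reset_index(), cfg.active_covariates())

    keep_chrom = ~g.variants["chrom"].astype(str).isin(cfg.exclude_chroms)
    variants = g.variants.loc[keep_chrom]
    order = sorted(
        variants.index, key=lambda i: (chrom_sort_key(variants.at[i, "chrom"]), variants.at[i, "pos"])
    )
    m_tests = len(order)
    if m_tests == 0:
        raise ValueError("no variants left to scan after chromosome exclusion")
    sig = bonferroni_threshold(cfg.alpha, m_tests)

    rows = []
    for i in order:
        col = g.calls[:, i].astype(float)
        nonmiss = col != MISSING
        n_alt = col[nonmiss].sum()
        maf = n_alt / (2 * nonmiss.sum()) if nonmiss.any() else np.nan
        rec = fit_additive_regression(y, col, covars)
        rows.append(
            {
                "CHR": variants.at[i, "chrom"],
                "SNP": variants.at[i, "id"],
                "BP": int(variants.at[i, "pos"]),
                "A1": variants.at[i, "allele2"],
                "MAF": maf,
                "N": rec["n_used"],
                "BETA": rec["beta"],
                "SE": rec["se"],
                "T": rec["tstat"],
                "P": rec["p"],
                "TIER": _tier(rec["p"], sig, cfg.suggestive_p),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = sig
    out.attrs["bonferroni_display"] = format_threshold(sig)
    out.attrs["suggestive_p"] = cfg.suggestive_p
    out.attrs["model"] = cfg.model
    return out


def qq_table(pvalues) -> tuple[pd.DataFrame, int]:
    """Expected vs observed -log10(p) pairs for a QQ plot.

    Observed p-values sorted ascending; the expected quantile for rank i of M
    is (i - 0.5) / M.  Returns the table and the count of skipped
    (unestimable) records.
    """
    p = np.asarray(pvalues, dtype=float)
    valid = np.isfinite(p)
    n_skipped = int((~valid).sum())
    p = np.sort(p[valid])
    if p.size == 0:
        raise ValueError("no valid p-values for the QQ table")
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    table = pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(p),
        }
    )
    return table, n_skipped


def genomic_lambda(pvalues) -> float:
    """Inflation factor: median association chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def manhattan_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: cumulative genome coordinate and -log10(p) per SNP.

    Chromosomes are concatenated in label order; the significance tier is the
    one carried by the scan records.
    """
    df = records.loc[np.isfinite(records["P"].to_numpy(dtype=float))].copy()
    df = df.sort_values(["CHR", "BP"], key=lambda s: s.map(chrom_sort_key) if s.name == "CHR" else s)
    offset = 0
    cum = np.empty(len(df), dtype=float)
    chroms = df["CHR"].astype(str).to_numpy()
    bp = df["BP"].to_numpy(dtype=float)
    for label in sorted(set(chroms), key=chrom_sort_key):
        mask = chroms == label
        cum[mask] = bp[mask] + offset
        offset += bp[mask].max()
    df["cum_pos"] = cum
    df["neglog10p"] = -np.log10(df["P"].to_numpy(dtype=float))
    return df[["CHR", "SNP", "BP", "cum_pos", "neglog10p", "P", "TIER"]].reset_index(
        drop=True
    )
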