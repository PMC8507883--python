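"""Derived phenotypes: MDRD eGFR, ln-transformed plasma aluminum, and
minor-allele additive genotype coding."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

# MDRD study equation coefficients (serum creatinine in mg/dL, age in years,
# eGFR in mL/min/1.73 m^2)
_MDRD_SCALE = 175.0
_MDRD_CREAT_EXP = -1.154
_MDRD_AGE_EXP = -0.203
_MDRD_FEMALE = 0.742
_MDRD_AFRICAN_AMERICAN = 1.21


def mdrd_egfr(creatinine, age, female, african_american=False):
    """Estimated GFR by the 4-variable MDRD study equation.

    eGFR = 175 * SCr^-1.154 * Age^-0.203 * 0.742(if female) * 1.21(if AA).
    Accepts scalars or arrays; creatinine (mg/dL) and age (years) must be
    positive.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("serum creatinine must be positive (mg/dL)")
    if np.any(age <= 0):
        raise ValueError("age must be positive (years)")
    female = np.asarray(female, dtype=bool)
    african_american = np.asarray(african_american, dtype=bool)
    egfr = (
        _MDRD_SCALE
        * creatinine**_MDRD_CREAT_EXP
        * age**_MDRD_AGE_EXP
        * np.where(female, _MDRD_FEMALE, 1.0)
        * np.where(african_american, _MDRD_AFRICAN_AMERICAN, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_from_egfr(egfr, age, female, african_american=False):
    """Invert the MDRD equation for serum creatinine (exact round trip)."""
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive (years)")
    female = np.asarray(female, dtype=bool)
    african_american = np.asarray(african_american, dtype=bool)
    base = (
        _MDRD_SCALE
        * age**_MDRD_AGE_EXP
        * np.where(female, _MDRD_FEMALE, 1.0)
        * np.where(african_american, _MDRD_AFRICAN_AMERICAN, 1.0)
    )
    scr = (egfr / base) ** (1.0 / _MDRD_CREAT_EXP)
    return scr if scr.ndim else float(scr)


def log_transform_al(al):
    """Natural log of plasma aluminum (μg/L); non-positive values are errors."""
    al = np.asarray(al, dtype=float)
    if np.any(al <= 0):
        raise ValueError("plasma aluminum must be positive for log transform")
    out = np.log(al)
    return out if out.ndim else float(out)


def derive_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns ln_al and egfr to a phenotype table.

    Expects columns al_ugL, creatinine_mgdl, age and sex ('M'/'F'); eGFR is
    recomputed from creatinine via the MDRD equation (non-African-American
    cohort by default, column ``african_american`` honoured when present).
    """
    out = pheno.copy()
    female = out["sex"].astype(str).str.upper().eq("F").to_numpy()
    aa = (
        out["african_american"].astype(bool).to_numpy()
        if "african_american" in out
        else np.zeros(len(out), dtype=bool)
    )
    out["ln_al"] = log_transform_al(out["al_ugL"].to_numpy())
    out["egfr"] = mdrd_egfr(
        out["creatinine_mgdl"].to_numpy(), out["age"].to_numpy(), female, aa
    )
    return out


def additive_code(g: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Recode calls to count the in-sample minor allele at every variant.

    On ingest calls count ``allele2`` (the VCF ALT allele).  Where that allele
    has frequency > 0.5 among non-missing calls the coding is flipped so values
    count the less frequent allele; exact 0.5 ties are broken toward the
    lexicographically smaller allele character.  Monomorphic variants keep an
    all-zero coding and are flagged.  The returned record makes genotype labels
    (e.g. CC/CT/TT -> 0/1/2) reproducible; applying the operation twice is a
    no-op.
    """
    calls = g.calls.copy()
    nonmissing = calls != MISSING
    counts = np.where(nonmissing, calls, 0).sum(axis=0)
    denom = 2 * nonmissing.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coded_freq = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    a1 = g.variants["allele1"].astype(str).to_numpy()
    a2 = g.variants["allele2"].astype(str).to_numpy()
    flip = coded_freq > 0.5
    tie = coded_freq == 0.5
    # tie: code the lexicographically smaller allele character
    flip = flip | (tie & (a2 > a1))
    calls[:, flip] = np.where(
        calls[:, flip] == MISSING, MISSING, 2 - calls[:, flip]
    ).astype(np.int8)

    minor = np.where(flip, a1, a2)
    major = np.where(flip, a2, a1)
    maf = np.where(np.isnan(coded_freq), np.nan, np.where(flip, 1 - coded_freq, coded_freq))
    record = pd.DataFrame(
        {
            "id": g.variants["id"].to_numpy(),
            "minor_allele": minor,
            "major_allele": major,
            "maf": maf,
            "flipped": flip,
            "monomorphic": (maf == 0) | np.isnan(coded_freq),
        }
    )
    variants = g.variants.copy()
    variants["allele1"] = major
    variants["allele2"] = minor
    coded = GenotypeMatrix(calls, list(g.sample_ids), variants)
    return coded, record
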