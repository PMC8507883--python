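"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Distinct from 0/1/2 and never imputed.
MISSING: int = -1

#: Required columns of a phenotype table, in canonical order.
PHENOTYPE_COLUMNS = (
    "sample_id",
    "al_ugL",
    "creatinine_mgdl",
    "age",
    "sex",
    "smoke",
    "drink",
)

VARIANT_COLUMNS = ("chrom", "pos", "id", "allele1", "allele2")


class AlmediationError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(AlmediationError, ValueError):
    """Invalid simulation or run configuration."""


class DegenerateInputError(AlmediationError, ValueError):
    """Input too degenerate for the requested computation."""


class EstimationError(AlmediationError, ValueError):
    """A model could not be estimated (singular design, constant genotype...)."""


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of additive genotype calls.

    ``calls[i, j]`` counts copies of the *coded* allele (``allele2`` on ingest,
    the in-sample minor allele after recoding) carried by sample ``i`` at
    variant ``j``; values are 0, 1, 2 or :data:`MISSING`.  ``variants`` holds
    per-variant metadata (chrom, 1-based pos, id, allele1, allele2).
    """

    calls: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x variants array")
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows of calls"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table missing columns {sorted(missing_cols)}")
        if len(self.variants) != m:
            raise ValueError(
                f"{len(self.variants)} variant rows for {m} columns of calls"
            )
        if m and (self.variants["pos"].to_numpy() <= 0).any():
            raise ValueError("variant positions must be positive (1-based)")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or MISSING")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/variant indices."""
        sample_idx = (
            np.arange(self.n_samples)
            if sample_idx is None
            else np.asarray(sample_idx, dtype=np.intp)
        )
        variant_idx = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=np.intp)
        )
        return GenotypeMatrix(
            calls=self.calls[np.ix_(sample_idx, variant_idx)].copy(),
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            variants=self.variants.iloc[variant_idx].reset_index(drop=True),
        )

    def variant_index(self, variant_id: str) -> int:
        """Column index of ``variant_id``; raises with the available ids."""
        ids = self.variants["id"]
        hits = np.flatnonzero(ids.to_numpy() == variant_id)
        if hits.size == 0:
            preview = ", ".join(ids.head(10))
            raise KeyError(
                f"variant {variant_id!r} not found; available ids start with: {preview}"
            )
        return int(hits[0])

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), list(self.sample_ids), self.variants.copy()
        )


def chrom_sort_key(label: str):
    """Order chromosome labels numerically where possible (1..22, X, Y, MT)."""
    s = str(label)
    if s.upper().startswith("CHR"):
        s = s[3:]
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s.upper())
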