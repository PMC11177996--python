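"""Core in-memory containers: genotype matrices, loci, summary-statistic tables.

Summary statistics and QTL datasets are plain pandas DataFrames with a
documented column schema; this module holds the schema constants plus the
variant-ID and allele-harmonization helpers shared by every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing dosage in the int8 genotype matrix

#: required columns of a per-variant association table (one trait, one ancestry)
SUMSTATS_COLUMNS = [
    "chrom", "pos", "ref", "alt", "id",
    "beta", "se", "z", "p", "maf", "mac", "n", "n_cases", "n_controls",
]

#: required columns of a molecular-QTL summary-statistics table
QTL_COLUMNS = ["analyte_id", "tissue", "chrom", "pos", "ref", "alt", "beta", "se", "p", "n"]


def variant_id(chrom, pos, ref, alt) -> str:
    """Canonical shared variant ID, e.g. ``chr19:18422832:T:C``."""
    c = str(chrom)
    if not c.startswith("chr"):
        c = "chr" + c
    return f"{c}:{pos}:{ref}:{alt}"


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G pairs cannot be oriented across datasets without strand info."""
    return _COMPLEMENT.get(ref.upper()) == alt.upper()


@dataclass
class GenotypeMatrix:
    """Additive dosages (0/1/2, missing=-1) for samples x variants.

    ``variants`` carries chrom, pos (1-based), ref, alt, id; positions are
    strictly increasing within a chromosome.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"variant positions not increasing on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_float(self, mean_impute: bool = True) -> np.ndarray:
        """Float dosages with missing entries mean-imputed per variant."""
        x = self.dosages.astype(float)
        miss = self.dosages == MISSING
        if miss.any():
            x[miss] = np.nan
            if mean_impute:
                col_means = np.nanmean(x, axis=0)
                col_means = np.where(np.isnan(col_means), 0.0, col_means)
                idx = np.where(miss)
                x[idx] = col_means[idx[1]]
        return x

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant, ignoring missing entries."""
        x = self.dosages.astype(float)
        x[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.loc[mask].reset_index(drop=True),
            self.dosages[:, np.asarray(mask)],
        )


@dataclass
class Locus:
    """A lead (sentinel) variant and its 1-Mb flanking window."""

    lead_id: str
    chrom: str
    lead_pos: int
    lead_p: float
    flank: int = 1_000_000
    member_ids: list[str] = field(default_factory=list)
    independent_signals: list[str] = field(default_factory=list)
    nearest_gene: Optional[str] = None

    @property
    def start(self) -> int:
        return max(1, self.lead_pos - self.flank)

    @property
    def end(self) -> int:
        return self.lead_pos + self.flank

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


def harmonize_to(reference: pd.DataFrame, other: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Align ``other`` to ``reference`` on chrom:pos, flipping beta for ref/alt swaps.

    Rows whose alleles match neither orientation, and strand-ambiguous rows
    that mismatch, are dropped. Returns the harmonized subset of ``other``
    (indexed like ``reference`` rows it matched) and a log dict with counts.
    """
    ref = reference.reset_index(drop=True).copy()
    ref["_key"] = ref["chrom"].astype(str) + ":" + ref["pos"].astype(str)
    oth = other.reset_index(drop=True).copy()
    oth["_key"] = oth["chrom"].astype(str) + ":" + oth["pos"].astype(str)
    merged = ref.merge(oth, on="_key", suffixes=("_a", "_b"))
    if merged.empty:
        return merged, {
            "n_overlap": 0, "n_kept": 0, "n_flipped": 0,
            "n_dropped_ambiguous": 0, "n_dropped_mismatch": 0,
        }

    same = (merged["ref_a"] == merged["ref_b"]) & (merged["alt_a"] == merged["alt_b"])
    swapped = (merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])
    ambiguous_mismatch = ~same & merged.apply(
        lambda r: is_strand_ambiguous(r["ref_b"], r["alt_b"]), axis=1
    )
    keep = (same | swapped) & ~ambiguous_mismatch

    out = merged.loc[keep].copy()
    out.loc[swapped[keep], "beta_b"] = -out.loc[swapped[keep], "beta_b"]
    log = {
        "n_overlap": int(len(merged)),
        "n_kept": int(keep.sum()),
        "n_flipped": int((swapped & keep).sum()),
        "n_dropped_ambiguous": int(ambiguous_mismatch.sum()),
        "n_dropped_mismatch": int((~same & ~swapped & ~ambiguous_mismatch).sum()),
    }
    return out, log
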