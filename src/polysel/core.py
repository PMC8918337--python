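"""Core in-memory containers shared across the pipeline.

The pipeline works on phased biallelic SNPs. Two containers cover every
stage: a :class:`HaplotypeMatrix` holding 0/1 alleles per variant x
haplotype together with variant metadata (including the ancestral-allele
call needed by haplotype statistics), and plain pandas tables for the
gene annotation, sample panel and environment inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ancestral-state codes stored in the variants table
ANCESTRAL_REF = "ref"
ANCESTRAL_ALT = "alt"
ANCESTRAL_UNKNOWN = "unknown"

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "ancestral"]


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles, one row per variant, one column per haplotype.

    Parameters
    ----------
    variants
        One row per variant with columns ``chrom, pos, id, ref, alt,
        ancestral``; ``ancestral`` is one of ``"ref"``, ``"alt"`` or
        ``"unknown"``. Positions are 1-based and strictly increasing
        within a chromosome.
    alleles
        ``(n_variants, n_haplotypes)`` array of 0/1. Haplotype columns
        come in pairs: columns ``2i`` and ``2i+1`` belong to sample ``i``.
    samples
        Sample identifiers, length ``n_haplotypes / 2``.
    """

    variants: pd.DataFrame
    alleles: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (variants x haplotypes)")
        if len(self.variants) != self.alleles.shape[0]:
            raise ValueError("variants table and allele matrix disagree on variant count")
        if self.samples and 2 * len(self.samples) != self.alleles.shape[1]:
            raise ValueError("haplotype column count must be 2 x sample count")
        vals = np.unique(self.alleles)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("alleles must be 0/1")
        pos = self.variants["pos"].to_numpy()
        for chrom in self.variants["chrom"].unique():
            p = pos[(self.variants["chrom"] == chrom).to_numpy()]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy(dtype=np.int64)

    def derived_alleles(self) -> np.ndarray:
        """Alleles recoded so 1 = derived, given the ancestral annotation.

        Rows with unknown ancestral state are returned unchanged; callers
        that need the derived coding must mask them via
        :meth:`known_ancestral_mask`.
        """
        flip = (self.variants["ancestral"] == ANCESTRAL_ALT).to_numpy()
        out = self.alleles.copy()
        out[flip] = 1 - out[flip]
        return out

    def known_ancestral_mask(self) -> np.ndarray:
        return (self.variants["ancestral"] != ANCESTRAL_UNKNOWN).to_numpy()

    def genotypes(self) -> np.ndarray:
        """Collapse haplotype pairs to diploid dosages (n_variants x n_samples)."""
        return (self.alleles[:, 0::2] + self.alleles[:, 1::2]).astype(np.int8)

    def take_haplotypes(self, hap_idx: np.ndarray) -> "HaplotypeMatrix":
        """Subset haplotype columns (sample ids dropped if pairs are broken)."""
        hap_idx = np.asarray(hap_idx)
        return HaplotypeMatrix(
            variants=self.variants.reset_index(drop=True),
            alleles=self.alleles[:, hap_idx],
            samples=[],
        )

    def take_samples(self, sample_ids: list[str]) -> "HaplotypeMatrix":
        missing = [s for s in sample_ids if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([self.samples.index(s) for s in sample_ids])
        cols = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
        return HaplotypeMatrix(
            variants=self.variants.reset_index(drop=True),
            alleles=self.alleles[:, cols],
            samples=list(sample_ids),
        )


def make_variants_table(
    pos: np.ndarray,
    chrom: str = "1",
    ids: list[str] | None = None,
    ref: list[str] | None = None,
    alt: list[str] | None = None,
    ancestral: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble a variants table with sensible defaults (A/G SNPs, ref ancestral)."""
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.size
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": pos,
            "id": ids if ids is not None else [f"snp{i}" for i in range(n)],
            "ref": ref if ref is not None else ["A"] * n,
            "alt": alt if alt is not None else ["G"] * n,
            "ancestral": ancestral if ancestral is not None else [ANCESTRAL_REF] * n,
        }
    )
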