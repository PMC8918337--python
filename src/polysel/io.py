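"""Reading and writing the standard inputs, QC filtering and gene assignment.

VCF parsing goes through cyvcf2; only biallelic SNPs are kept, the
ancestral allele comes from the INFO ``AA`` field (case-insensitive,
lowercase accepted by default), and phased GT fields populate the
haplotype matrix. Gene, panel and environment tables travel as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    ANCESTRAL_ALT,
    ANCESTRAL_REF,
    ANCESTRAL_UNKNOWN,
    HaplotypeMatrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "load_vcf",
    "write_vcf",
    "QcReport",
    "qc_filter",
    "ld_prune",
    "assign_snps_to_genes",
    "read_gene_table",
    "write_gene_table",
    "read_panel",
    "write_panel",
    "read_environment",
    "write_environment",
]


def load_vcf(
    path: str | Path,
    samples: list[str] | None = None,
    accept_lowercase_aa: bool = True,
) -> tuple[HaplotypeMatrix, dict]:
    """Read phased biallelic SNPs into a :class:`HaplotypeMatrix`.

    Multi-allelic or non-SNP records are dropped (counted in the report).
    The INFO ``AA`` field sets the ancestral state: matching REF maps to
    ``ref``, matching ALT to ``alt``, anything else (or absent) to
    ``unknown`` — such variants stay usable for frequency statistics but
    are excluded from the haplotype scans downstream. Records with any
    unphased genotype are kept but flagged in the report (suitable for
    genotype-level statistics only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    if samples is not None:
        missing = sorted(set(samples) - set(vcf.samples))
        if missing:
            raise KeyError(f"requested samples absent from VCF: {missing}")
        vcf.set_samples(samples)
    kept_samples = list(vcf.samples)

    rows, alleles = [], []
    n_dropped = 0
    unphased_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        aa = rec.INFO.get("AA")
        ancestral = ANCESTRAL_UNKNOWN
        if aa:
            aa = str(aa).split("|")[0].strip()
            if accept_lowercase_aa:
                aa = aa.upper()
            if aa == rec.REF.upper():
                ancestral = ANCESTRAL_REF
            elif aa == rec.ALT[0].upper():
                ancestral = ANCESTRAL_ALT
        gt = np.asarray(rec.genotype.array())  # (n_samples, 3): a0, a1, phased
        if np.any(gt[:, 2] == 0):
            unphased_rows.append(len(rows))
        alleles.append(np.clip(gt[:, :2], 0, 1).reshape(-1).astype(np.int8))
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "ancestral": ancestral,
            }
        )
    if n_dropped:
        log.info("load_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    variants = pd.DataFrame(rows)
    mat = HaplotypeMatrix(
        variants=variants,
        alleles=np.vstack(alleles) if alleles else np.empty((0, 2 * len(kept_samples)), np.int8),
        samples=kept_samples,
    )
    report = {"n_dropped_multiallelic": n_dropped, "unphased_variant_rows": unphased_rows}
    return mat, report


def write_vcf(haps: HaplotypeMatrix, path: str | Path) -> None:
    """Write a phased VCF 4.2 with INFO AA carrying the ancestral base."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = haps.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(haps.samples) + "\n")
        A = haps.alleles
        for i, row in enumerate(haps.variants.itertuples(index=False)):
            if row.ancestral == ANCESTRAL_REF:
                info = f"AA={row.ref}"
            elif row.ancestral == ANCESTRAL_ALT:
                info = f"AA={row.alt}"
            else:
                info = "."
            gts = "\t".join(
                f"{A[i, 2 * s]}|{A[i, 2 * s + 1]}" for s in range(len(haps.samples))
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


@dataclass
class QcReport:
    n_individuals_removed: int
    n_snps_removed_missing: int
    n_snps_removed_maf: int
    kept_samples: np.ndarray
    kept_snps: np.ndarray


def qc_filter(
    G: np.ndarray,
    max_ind_missing: float = 0.10,
    max_snp_missing: float = 0.05,
    min_maf: float = 0.02,
) -> tuple[np.ndarray, QcReport]:
    """Standard QC on a dosage matrix (missing coded -1).

    Filter order: individuals with more than ``max_ind_missing`` missing
    calls first, then SNPs missing in more than ``max_snp_missing`` of the
    retained individuals, then SNPs with minor allele frequency below
    ``min_maf`` recomputed on the retained samples.
    """
    for t in (max_ind_missing, max_snp_missing, min_maf):
        if not (0.0 <= t <= 1.0):
            raise ValueError("QC thresholds must lie in [0, 1]")
    G = np.asarray(G)
    miss = G < 0
    ind_rate = miss.mean(axis=0)
    keep_ind = ind_rate <= max_ind_missing
    if not np.any(keep_ind):
        raise ValueError("QC removed every individual")
    G1 = G[:, keep_ind]
    snp_rate = (G1 < 0).mean(axis=1)
    keep_snp = snp_rate <= max_snp_missing
    G2 = G1[keep_snp]
    called = G2 >= 0
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, G2, 0).sum(axis=1) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(p, 1 - p)
    keep_maf = (maf >= min_maf) & (n_called > 0)
    kept_snps = np.flatnonzero(keep_snp)[keep_maf]
    report = QcReport(
        n_individuals_removed=int((~keep_ind).sum()),
        n_snps_removed_missing=int((~keep_snp).sum()),
        n_snps_removed_maf=int((~keep_maf).sum()),
        kept_samples=np.flatnonzero(keep_ind),
        kept_snps=kept_snps,
    )
    return G[np.ix_(kept_snps, report.kept_samples)], report


def _r2_genotype(G: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages (the usual pruning r²)."""
    x, y = G[i].astype(float), G[j].astype(float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    G: np.ndarray,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Within each window of ``window`` SNPs, every pair with r² above
    ``r2_max`` drops the later SNP; the window then shifts ``step`` SNPs
    forward. Deterministic given input order.
    """
    n = G.shape[0]
    if n < 2:
        return np.arange(n)
    removed = np.zeros(n, dtype=bool)
    start = 0
    while True:
        idx = [i for i in range(start, min(start + window, n)) if not removed[i]]
        for a in range(len(idx)):
            if removed[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if removed[idx[b]]:
                    continue
                if _r2_genotype(G, idx[a], idx[b]) > r2_max:
                    removed[idx[b]] = True
        if start + window >= n:
            break
        start += step
    return np.flatnonzero(~removed)


def assign_snps_to_genes(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Map each gene to the indices of SNPs inside its body (inclusive).

    A SNP at ``start`` or ``end`` belongs to the gene; a SNP may fall in
    several overlapping genes. Genes without SNPs map to empty arrays.
    Raises when a gene's chromosome label never occurs among the variants
    while other labels do match (build mismatch guard).
    """
    chrom_labels = set(variants["chrom"].unique())
    out: dict[str, np.ndarray] = {}
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    known_gene_chroms = set(genes["chrom"].unique())
    if chrom_labels and known_gene_chroms and chrom_labels.isdisjoint(known_gene_chroms):
        raise ValueError(
            f"no gene chromosome label matches the variants: genes use "
            f"{sorted(known_gene_chroms)}, variants use {sorted(chrom_labels)}"
        )
    for g in genes.itertuples(index=False):
        sel = (chroms == g.chrom) & (pos >= g.start) & (pos <= g.end)
        out[g.gene_id] = np.flatnonzero(sel)
    return out


# --- TSV tables -------------------------------------------------------------

GENE_COLS = ["gene_id", "chrom", "start", "end", "coding_length", "gc", "recomb_cm_mb"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table lacks columns {missing}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene with start > end")
    return genes


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    if panel["sample"].duplicated().any():
        raise ValueError("panel lists a sample twice")
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_environment(path: str | Path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t")
    vals = env["zinc_deficiency_pct"]
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("zinc_deficiency_pct outside [0, 100]")
    return env


def write_environment(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index=False)
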