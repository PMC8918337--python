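"""Outlier gene and candidate SNP calling, plus the functional filter.

Genes are called outliers against the empirical reference-gene score
distribution (top 1%, tail chosen per statistic). SNPs are called by
resampling consistency: a target SNP is a candidate when its score
exceeds the 99th-percentile cutoff of the pooled SNP scores of a matched
set in at least 95% of the resampling sets. Candidates can then be
screened for functional relevance with the CADD / Eigen / Eigen-PC /
FitCons disjunction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["gene_outliers", "snp_candidates", "set_cutoffs", "filter_functional"]


def gene_outliers(
    ref_scores: pd.Series,
    target_scores: pd.Series,
    top: float = 0.01,
    tail: str = "upper",
    min_ref: int = 200,
) -> pd.DataFrame:
    """Flag target genes in the extreme ``top`` tail of the reference genes.

    Upper tail compares against the (1 - top) quantile (used for FST,
    |iHS|, XP-EHH); lower tail against the ``top`` quantile (Tajima's D).
    Targets with undefined scores are excluded and reported.
    """
    ref = ref_scores.dropna()
    if ref.size < min_ref:
        raise ValueError(f"reference distribution has {ref.size} genes (< {min_ref})")
    if tail == "upper":
        cutoff = float(np.quantile(ref.to_numpy(), 1.0 - top))
        flag = target_scores > cutoff
    elif tail == "lower":
        cutoff = float(np.quantile(ref.to_numpy(), top))
        flag = target_scores < cutoff
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    excluded = target_scores.index[target_scores.isna()]
    if len(excluded):
        log.info("gene_outliers: %d target(s) without a score excluded", len(excluded))
    return pd.DataFrame(
        {
            "score": target_scores,
            "cutoff": cutoff,
            "outlier": flag.where(~target_scores.isna(), other=pd.NA),
        }
    )


def set_cutoffs(
    snp_scores: np.ndarray,
    gene_snps: dict[str, np.ndarray],
    sets: np.ndarray,
    pct: float = 99.0,
    min_snps: int = 100,
) -> np.ndarray:
    """Per-resample-set ``pct``-percentile cutoff of pooled SNP scores.

    Shared intermediate between the proportion enrichment test and the
    SNP consistency calls; sets pooling fewer than ``min_snps`` scored
    SNPs yield NaN.
    """
    snp_scores = np.asarray(snp_scores, dtype=float)
    out = np.full(sets.shape[0], np.nan)
    for r in range(sets.shape[0]):
        idx = np.concatenate([gene_snps.get(g, np.empty(0, int)) for g in sets[r]])
        pool = snp_scores[idx.astype(int)]
        pool = pool[~np.isnan(pool)]
        if pool.size >= min_snps:
            out[r] = np.percentile(pool, pct)
    return out


def snp_candidates(
    snp_scores: np.ndarray,
    gene_snps: dict[str, np.ndarray],
    targets: list[str],
    sets: np.ndarray,
    snp_ids: np.ndarray | None = None,
    pct: float = 99.0,
    consistency_min: float = 0.95,
    cutoffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Candidate target SNPs by resampling consistency.

    For each SNP in a target gene, consistency is the fraction of usable
    resample sets whose pooled-score percentile cutoff the SNP's score
    strictly exceeds (a tie counts as not exceeding). SNPs with
    consistency >= ``consistency_min`` are returned, sorted by
    consistency then score. Pass precomputed ``cutoffs`` (from
    :func:`set_cutoffs`) to share work with the proportion test.
    """
    snp_scores = np.asarray(snp_scores, dtype=float)
    if cutoffs is None:
        cutoffs = set_cutoffs(snp_scores, gene_snps, sets, pct=pct)
    cut = cutoffs[~np.isnan(cutoffs)]
    if cut.size == 0:
        raise ValueError("no usable resample set cutoff")
    rows = []
    for t in targets:
        for j in gene_snps.get(t, np.empty(0, int)):
            s = snp_scores[int(j)]
            if np.isnan(s):
                continue
            cons = float((s > cut).mean())
            rows.append(
                {
                    "snp": snp_ids[int(j)] if snp_ids is not None else int(j),
                    "gene": t,
                    "score": float(s),
                    "consistency": cons,
                }
            )
    df = pd.DataFrame(rows, columns=["snp", "gene", "score", "consistency"])
    df = df[df["consistency"] >= consistency_min]
    return df.sort_values(["consistency", "score"], ascending=False).reset_index(drop=True)


def filter_functional(
    candidates: pd.DataFrame,
    annotations: pd.DataFrame,
    cadd_min: float = 10.0,
    eigen_min: float = 0.0,
    eigenpc_min: float = 0.0,
    fitcons_p_max: float = 0.003,
) -> pd.DataFrame:
    """Keep candidates with at least one functional-relevance signal.

    A candidate passes when any present annotation satisfies: CADD Phred
    strictly over ``cadd_min``, Eigen > ``eigen_min``, Eigen-PC >
    ``eigenpc_min``, or FitCons p < ``fitcons_p_max`` (disjunction over
    present fields; thresholds are strict). Candidates absent from the
    annotation table are dropped with a logged count; all annotation
    columns are carried through.
    """
    ann = annotations.set_index("snp")
    present = candidates["snp"].isin(ann.index)
    n_unann = int((~present).sum())
    if n_unann:
        log.info("filter_functional: dropping %d unannotated candidate(s)", n_unann)
    cand = candidates[present].copy()
    joined = cand.join(ann, on="snp")

    def relevant(row: pd.Series) -> bool:
        checks = [
            ("cadd_phred", lambda v: v > cadd_min),
            ("eigen", lambda v: v > eigen_min),
            ("eigen_pc", lambda v: v > eigenpc_min),
            ("fitcons_p", lambda v: v < fitcons_p_max),
        ]
        for col, ok in checks:
            v = row.get(col)
            if v is not None and not pd.isna(v) and ok(v):
                return True
        return False

    keep = joined.apply(relevant, axis=1) if len(joined) else pd.Series([], dtype=bool)
    return joined[keep].reset_index(drop=True)
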