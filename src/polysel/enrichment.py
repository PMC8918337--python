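"""Gene-set enrichment against the matched-gene resampling null.

Three tests ask whether the target gene set deviates from what matched
reference genes show genome-wide:

* ``rank_test`` — the mean per-gene aggregate (max or average) of the
  targets, ranked within the distribution of the same mean over resampled
  matched sets;
* ``proportion_test`` — the fraction of target SNPs exceeding each
  resampled set's own 99th-percentile SNP score, tested against the
  nominal 1% tail;
* ``sumstat_test`` — the sum of per-gene maximum scores standardized
  within SNP-count bins, controlling the SNP-density confound.

All three are deterministic given scores and sets. Rank and SUMSTAT
p-values use the (1+k)/(R+1) convention and never reach 0; the
proportion test follows its literal definition and can (documented
asymmetry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "rank_test", "proportion_test", "sumstat_test"]


@dataclass
class EnrichmentResult:
    statistic: str
    aggregation: str
    tail: str
    observed: float
    n_sets: int
    p: float
    extras: dict = field(default_factory=dict)


def _score_matrix(gene_scores: pd.Series, sets: np.ndarray) -> np.ndarray:
    """Look up per-gene scores for every slot of every set (NaN if absent)."""
    lut = gene_scores.to_dict()
    flat = np.array([lut.get(g, np.nan) for g in sets.ravel()], dtype=float)
    return flat.reshape(sets.shape)


def rank_test(
    gene_scores: pd.Series,
    targets: list[str],
    sets: np.ndarray,
    aggregation: str = "max",
    tail: str = "upper",
    min_sets: int = 100,
) -> EnrichmentResult:
    """Rank the targets' mean gene score within the resampling null.

    ``gene_scores`` holds the chosen per-gene aggregate for every scored
    gene. A target without a score is excluded together with its matched
    slot in every set (exclusion propagation). p = (1 + #{null >= obs}) /
    (R + 1) for the upper tail, mirrored for the lower (used for the
    negative-Tajima's-D direction).
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    tgt = np.array([gene_scores.get(t, np.nan) for t in targets], dtype=float)
    usable = ~np.isnan(tgt)
    if not usable.any():
        raise ValueError("no target gene has a usable score")
    if (~usable).any():
        dropped = [t for t, u in zip(targets, usable) if not u]
        log.info("rank_test: excluding unscored targets and their slots: %s", dropped)
    null = _score_matrix(gene_scores, sets[:, usable])
    null_means = np.nanmean(null, axis=1)
    ok = ~np.isnan(null_means)
    null_means = null_means[ok]
    R = null_means.size
    if R < min_sets:
        raise ValueError(f"only {R} usable resample sets (< {min_sets})")
    observed = float(tgt[usable].mean())
    if tail == "upper":
        k = int((null_means >= observed).sum())
    else:
        k = int((null_means <= observed).sum())
    return EnrichmentResult(
        statistic="",
        aggregation=aggregation,
        tail=tail,
        observed=observed,
        n_sets=R,
        p=(1 + k) / (R + 1),
        extras={"null_mean": float(null_means.mean()), "n_targets_used": int(usable.sum())},
    )


def proportion_test(
    snp_scores: np.ndarray,
    gene_snps: dict[str, np.ndarray],
    targets: list[str],
    sets: np.ndarray,
    pct: float = 99.0,
    min_snps: int = 100,
    mode: str = "literal",
) -> EnrichmentResult:
    """Permutation test on the proportion of highly scored target SNPs.

    Per resample set r: the cutoff is the ``pct`` percentile (linear
    interpolation) of the SNP scores pooled over r's genes, and prop_r is
    the fraction of target-set SNP scores strictly above it. Sets pooling
    fewer than ``min_snps`` SNPs are dropped (unstable percentile).

    ``mode="literal"`` reads the test as: p = fraction of sets where
    prop_r <= the nominal tail (1 - pct/100). ``mode="empirical"``
    compares prop_r against each set's own exceedance of its cutoff
    (which differs from the nominal tail only through ties) with the
    (1+k)/(R+1) convention.
    """
    snp_scores = np.asarray(snp_scores, dtype=float)
    tgt_idx = np.concatenate([gene_snps[t] for t in targets]) if targets else np.array([], int)
    tgt_pool = snp_scores[tgt_idx.astype(int)]
    tgt_pool = tgt_pool[~np.isnan(tgt_pool)]
    if tgt_pool.size == 0:
        raise ValueError("target gene set has no scored SNPs")
    nominal = 1.0 - pct / 100.0
    props, own = [], []
    n_dropped = 0
    for r in range(sets.shape[0]):
        idx = np.concatenate([gene_snps.get(g, np.empty(0, int)) for g in sets[r]])
        pool = snp_scores[idx.astype(int)]
        pool = pool[~np.isnan(pool)]
        if pool.size < min_snps:
            n_dropped += 1
            continue
        cutoff = np.percentile(pool, pct)
        props.append(float((tgt_pool > cutoff).mean()))
        own.append(float((pool > cutoff).mean()))
    if n_dropped:
        log.warning("proportion_test: dropped %d sets with < %d SNPs", n_dropped, min_snps)
    props_a = np.asarray(props)
    R = props_a.size
    if R == 0:
        raise ValueError("no usable resample set")
    if mode == "literal":
        p = float((props_a <= nominal).mean())
    elif mode == "empirical":
        k = int((props_a <= np.asarray(own)).sum())
        p = (1 + k) / (R + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EnrichmentResult(
        statistic="",
        aggregation="proportion",
        tail="upper",
        observed=float(props_a.mean()),
        n_sets=R,
        p=p,
        extras={"nominal_tail": nominal, "n_target_snps": int(tgt_pool.size)},
    )


def _density_bins(counts: np.ndarray, n_bins: int, min_per_bin: int = 5) -> np.ndarray:
    """Equal-occupancy bin edges over SNP counts, merging thin bins."""
    qs = np.quantile(counts, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    while edges.size > 2:
        assign = np.clip(np.searchsorted(edges, counts, side="right") - 1, 0, edges.size - 2)
        occ = np.bincount(assign, minlength=edges.size - 1)
        thin = np.flatnonzero(occ < min_per_bin)
        if thin.size == 0:
            break
        b = thin[0]
        drop = b + 1 if b + 1 < edges.size - 1 else b
        log.info("sumstat: merging thin SNP-count bin %d into its neighbour", b)
        edges = np.delete(edges, drop)
    return edges


def sumstat_test(
    max_scores: pd.Series,
    snp_counts: pd.Series,
    targets: list[str],
    sets: np.ndarray,
    n_bins: int = 13,
    standardization: str = "z",
) -> EnrichmentResult:
    """SUMSTAT: sum of per-gene max scores standardized within SNP-count bins.

    Bins are equal-occupancy quantile bins of SNP count over the reference
    genes (all scored non-target genes); within each bin the max score is
    standardized using the reference genes' mean and SD
    (``standardization="z"``) or mapped through a rank-based inverse
    normal (``"rank"``). The observed statistic is the sum of the targets'
    standardized scores; the null sums each resample set's the same way;
    p = (1 + #{null >= obs}) / (R + 1).
    """
    scored = max_scores.dropna()
    target_set = set(targets)
    ref_ids = [g for g in scored.index if g not in target_set]
    if len(ref_ids) < 10:
        raise ValueError("too few scored reference genes for SUMSTAT")
    ref_counts = snp_counts.loc[ref_ids].to_numpy(dtype=float)
    edges = _density_bins(ref_counts, n_bins)

    def bin_of(counts: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(edges, counts, side="right") - 1, 0, edges.size - 2)

    ref_bins = bin_of(ref_counts)
    ref_vals = scored.loc[ref_ids].to_numpy(dtype=float)
    z_lut: dict[str, float] = {}
    for b in np.unique(ref_bins):
        sel = ref_bins == b
        vals = ref_vals[sel]
        ids = np.asarray(ref_ids, dtype=object)[sel]
        if standardization == "z":
            mu, sd = vals.mean(), vals.std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero variance in SNP-count bin {b}")
            bz = (vals - mu) / sd
        elif standardization == "rank":
            ranks = pd.Series(vals).rank(method="average").to_numpy()
            bz = norm.ppf(ranks / (vals.size + 1))
        else:
            raise ValueError(f"unknown standardization {standardization!r}")
        z_lut.update(zip(ids, bz))
        # targets falling in this bin standardized against the reference genes
        if standardization == "z":
            for t in targets:
                if t in scored.index and bin_of(np.array([snp_counts[t]]))[0] == b:
                    z_lut[t] = (scored[t] - mu) / sd
        else:
            srt = np.sort(vals)
            for t in targets:
                if t in scored.index and bin_of(np.array([snp_counts[t]]))[0] == b:
                    rank = np.searchsorted(srt, scored[t], side="right") + 0.5
                    z_lut[t] = float(norm.ppf(rank / (vals.size + 1)))

    tgt_z = np.array([z_lut.get(t, np.nan) for t in targets])
    usable = ~np.isnan(tgt_z)
    if not usable.any():
        raise ValueError("no target gene standardizable")
    observed = float(tgt_z[usable].sum())
    null = np.array(
        [[z_lut.get(g, np.nan) for g in row] for row in sets[:, usable]], dtype=float
    )
    null_sums = np.nansum(null, axis=1)
    R = null_sums.size
    k = int((null_sums >= observed).sum())
    return EnrichmentResult(
        statistic="",
        aggregation="SUMSTAT",
        tail="upper",
        observed=observed,
        n_sets=R,
        p=(1 + k) / (R + 1),
        extras={"n_bins_used": int(np.unique(ref_bins).size)},
    )
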