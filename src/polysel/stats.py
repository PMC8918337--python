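"""Per-SNP and per-gene selection statistics.

Implements the estimators the enrichment machinery consumes:

* Weir & Cockerham (1984) method-of-moments FST with the a/b/c variance
  components and the n_c sample-size correction, plus the per-gene
  weighted-average (ratio-of-sums) and maximum summaries;
* extended haplotype homozygosity (EHH) decay curves and the integrated
  haplotype score iHS = ln(iHH_derived / iHH_ancestral), with the usual
  physical-distance integration guards (EHH cutoff, maximum extension,
  large-gap abort, gap-scaled trapezoids);
* the cross-population XP-EHH log-ratio with the pooled-EHH stopping rule;
* Tajima's D per gene region from allele counts;
* haplotype-based LD r².

Sign conventions: iHS is ln(iHH_derived/iHH_ancestral); downstream
analyses use |iHS|, so the convention only affects diagnostics. Negative
per-SNP FST estimates are preserved (no zero-clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix

__all__ = [
    "FstComponents",
    "ScanParams",
    "EhhCurve",
    "wc_fst_components",
    "wc_fst_from_genotypes",
    "gene_fst_summary",
    "ehh_curve",
    "ihs_unstandardized",
    "ihs_scan",
    "xpehh",
    "standardize_scores",
    "tajimas_d",
    "ld_r2",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------


@dataclass
class FstComponents:
    """Per-SNP Weir-Cockerham variance components and point estimate.

    ``a`` is the among-population component, ``b`` among individuals
    within populations, ``c`` within individuals. ``theta`` is
    a/(a+b+c), NaN where both samples are monomorphic (zero denominator);
    negative estimates are preserved.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom != 0, self.a / denom, np.nan)
        return t


def wc_fst_components(
    n1: np.ndarray,
    p1: np.ndarray,
    h1: np.ndarray,
    n2: np.ndarray,
    p2: np.ndarray,
    h2: np.ndarray,
) -> FstComponents:
    """Two-population Weir-Cockerham components, vectorized over SNPs.

    Parameters are per-population sample sizes (diploid individuals with
    calls), alternate-allele frequencies, and observed heterozygote
    proportions; all broadcastable arrays. Each n must be >= 2.
    """
    n = np.stack([np.broadcast_arrays(n1, p1)[0], np.broadcast_arrays(n2, p2)[0]]).astype(float)
    p = np.stack(np.broadcast_arrays(p1, p2)).astype(float)
    h = np.stack(np.broadcast_arrays(h1, h2)).astype(float)
    if np.any(n < 2):
        raise ValueError("each population needs n >= 2 individuals")
    r = 2.0
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    # both samples monomorphic for the same allele: all components exactly 0
    mono = (s2 == 0) & (pbar * (1 - pbar) == 0)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    c = np.where(mono, 0.0, c)
    return FstComponents(a=np.atleast_1d(a), b=np.atleast_1d(b), c=np.atleast_1d(c))


def wc_fst_from_genotypes(
    G: np.ndarray,
    panel: pd.DataFrame,
    pop_a: str,
    pop_b: str,
) -> FstComponents:
    """Components for every SNP of a dosage matrix (missing coded -1)."""
    stats = []
    for pop in (pop_a, pop_b):
        cols = (panel["population"] == pop).to_numpy()
        if cols.sum() == 0:
            raise KeyError(f"population {pop!r} absent from panel")
        sub = G[:, cols]
        called = sub >= 0
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, np.where(called, sub, 0).sum(axis=1) / (2 * n), np.nan)
            het = np.where(n > 0, ((sub == 1) & called).sum(axis=1) / n, np.nan)
        stats.append((n, p, het))
    (na, pa, ha), (nb, pb, hb) = stats
    return wc_fst_components(na, pa, ha, nb, pb, hb)


def gene_fst_summary(comp: FstComponents, snp_idx: np.ndarray) -> dict:
    """Per-gene FST summary: WA FST = sum(a)/sum(a+b+c), Max FST = max theta.

    SNPs with undefined theta are excluded; a gene where every SNP is
    undefined yields NaN summaries (flagged via n_snps = 0 downstream).
    """
    snp_idx = np.asarray(snp_idx, dtype=int)
    a = comp.a[snp_idx]
    denom = a + comp.b[snp_idx] + comp.c[snp_idx]
    ok = denom != 0
    if not np.any(ok):
        return {"wa_fst": np.nan, "max_fst": np.nan, "n_snps": 0}
    wa = a[ok].sum() / denom[ok].sum()
    theta = a[ok] / denom[ok]
    return {"wa_fst": float(wa), "max_fst": float(theta.max()), "n_snps": int(ok.sum())}


# ---------------------------------------------------------------------------
# Haplotype homozygosity
# ---------------------------------------------------------------------------


@dataclass
class ScanParams:
    """Integration guards for the haplotype scans (physical distance, bp).

    Defaults follow the common selection-scan conventions: EHH decay
    integrated until it falls below ``ehh_cutoff``; extension capped at
    ``max_extend_bp``; an inter-marker gap above ``gap_abort_bp`` aborts
    the locus; gaps above ``gap_scale_bp`` contribute area scaled by
    ``gap_scale_bp / gap``. ``maf_cut`` restricts iHS to cores with
    derived frequency in [maf_cut, 1 - maf_cut]. With ``trunc_ok`` False
    a walk that reaches the region edge before the cutoff invalidates the
    locus; True keeps the partial integral (useful on short regions).
    """

    ehh_cutoff: float = 0.05
    max_extend_bp: int = 1_000_000
    gap_abort_bp: int = 200_000
    gap_scale_bp: int = 20_000
    maf_cut: float = 0.05
    trunc_ok: bool = False
    n_freq_bins: int = 100


@dataclass
class EhhCurve:
    """EHH decay for one allele class at one core SNP.

    ``left`` and ``right`` are (distance_bp, ehh) arrays walking outward
    marker-by-marker; both start at (0, 1).
    """

    core: int
    left: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    right: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _hap_homozygosity(labels: np.ndarray) -> float:
    counts = np.bincount(labels)
    n = labels.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk_ehh(
    alleles: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    carriers: np.ndarray,
    include_core_allele: bool = False,
) -> np.ndarray:
    """(distance, ehh) pairs walking from the core in one direction.

    EHH(d) is the probability that two distinct haplotypes of the class
    are identical over all markers from the core out to distance d.
    """
    n = carriers.size
    if n < 2:
        raise ValueError("allele class needs at least 2 carriers")
    if include_core_allele:
        labels = alleles[core, carriers].astype(np.int64)
        labels = np.unique(labels, return_inverse=True)[1]
        start = _hap_homozygosity(labels)
    else:
        labels = np.zeros(n, dtype=np.int64)
        start = 1.0
    out = [(0.0, start)]
    j = core + step
    S = alleles.shape[0]
    while 0 <= j < S:
        labels = labels * 2 + alleles[j, carriers]
        labels = np.unique(labels, return_inverse=True)[1]
        out.append((float(abs(positions[j] - positions[core])), _hap_homozygosity(labels)))
        j += step
    return np.asarray(out)


def ehh_curve(haps: HaplotypeMatrix, core: int, allele: int) -> EhhCurve:
    """EHH decay curve for carriers of ``allele`` (0 or 1) at ``core``."""
    carriers = np.flatnonzero(haps.alleles[core] == allele)
    pos = haps.positions
    return EhhCurve(
        core=core,
        left=_walk_ehh(haps.alleles, pos, core, -1, carriers),
        right=_walk_ehh(haps.alleles, pos, core, +1, carriers),
    )


def _ihh_one_dir(
    alleles: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    carriers: np.ndarray,
    params: ScanParams,
    include_core_allele: bool = False,
) -> float | None:
    """Walk and integrate in one pass, stopping at the EHH cutoff.

    Equivalent to integrating the full :func:`_walk_ehh` curve but does
    not extend the walk beyond the stopping marker.
    """
    n = carriers.size
    if n < 2:
        raise ValueError("allele class needs at least 2 carriers")
    if include_core_allele:
        labels = np.unique(alleles[core, carriers], return_inverse=True)[1].astype(np.int64)
        e_prev = _hap_homozygosity(labels)
    else:
        labels = np.zeros(n, dtype=np.int64)
        e_prev = 1.0
    d_prev = 0.0
    area = 0.0
    truncated = False
    j = core + step
    S = alleles.shape[0]
    while 0 <= j < S:
        d = float(abs(positions[j] - positions[core]))
        if d > params.max_extend_bp:
            truncated = True
            break
        gap = d - d_prev
        if gap > params.gap_abort_bp:
            return None
        labels = labels * 2 + alleles[j, carriers]
        labels = np.unique(labels, return_inverse=True)[1]
        e = _hap_homozygosity(labels)
        scale = min(1.0, params.gap_scale_bp / gap) if gap > 0 else 1.0
        area += 0.5 * (e_prev + e) * gap * scale
        if e < params.ehh_cutoff:
            truncated = True
            break
        d_prev, e_prev = d, e
        j += step
    if not truncated and not params.trunc_ok:
        return None
    return area


def _ihh_both_dirs(
    alleles: np.ndarray,
    positions: np.ndarray,
    core: int,
    carriers: np.ndarray,
    params: ScanParams,
    include_core_allele: bool = False,
) -> float | None:
    total = 0.0
    for step in (-1, +1):
        part = _ihh_one_dir(alleles, positions, core, step, carriers, params, include_core_allele)
        if part is None:
            return None
        total += part
    return total


def ihs_unstandardized(
    haps: HaplotypeMatrix,
    core: int,
    params: ScanParams | None = None,
) -> float | None:
    """Unstandardized iHS = ln(iHH_derived / iHH_ancestral) at one core SNP.

    Returns None (locus skipped) when the ancestral state is unknown, the
    derived frequency falls outside [maf_cut, 1 - maf_cut], either class
    has < 2 carriers, an integration guard trips, or an iHH is zero.
    """
    params = params or ScanParams()
    if not haps.known_ancestral_mask()[core]:
        return None
    der = haps.derived_alleles()
    freq = der[core].mean()
    if freq < params.maf_cut or freq > 1 - params.maf_cut:
        return None
    carriers_d = np.flatnonzero(der[core] == 1)
    carriers_a = np.flatnonzero(der[core] == 0)
    if carriers_d.size < 2 or carriers_a.size < 2:
        return None
    pos = haps.positions
    ihh_d = _ihh_both_dirs(der, pos, core, carriers_d, params)
    if ihh_d is None:
        return None
    ihh_a = _ihh_both_dirs(der, pos, core, carriers_a, params)
    if ihh_a is None or ihh_a == 0.0 or ihh_d == 0.0:
        return None
    return float(np.log(ihh_d / ihh_a))


def ihs_scan(
    haps: HaplotypeMatrix,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Unstandardized iHS at every eligible SNP of a region.

    Returns a frame with snp index, position, derived frequency and the
    unstandardized score; loci skipped by the guards are absent.
    """
    params = params or ScanParams()
    der = haps.derived_alleles()
    freqs = der.mean(axis=1)
    rows = []
    for j in range(haps.n_variants):
        v = ihs_unstandardized(haps, j, params)
        if v is not None:
            rows.append((j, int(haps.positions[j]), float(freqs[j]), v))
    return pd.DataFrame(rows, columns=["snp", "pos", "derived_freq", "ihs_unstd"])


def xpehh(
    haps_obs: HaplotypeMatrix,
    haps_ref: HaplotypeMatrix,
    core: int,
    params: ScanParams | None = None,
) -> float | None:
    """Unstandardized XP-EHH = ln(iHH_obs / iHH_ref) at one core SNP.

    EHH in each population is computed over all haplotypes (core allele
    included in the haplotype identity); each direction's integration
    stops where the pooled two-population EHH falls below the cutoff.
    Positive values mean longer haplotypes in the observed population.
    Returns None when the reference iHH is zero or a guard trips.
    """
    params = params or ScanParams()
    if not np.array_equal(haps_obs.positions, haps_ref.positions):
        raise ValueError("populations must share the variant grid")
    pos = haps_obs.positions
    pooled = np.concatenate([haps_obs.alleles, haps_ref.alleles], axis=1)
    all_obs = np.arange(haps_obs.n_haplotypes)
    all_ref = np.arange(haps_ref.n_haplotypes)
    all_pool = np.arange(pooled.shape[1])

    ihh_obs = ihh_ref = 0.0
    S = pooled.shape[0]
    for step in (-1, +1):
        lab_p = np.unique(pooled[core, all_pool], return_inverse=True)[1].astype(np.int64)
        lab_o = np.unique(haps_obs.alleles[core], return_inverse=True)[1].astype(np.int64)
        lab_r = np.unique(haps_ref.alleles[core], return_inverse=True)[1].astype(np.int64)
        e_p = _hap_homozygosity(lab_p)
        e_o = _hap_homozygosity(lab_o)
        e_r = _hap_homozygosity(lab_r)
        d_prev = 0.0
        truncated = False
        j = core + step
        while 0 <= j < S:
            d = float(abs(pos[j] - pos[core]))
            if d > params.max_extend_bp:
                truncated = True
                break
            gap = d - d_prev
            if gap > params.gap_abort_bp:
                return None
            lab_p = np.unique(lab_p * 2 + pooled[j], return_inverse=True)[1]
            lab_o = np.unique(lab_o * 2 + haps_obs.alleles[j], return_inverse=True)[1]
            lab_r = np.unique(lab_r * 2 + haps_ref.alleles[j], return_inverse=True)[1]
            ne_p = _hap_homozygosity(lab_p)
            ne_o = _hap_homozygosity(lab_o)
            ne_r = _hap_homozygosity(lab_r)
            scale = min(1.0, params.gap_scale_bp / gap) if gap > 0 else 1.0
            ihh_obs += 0.5 * (e_o + ne_o) * gap * scale
            ihh_ref += 0.5 * (e_r + ne_r) * gap * scale
            if ne_p < params.ehh_cutoff:  # pooled stopping rule
                truncated = True
                break
            e_p, e_o, e_r = ne_p, ne_o, ne_r
            d_prev = d
            j += step
        if not truncated and not params.trunc_ok:
            return None
    if ihh_ref == 0.0 or ihh_obs == 0.0:
        return None
    return float(np.log(ihh_obs / ihh_ref))


def standardize_scores(
    values: np.ndarray,
    derived_freqs: np.ndarray | None = None,
    mode: str = "ihs",
    n_bins: int = 100,
) -> np.ndarray:
    """Standardize raw haplotype scores.

    ``mode="ihs"``: z-score within equal-width derived-allele-frequency
    bins over [0, 1]; bins with fewer than 2 values are merged into the
    nearest populated neighbour. A merged bin with zero variance yields
    NaN (flagged, never silently zero). ``mode="xpehh"``: one global
    z-score, sign preserved.
    """
    values = np.asarray(values, dtype=float)
    if mode == "xpehh":
        sd = values.std(ddof=0)
        if sd == 0:
            return np.full_like(values, np.nan)
        return (values - values.mean()) / sd
    if mode != "ihs":
        raise ValueError(f"unknown mode {mode!r}")
    if derived_freqs is None:
        raise ValueError("ihs mode needs derived_freqs")
    freqs = np.asarray(derived_freqs, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    # merge underpopulated bins into the nearest populated bin centre
    counts = np.bincount(bins, minlength=n_bins)
    good = np.flatnonzero(counts >= 2)
    if good.size == 0:
        return np.full_like(values, np.nan)
    centres = (edges[:-1] + edges[1:]) / 2
    remap = good[np.argmin(np.abs(centres[:, None] - centres[good][None, :]), axis=1)]
    merged = remap[bins]
    out = np.full_like(values, np.nan)
    for b in np.unique(merged):
        sel = merged == b
        sd = values[sel].std(ddof=0)
        if sd > 0:
            out[sel] = (values[sel] - values[sel].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Site-frequency-spectrum and LD statistics
# ---------------------------------------------------------------------------


def tajimas_d(alt_counts: np.ndarray, n: int) -> float:
    """Tajima's D from per-site alternate allele counts over n chromosomes.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard constants;
    pi from pairwise differences via allele counts. NaN when there are no
    segregating sites (the gene is excluded, not scored 0).
    """
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    ac = np.asarray(alt_counts, dtype=float)
    seg = (ac > 0) & (ac < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    ac = ac[seg]
    pi = float((2.0 * ac * (n - ac) / (n * (n - 1))).sum())
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


def ld_r2(haps: HaplotypeMatrix | np.ndarray, snp_i: int, snp_j: int) -> float:
    """Haplotype LD r² = D² / (pA qA pB qB); NaN for a monomorphic SNP."""
    alleles = haps.alleles if isinstance(haps, HaplotypeMatrix) else np.asarray(haps)
    x = alleles[snp_i].astype(float)
    y = alleles[snp_j].astype(float)
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    D = (x * y).mean() - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))
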