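"""Seeded synthetic inputs with the statistical structure the scans assume.

Every generator is a pure function of its arguments (seed included), so the
whole pipeline is testable at desk scale without any external download:

* multi-population genotypes under the Balding-Nichols model at a target
  fixation index;
* phased haplotype regions from a founder-mosaic model, with an optional
  injected incomplete sweep (long homozygous haplotypes around a core
  allele at a chosen carrier fraction);
* gene metadata tables guaranteeing matched-gene availability for each
  designated target gene;
* a population-level environment gradient (zinc-deficiency percentage)
  with an optional logistic effect of environment on genotype state.

The founder-mosaic haplotypes are a deliberate non-biological stand-in for
a coalescent simulation: they give controllable extended-haplotype decay
at a fraction of the cost, which is all the haplotype statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ANCESTRAL_REF, HaplotypeMatrix, make_variants_table

__all__ = [
    "SimConfig",
    "sim_structured_genotypes",
    "sim_haplotype_region",
    "inject_sweep",
    "sim_gene_metadata",
    "sim_environment",
]


@dataclass
class SimConfig:
    """Configuration for the synthetic generators.

    ``n_per_pop`` holds diploid sample counts per population. ``fst_target``
    is the Balding-Nichols F in [0, 1). ``sweep`` is an optional
    ``(core_pos_bp, carrier_fraction, decay_bp)`` triple and ``env_effect``
    an optional ``(causal_snp_index, slope_per_unit_env)`` pair; both are
    consumed by the dedicated operations rather than implicitly.
    """

    seed: int = 0
    n_pops: int = 2
    n_per_pop: tuple[int, ...] = (50, 50)
    n_snps: int = 1000
    fst_target: float = 0.1
    region_length: int = 1_000_000
    sweep: tuple[int, float, float] | None = None
    env_effect: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError(f"fst_target must lie in [0, 1), got {self.fst_target}")
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        if self.sweep is not None:
            cf = self.sweep[1]
            if not (0.0 < cf <= 1.0):
                raise ValueError("carrier fraction must lie in (0, 1]")


def sim_structured_genotypes(cfg: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Balding-Nichols genotypes: (n_snps x n_samples) dosages plus a panel.

    Per SNP, an ancestral frequency p ~ Uniform(0.05, 0.95); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``cfg.fst_target`` (F = 0 gives the ancestral frequency exactly);
    genotypes are Binomial(2, pop frequency).
    """
    if cfg.n_pops < 2:
        raise ValueError("need at least two populations")
    if cfg.n_snps < 1:
        raise ValueError("need at least one SNP")
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    F = cfg.fst_target
    geno_blocks = []
    records = []
    for k, n_k in enumerate(cfg.n_per_pop):
        if F == 0.0:
            pk = p
        else:
            shape = (1.0 - F) / F
            pk = rng.beta(p * shape, (1.0 - p) * shape)
        geno_blocks.append(rng.binomial(2, pk[:, None], size=(cfg.n_snps, n_k)))
        records += [
            {"sample": f"pop{k}_s{i}", "population": f"pop{k}", "group": f"pop{k}"}
            for i in range(n_k)
        ]
    G = np.concatenate(geno_blocks, axis=1).astype(np.int8)
    panel = pd.DataFrame.from_records(records)
    return G, panel


def sim_haplotype_region(
    cfg: SimConfig,
    n_founders: int | None = None,
    switch_mean_bp: float = 20_000.0,
    founder_sfs: str = "neutral",
) -> HaplotypeMatrix:
    """Founder-mosaic phased haplotypes over one region.

    Founder haplotypes carry derived alleles at counts drawn from a
    neutral site-frequency spectrum (P(count = i) proportional to 1/i;
    ``founder_sfs="uniform"`` instead draws per-SNP frequencies
    Uniform(0.1, 0.9)). Each output haplotype is a recombinant mosaic of
    founders with exponentially distributed switch distances (mean
    ``switch_mean_bp``). ``n_founders`` defaults to half the output
    haplotype count (minimum 8) so the sample spectrum stays close to the
    founder spectrum. Positions are strictly increasing; the reference
    allele is recorded as ancestral at every SNP.
    """
    if cfg.region_length <= 0:
        raise ValueError("region_length must be positive")
    if cfg.n_snps < 2:
        raise ValueError("need at least two SNPs")
    rng = np.random.default_rng(cfg.seed)
    n_haps = 2 * int(sum(cfg.n_per_pop))
    if n_founders is None:
        n_founders = max(8, n_haps // 2)
    if n_founders < 2:
        raise ValueError("need at least two founder haplotypes")
    pos = np.sort(rng.choice(np.arange(1, cfg.region_length + 1), size=cfg.n_snps, replace=False))
    if founder_sfs == "neutral":
        i = np.arange(1, n_founders)
        w = 1.0 / i
        counts = rng.choice(i, size=cfg.n_snps, p=w / w.sum())
        founders = np.zeros((cfg.n_snps, n_founders), dtype=np.int8)
        for j, c in enumerate(counts):
            founders[j, rng.choice(n_founders, c, replace=False)] = 1
    elif founder_sfs == "uniform":
        freq = rng.uniform(0.1, 0.9, size=cfg.n_snps)
        founders = (rng.random((cfg.n_snps, n_founders)) < freq[:, None]).astype(np.int8)
    else:
        raise ValueError(f"unknown founder_sfs {founder_sfs!r}")

    alleles = np.empty((cfg.n_snps, n_haps), dtype=np.int8)
    row_idx = np.arange(cfg.n_snps)
    for h in range(n_haps):
        # breakpoints along the region with exponential inter-switch distances
        n_seg = max(1, int(cfg.region_length / switch_mean_bp * 3) + 8)
        breaks = pos[0] + np.cumsum(rng.exponential(switch_mean_bp, size=n_seg))
        seg = np.searchsorted(breaks, pos, side="right")
        founder_of_seg = rng.integers(n_founders, size=n_seg + 1)
        alleles[:, h] = founders[row_idx, founder_of_seg[seg]]

    variants = make_variants_table(pos, ancestral=[ANCESTRAL_REF] * cfg.n_snps)
    samples = [f"s{i}" for i in range(n_haps // 2)]
    return HaplotypeMatrix(variants=variants, alleles=alleles, samples=samples)


def inject_sweep(
    haps: HaplotypeMatrix,
    core: int,
    carrier_fraction: float,
    decay_bp: float,
    seed: int = 0,
) -> HaplotypeMatrix:
    """Overwrite a carrier subset with a core haplotype that decays with distance.

    ``round(carrier_fraction * n_haps)`` haplotypes get the derived allele
    at ``core``; each flanking SNP of a carrier is replaced by the
    template haplotype with marginal probability
    ``exp(-distance / decay_bp)``. The overwrite is realised as one
    contiguous tract per carrier and side, with an Exponential(decay_bp)
    extent — the marginal per-SNP probability is exactly the exponential
    decay, while carriers share unbroken homozygous tracts the way sweep
    haplotypes broken by single recombination events do. Non-carriers are
    left untouched (core set to ancestral so the derived frequency at the
    core equals the carrier fraction up to rounding).
    """
    if not (0 < carrier_fraction <= 1.0):
        raise ValueError("carrier_fraction must lie in (0, 1]")
    if decay_bp <= 0:
        raise ValueError("decay_bp must be positive")
    if not (0 <= core < haps.n_variants):
        raise IndexError(f"core index {core} out of range")
    rng = np.random.default_rng(seed)
    n = haps.n_haplotypes
    n_car = int(round(carrier_fraction * n))
    carriers = rng.choice(n, size=n_car, replace=False)

    alleles = haps.alleles.copy()
    template = alleles[:, rng.integers(n)].copy()
    template[core] = 1  # derived at the core
    pos = haps.positions
    dist = np.abs(pos - pos[core]).astype(float)
    alleles[core, :] = 0
    for h in carriers:
        ext_left = rng.exponential(decay_bp)
        ext_right = rng.exponential(decay_bp)
        hit = ((pos < pos[core]) & (dist <= ext_left)) | (
            (pos > pos[core]) & (dist <= ext_right)
        )
        hit[core] = True
        alleles[hit, h] = template[hit]
    return HaplotypeMatrix(variants=haps.variants, alleles=alleles, samples=haps.samples)


def sim_gene_metadata(
    n_genes: int,
    targets: int = 24,
    seed: int = 0,
    min_pool: int = 50,
    tol: float = 0.2,
    max_retries: int = 20,
) -> pd.DataFrame:
    """Gene annotation table guaranteeing matched-gene availability.

    Coding lengths are log-normal, GC fractions Beta-distributed and
    recombination rates Gamma-distributed, roughly mimicking human
    protein-coding genes. Each of the ``targets`` designated target genes
    is guaranteed at least ``min_pool`` reference genes differing by less
    than ``tol`` (relative to the target) in all three covariates; the
    guarantee is met by seeding the background with jittered copies of the
    targets. Intervals are non-overlapping on one chromosome.
    """
    if n_genes < targets * min_pool:
        raise ValueError(
            f"n_genes={n_genes} cannot guarantee pools of {min_pool} for "
            f"{targets} targets (need >= {targets * min_pool}); a table with "
            "n_genes == targets would make every target match only itself"
        )
    rng = np.random.default_rng(seed)

    def draw_covariates(n: int) -> np.ndarray:
        length = rng.lognormal(mean=7.0, sigma=0.6, size=n)
        gc = rng.beta(12, 14, size=n)
        rec = rng.gamma(shape=2.0, scale=0.6, size=n)
        return np.column_stack([length, gc, rec])

    for _attempt in range(max_retries):
        tgt = draw_covariates(targets)
        n_bg = n_genes - targets
        # seed min_pool jittered clones per target inside the +/- tol box
        jitter_per = min(min_pool, n_bg // targets)
        clones = []
        for t in range(targets):
            fac = rng.uniform(1 - 0.9 * tol, 1 + 0.9 * tol, size=(jitter_per, 3))
            clones.append(tgt[t] * fac)
        bg = np.vstack(clones + [draw_covariates(n_bg - jitter_per * targets)])
        cov = np.vstack([tgt, bg])
        # verify the guarantee with a direct filter
        ok = True
        for t in range(targets):
            rel = np.abs(cov[targets:] - tgt[t]) / tgt[t]
            if int(np.sum(np.all(rel < tol, axis=1))) < min_pool:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not guarantee {min_pool} matched genes per target after {max_retries} tries"
        )

    order = rng.permutation(n_genes)
    cov = cov[order]
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[np.argsort(order)[:targets]] = True

    span = (cov[:, 0] * rng.uniform(1.5, 8.0, size=n_genes)).astype(np.int64)
    gaps = rng.integers(1_000, 50_000, size=n_genes)
    starts = np.cumsum(gaps + np.concatenate([[0], span[:-1]]))
    ends = starts + span - 1
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "chrom": "1",
            "start": starts,
            "end": ends,
            "coding_length": cov[:, 0],
            "gc": cov[:, 1],
            "recomb_cm_mb": cov[:, 2],
            "is_target": is_target,
        }
    )
    return genes


def sim_environment(
    panel: pd.DataFrame,
    genotypes: np.ndarray | None = None,
    causal_snp: int | None = None,
    slope: float = 0.0,
    seed: int = 0,
    alpha: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Population-level environment values, optionally driving one SNP.

    Each population receives a zinc-deficiency percentage ~ Uniform(0, 100).
    When ``causal_snp`` is set, that SNP's genotypes are resampled so each
    individual's alt-allele dosage is Binomial(2, expit(alpha + slope*env)).
    With ``alpha=None`` the intercept is centred at the mean environment so
    the baseline carrier probability is 1/2; ``slope=0`` reduces to the
    null. Returns the environment table and the (possibly modified)
    genotype matrix.
    """
    rng = np.random.default_rng(seed)
    pops = list(pd.unique(panel["population"]))
    env = pd.DataFrame(
        {"population": pops, "zinc_deficiency_pct": rng.uniform(0, 100, size=len(pops))}
    )
    out = genotypes
    if causal_snp is not None:
        if genotypes is None:
            raise ValueError("genotypes required when causal_snp is set")
        if not (0 <= causal_snp < genotypes.shape[0]):
            raise IndexError(f"causal_snp {causal_snp} out of range")
        env_map = dict(zip(env["population"], env["zinc_deficiency_pct"]))
        e = panel["population"].map(env_map).to_numpy(dtype=float)
        a = -slope * e.mean() if alpha is None else alpha
        p = expit(a + slope * e)
        out = genotypes.copy()
        out[causal_snp] = rng.binomial(2, p).astype(genotypes.dtype)
    return env, out
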