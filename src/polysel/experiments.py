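"""Desk-scale validation experiments for the whole inference chain.

Each function sets up a self-contained simulation study with the package's
generators, runs the relevant stage(s), and returns summary numbers:
estimator recovery, null calibration of the enrichment and association
tests, and signal recovery for an injected sweep and an environment
effect. The study conditions (sample sizes, gene counts, replicate
counts) are fixed here as the package's reference settings; every source
of randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import rank_test, sumstat_test
from .gea import compute_pcs, encode_genotype_presence, fit_gea_model, gea_scan
from .matching import build_matched_pool, sample_matched_sets
from .pipeline import RunConfig, run_pipeline
from .stats import ScanParams, ihs_scan, standardize_scores, wc_fst_from_genotypes
from .synthetic import (
    SimConfig,
    inject_sweep,
    sim_environment,
    sim_gene_metadata,
    sim_haplotype_region,
    sim_structured_genotypes,
)

__all__ = [
    "fst_recovery",
    "enrichment_null_calibration",
    "gea_null_calibration",
    "sweep_recovery",
    "env_effect_power",
    "pipeline_determinism",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=n)


def fst_recovery(
    seed: int = 0,
    f_values: tuple[float, ...] = (0.02, 0.1, 0.25),
    n_reps: int = 20,
    n_snps: int = 2000,
    n_per_pop: int = 50,
) -> pd.DataFrame:
    """Genome-wide ratio-of-sums FST vs the Balding-Nichols F that generated it.

    Returns one row per F with the mean estimate over replicates and the
    relative error of that mean.
    """
    rows = []
    seeds = _child_seeds(seed, len(f_values) * n_reps).reshape(len(f_values), n_reps)
    for i, F in enumerate(f_values):
        ests = []
        for rep in range(n_reps):
            cfg = SimConfig(
                seed=int(seeds[i, rep]),
                n_snps=n_snps,
                n_per_pop=(n_per_pop, n_per_pop),
                fst_target=F,
            )
            G, panel = sim_structured_genotypes(cfg)
            comp = wc_fst_from_genotypes(G, panel, "pop0", "pop1")
            ests.append(comp.a.sum() / (comp.a + comp.b + comp.c).sum())
        m = float(np.mean(ests))
        rows.append({"F": F, "mean_estimate": m, "rel_error": (m - F) / F, "n_reps": n_reps})
    return pd.DataFrame(rows)


def enrichment_null_calibration(
    seed: int = 0,
    n_reps: int = 200,
    n_genes: int = 1300,
    n_targets: int = 24,
    n_sets: int = 500,
) -> dict:
    """Type-I rate of the rank and SUMSTAT tests under an exchangeable null.

    Per replicate, every gene receives an iid standard-normal score (and
    an independent SNP count), and the "target" set is itself one random
    matched draw from the pools, so its mean is exchangeable with the
    null sets and the empirical p-value is uniform by construction.
    Returns the fraction of p < 0.05 for each test.
    """
    s = _child_seeds(seed, 3)
    genes = sim_gene_metadata(n_genes, targets=n_targets, seed=int(s[0]))
    targets = list(genes.loc[genes["is_target"], "gene_id"])
    pools = build_matched_pool(targets, genes)
    sets = sample_matched_sets(pools, n_sets=n_sets, seed=int(s[1]))
    rng = np.random.default_rng(int(s[2]))
    ids = genes["gene_id"].to_numpy()
    p_rank, p_sum = [], []
    for rep in range(n_reps):
        scores = pd.Series(rng.normal(size=ids.size), index=ids)
        counts = pd.Series(rng.integers(10, 200, size=ids.size), index=ids)
        pseudo = list(sample_matched_sets(pools, n_sets=1, seed=int(rng.integers(2**31)))[0])
        p_rank.append(rank_test(scores, pseudo, sets).p)
        p_sum.append(sumstat_test(scores, counts, pseudo, sets).p)
    return {
        "rank_rejection_rate": float(np.mean(np.asarray(p_rank) < 0.05)),
        "sumstat_rejection_rate": float(np.mean(np.asarray(p_sum) < 0.05)),
        "n_reps": n_reps,
    }


def gea_null_calibration(
    seed: int = 0,
    n_reps: int = 250,
    n_pops: int = 4,
    n_per_pop: int = 30,
    n_snps: int = 30,
) -> dict:
    """Type-I rate of the G likelihood-ratio score with a zero-slope environment.

    One logistic genotype-presence fit per replicate. The tested SNP is
    drawn from the environment-effect generative model with slope 0 —
    the model's own null, where genotype states are independent of both
    environment and population structure. (A population-structured SNP
    with a population-level environment is a different, harder null: the
    individual-level test is anti-conservative there; see the methods
    note.) Returns the fraction of G-test p-values below 0.05.
    """
    seeds = _child_seeds(seed, n_reps)
    ps = []
    for rep in range(n_reps):
        rs = int(seeds[rep])
        cfg = SimConfig(
            seed=rs, n_snps=n_snps, n_pops=n_pops,
            n_per_pop=(n_per_pop,) * n_pops, fst_target=0.05,
        )
        G, panel = sim_structured_genotypes(cfg)
        env, G = sim_environment(panel, G, causal_snp=0, slope=0.0, seed=rs + 1)
        pcs = compute_pcs(G, k=2)
        env_map = dict(zip(env["population"], env["zinc_deficiency_pct"]))
        e = panel["population"].map(env_map).to_numpy(dtype=float)
        states = encode_genotype_presence(G[0])
        if not states:
            continue
        vec = next(iter(states.values()))
        try:
            fit = fit_gea_model(vec, e, pcs)
        except ValueError:
            continue
        if fit.converged:
            ps.append(fit.p_g)
    ps_a = np.asarray(ps)
    return {
        "g_rejection_rate": float(np.mean(ps_a < 0.05)),
        "n_fits": int(ps_a.size),
    }


def sweep_recovery(
    seed: int = 0,
    n_reps: int = 20,
    n_ref_genes: int = 200,
    n_snps: int = 60,
    n_dip: int = 60,
    region: int = 400_000,
    carrier_fraction: float = 0.8,
    decay_bp: float = 100_000.0,
) -> dict:
    """How often an injected sweep gene reaches the top 1% of Max |iHS|.

    Per replicate, one swept gene plus ``n_ref_genes`` neutral gene
    regions are scanned for iHS; scores are standardized genome-wide
    within derived-frequency bins, and success means at most 1% of the
    reference genes beat the swept gene's maximum |iHS|.
    """
    seeds = _child_seeds(seed, n_reps)
    params = ScanParams(trunc_ok=True)
    top_k = max(1, int(np.floor(n_ref_genes * 0.01)))
    successes = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(int(seeds[rep]))
        scans = []
        for g in range(n_ref_genes + 1):
            s = int(rng.integers(2**31))
            haps = sim_haplotype_region(
                SimConfig(seed=s, n_snps=n_snps, n_pops=1, n_per_pop=(n_dip,),
                          region_length=region)
            )
            if g == 0:
                haps = inject_sweep(
                    haps, core=n_snps // 2, carrier_fraction=carrier_fraction,
                    decay_bp=decay_bp, seed=s + 1,
                )
            df = ihs_scan(haps, params)
            df["gene"] = g
            scans.append(df)
        big = pd.concat(scans, ignore_index=True)
        z = standardize_scores(
            big["ihs_unstd"].to_numpy(), big["derived_freq"].to_numpy(), mode="ihs"
        )
        big["absz"] = np.abs(z)
        mx = big.dropna(subset=["absz"]).groupby("gene")["absz"].max()
        n_above = int((mx > mx[0]).sum())
        successes += int(n_above <= top_k)
    return {"success_rate": successes / n_reps, "n_reps": n_reps}


def env_effect_power(
    seed: int = 0,
    n_reps: int = 20,
    slope: float = 0.15,
    n_pops: int = 12,
    n_per_pop: int = 25,
    n_snps: int = 40,
    causal_snp: int = 5,
) -> dict:
    """How often the causal SNP is BH-significant in the association scan.

    ``slope`` is the logistic effect per unit environment (0.15/unit =
    1.5 per 10 percentage points of zinc deficiency). Success means at
    least one genotype state of the causal SNP passes the conjunction of
    BH-adjusted G and Wald at q <= 0.05.
    """
    seeds = _child_seeds(seed, n_reps)
    hits = 0
    for rep in range(n_reps):
        rs = int(seeds[rep])
        cfg = SimConfig(
            seed=rs, n_snps=n_snps, n_pops=n_pops,
            n_per_pop=(n_per_pop,) * n_pops, fst_target=0.05,
        )
        G, panel = sim_structured_genotypes(cfg)
        env, G2 = sim_environment(panel, G, causal_snp=causal_snp, slope=slope, seed=rs + 1)
        pcs = compute_pcs(G2, k=2)
        tab = gea_scan(G2, panel, env, pcs=pcs)
        sig = tab[(tab["snp"] == causal_snp) & tab["significant"]]
        hits += int(len(sig) > 0)
    return {"power": hits / n_reps, "n_reps": n_reps}


def pipeline_determinism(seed: int, work_dir: str | Path) -> bool:
    """Run the synthetic pipeline twice with one seed; outputs must match byte-wise."""
    work = Path(work_dir)
    cfg = RunConfig(
        seed=seed, n_genes=120, n_targets=12, min_pool=4, n_sets=120,
        n_per_pop=25, snps_per_gene=20, run_gea=False,
    )
    run_pipeline(cfg, out_dir=work / "run1")
    run_pipeline(cfg, out_dir=work / "run2")
    names = [p.name for p in sorted((work / "run1").iterdir())]
    same = True
    for name in names:
        if not filecmp.cmp(work / "run1" / name, work / "run2" / name, shallow=False):
            same = False
    return same and len(names) > 0
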