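from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polysel import (
    SimConfig,
    build_matched_pool,
    inject_sweep,
    sim_environment,
    sim_gene_metadata,
    sim_haplotype_region,
    sim_structured_genotypes,
    tajimas_d,
)


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(fst_target=1.0)
    with pytest.raises(ValueError):
        SimConfig(n_pops=3, n_per_pop=(10, 10))
    with pytest.raises(ValueError):
        SimConfig(sweep=(100, 1.5, 1000.0))


def test_structured_genotypes_shape_and_determinism():
    cfg = SimConfig(seed=9, n_snps=100, n_per_pop=(10, 20))
    G1, panel1 = sim_structured_genotypes(cfg)
    G2, panel2 = sim_structured_genotypes(cfg)
    assert G1.shape == (100, 30)
    assert np.array_equal(G1, G2)
    pd.testing.assert_frame_equal(panel1, panel2)
    assert set(np.unique(G1)) <= {0, 1, 2}
    assert list(panel1["population"].value_counts().sort_index()) == [10, 20]


def test_structured_genotypes_f_zero_identical_frequencies():
    cfg = SimConfig(seed=10, n_snps=3000, n_per_pop=(500, 500), fst_target=0.0)
    G, panel = sim_structured_genotypes(cfg)
    p0 = G[:, :500].mean(axis=1) / 2
    p1 = G[:, 500:].mean(axis=1) / 2
    # same underlying frequency: differences are pure binomial noise
    assert np.abs(p0 - p1).mean() < 0.02


def test_haplotype_region_shape_and_determinism():
    cfg = SimConfig(seed=3, n_snps=50, n_pops=1, n_per_pop=(25,), region_length=300_000)
    h1 = sim_haplotype_region(cfg)
    h2 = sim_haplotype_region(cfg)
    assert h1.alleles.shape == (50, 50)
    assert np.array_equal(h1.alleles, h2.alleles)
    assert np.all(np.diff(h1.positions) > 0)
    assert h1.positions[-1] <= 300_000
    assert (h1.variants["ancestral"] == "ref").all()


def test_haplotype_region_tajima_near_zero():
    # the neutral founder spectrum should keep sample Tajima's D around 0
    ds = []
    for seed in range(25):
        cfg = SimConfig(seed=seed, n_snps=80, n_pops=1, n_per_pop=(30,), region_length=400_000)
        h = sim_haplotype_region(cfg)
        ds.append(tajimas_d(h.alleles.sum(axis=1), h.n_haplotypes))
    assert abs(np.nanmean(ds)) < 1.0


def test_inject_sweep_core_frequency_and_tracts():
    cfg = SimConfig(seed=5, n_snps=60, n_pops=1, n_per_pop=(40,), region_length=400_000)
    haps = sim_haplotype_region(cfg)
    swept = inject_sweep(haps, core=30, carrier_fraction=0.8, decay_bp=100_000, seed=6)
    freq = swept.alleles[30].mean()
    assert freq == pytest.approx(0.8, abs=1 / haps.n_haplotypes)
    # non-carrier columns untouched
    non_carriers = np.flatnonzero(swept.alleles[30] == 0)
    off_core = np.delete(np.arange(60), 30)
    assert np.array_equal(
        swept.alleles[np.ix_(off_core, non_carriers)],
        haps.alleles[np.ix_(off_core, non_carriers)],
    )
    # carriers share the template near the core far more than far away
    carriers = np.flatnonzero(swept.alleles[30] == 1)
    near = np.abs(swept.positions - swept.positions[30]) < 20_000
    near[30] = False
    far = np.abs(swept.positions - swept.positions[30]) > 100_000
    assert near.any() and far.any()
    same_near = (swept.alleles[np.ix_(near, carriers)] == swept.alleles[near][:, [carriers[0]]]).mean()
    same_far = (swept.alleles[np.ix_(far, carriers)] == swept.alleles[far][:, [carriers[0]]]).mean()
    assert same_near > same_far


def test_inject_sweep_validation(small_haps):
    with pytest.raises(ValueError):
        inject_sweep(small_haps, 0, 0.0, 1000.0)
    with pytest.raises(ValueError):
        inject_sweep(small_haps, 0, 0.5, -1.0)
    with pytest.raises(IndexError):
        inject_sweep(small_haps, 999, 0.5, 1000.0)


def test_gene_metadata_guarantees_pools():
    genes = sim_gene_metadata(400, targets=6, seed=3, min_pool=20)
    assert len(genes) == 400
    assert genes["is_target"].sum() == 6
    assert (genes["start"] <= genes["end"]).all()
    # intervals must not overlap
    srt = genes.sort_values("start")
    assert (srt["start"].to_numpy()[1:] > srt["end"].to_numpy()[:-1]).all()
    targets = list(genes.loc[genes["is_target"], "gene_id"])
    pools = build_matched_pool(targets, genes)
    assert all(len(pools[t]) >= 20 for t in targets)


def test_gene_metadata_rejects_impossible_request():
    with pytest.raises(ValueError):
        sim_gene_metadata(100, targets=24, min_pool=50)


def test_sim_environment_range_and_null():
    _, panel = sim_structured_genotypes(SimConfig(seed=1, n_snps=5, n_per_pop=(5, 5)))
    env, out = sim_environment(panel, seed=2)
    assert out is None
    assert env["zinc_deficiency_pct"].between(0, 100).all()
    assert len(env) == 2


def test_sim_environment_effect_direction():
    cfg = SimConfig(seed=4, n_snps=5, n_pops=10, n_per_pop=(40,) * 10, fst_target=0.02)
    G, panel = sim_structured_genotypes(cfg)
    env, G2 = sim_environment(panel, G, causal_snp=2, slope=0.2, seed=5)
    env_map = dict(zip(env["population"], env["zinc_deficiency_pct"]))
    e = panel["population"].map(env_map).to_numpy(float)
    hi = G2[2, e > np.median(e)].mean()
    lo = G2[2, e <= np.median(e)].mean()
    assert hi > lo  # positive slope raises the dosage with the environment
    # other SNPs untouched
    assert np.array_equal(np.delete(G2, 2, axis=0), np.delete(G, 2, axis=0))


def test_sim_environment_requires_genotypes_for_effect():
    _, panel = sim_structured_genotypes(SimConfig(seed=1, n_snps=5, n_per_pop=(5, 5)))
    with pytest.raises(ValueError):
        sim_environment(panel, causal_snp=0, slope=0.1)
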