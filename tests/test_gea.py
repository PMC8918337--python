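from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from polysel import (
    SimConfig,
    bh_adjust,
    compute_pcs,
    encode_genotype_presence,
    fit_gea_model,
    gea_scan,
    sim_environment,
    sim_structured_genotypes,
    spearman_env,
)

from .oracles import bh_oracle, spearman_rho_oracle


def test_bh_matches_oracle_on_1000_instances(rng):
    for _ in range(1000):
        m = int(rng.integers(1, 30))
        p = rng.uniform(0, 1, size=m)
        q, _ = bh_adjust(p)
        ref = bh_oracle(list(p))
        assert np.allclose(q, ref, atol=1e-12)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.5]))
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, np.nan]))


def test_bh_monotone_in_p(rng):
    p = np.sort(rng.uniform(0, 1, size=20))
    q, _ = bh_adjust(p)
    assert np.all(np.diff(q) >= -1e-15)


def test_spearman_rho_matches_oracle_on_1000_instances(rng):
    for _ in range(1000):
        n = int(rng.integers(5, 15))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rng.random() < 0.3:  # exercise ties
            x = np.round(x)
            y = np.round(y)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        # exact_below=0 keeps this a rho check (the exact permutation p is
        # covered separately and would dominate the runtime here)
        rho, _ = spearman_env(x, y, min_pops=5, exact_below=0)
        assert rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)


def test_spearman_exact_p_small_n():
    # monotone data, n=6: exact permutation p for perfect rank agreement
    x = np.arange(6, dtype=float)
    y = x**2
    rho, p = spearman_env(x, y)
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 720)  # only the two perfect orderings


def test_spearman_excludes_small_populations():
    x = np.arange(8, dtype=float)
    y = x.copy()
    y[-1] = -100  # would break monotonicity, but its population is too small
    sizes = np.array([20] * 7 + [5])
    rho, _ = spearman_env(x, y, pop_sizes=sizes)
    assert rho == pytest.approx(1.0)


def test_spearman_too_few_pops():
    with pytest.raises(ValueError):
        spearman_env(np.arange(3.0), np.arange(3.0))


def test_spearman_t_approx_matches_scipy(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    rho, p = spearman_env(x, y)
    ref = sps.spearmanr(x, y)
    assert rho == pytest.approx(float(ref.statistic), abs=1e-12)
    assert p == pytest.approx(float(ref.pvalue), rel=1e-6)


def test_encode_genotype_presence():
    g = np.array([0, 0, 1, 2, 1, -1])
    states = encode_genotype_presence(g)
    assert set(states) == {"hom-ref", "het", "hom-alt"}
    het = states["het"]
    assert np.isnan(het[5])  # missing propagates as NaN
    assert het[2] == 1.0 and het[0] == 0.0
    # absent state skipped
    assert "hom-alt" not in encode_genotype_presence(np.array([0, 1, 0, 1]))


def test_compute_pcs_separates_populations():
    G, panel = sim_structured_genotypes(
        SimConfig(seed=2, n_snps=500, n_per_pop=(40, 40), fst_target=0.2)
    )
    pcs = compute_pcs(G, k=2)
    assert pcs.shape == (80, 2)
    pop0 = pcs[:40, 0]
    pop1 = pcs[40:, 0]
    assert abs(pop0.mean() - pop1.mean()) > 2 * (pop0.std() + pop1.std())
    # sign convention makes the decomposition fully deterministic
    assert np.allclose(pcs, compute_pcs(G, k=2))


def test_compute_pcs_rank_guard():
    G = np.tile(np.array([[0], [1], [2]]), (1, 6))  # rank-deficient
    with pytest.raises(ValueError):
        compute_pcs(G.T @ np.ones((3, 3), int) * 0 + G[:, :6], k=5)


def test_fit_gea_model_recovers_strong_effect(rng):
    n = 400
    env = rng.uniform(0, 100, size=n)
    logits = -5 + 0.1 * env
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
    fit = fit_gea_model(y, env, pcs=None)
    assert fit.converged
    assert fit.beta_env == pytest.approx(0.1, abs=0.03)
    assert fit.p_g < 1e-10 and fit.p_wald < 1e-10
    assert fit.g_score >= 0 and fit.wald >= 0


def test_fit_gea_model_guards():
    env = np.linspace(0, 100, 30)
    with pytest.raises(ValueError):
        fit_gea_model(np.ones(30), env, None)  # constant presence
    with pytest.raises(ValueError):
        fit_gea_model(np.tile([0.0, 1.0], 15), np.full(30, 5.0), None)  # flat env
    with pytest.raises(ValueError):
        fit_gea_model(np.tile([0.0, 1.0], 5), env[:10], None)  # too few points


def test_gea_scan_null_has_no_hits():
    cfg = SimConfig(seed=21, n_snps=25, n_pops=4, n_per_pop=(30,) * 4, fst_target=0.02)
    G, panel = sim_structured_genotypes(cfg)
    env, _ = sim_environment(panel, seed=22)
    tab = gea_scan(G, panel, env, pcs=compute_pcs(G, k=2))
    assert {"snp", "genotype_state", "q_G", "q_Wald", "significant"} <= set(tab.columns)
    assert tab["significant"].mean() < 0.2


def test_gea_scan_finds_causal_snp():
    cfg = SimConfig(seed=23, n_snps=40, n_pops=12, n_per_pop=(25,) * 12, fst_target=0.05)
    G, panel = sim_structured_genotypes(cfg)
    env, G2 = sim_environment(panel, G, causal_snp=5, slope=0.15, seed=24)
    tab = gea_scan(G2, panel, env, pcs=compute_pcs(G2, k=2))
    hit = tab[(tab["snp"] == 5) & tab["significant"]]
    assert len(hit) > 0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_oracle_property(pvals):
    q, flags = bh_adjust(np.array(pvals))
    assert np.allclose(q, bh_oracle(pvals), atol=1e-12)
    assert np.all((q >= np.array(pvals) - 1e-15) & (q <= 1.0 + 1e-15))
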