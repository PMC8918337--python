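from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polysel import (
    build_matched_pool,
    proportion_test,
    rank_test,
    sample_matched_sets,
    sim_gene_metadata,
    sumstat_test,
)


@pytest.fixture(scope="module")
def setup():
    genes = sim_gene_metadata(400, targets=6, seed=3, min_pool=20)
    targets = list(genes.loc[genes["is_target"], "gene_id"])
    pools = build_matched_pool(targets, genes)
    sets = sample_matched_sets(pools, n_sets=300, seed=8)
    rng = np.random.default_rng(17)
    scores = pd.Series(rng.normal(size=len(genes)), index=genes["gene_id"])
    counts = pd.Series(rng.integers(10, 100, size=len(genes)), index=genes["gene_id"])
    return genes, targets, sets, scores, counts


def test_rank_test_enriched_targets(setup):
    genes, targets, sets, scores, _ = setup
    boosted = scores.copy()
    boosted[targets] += 5.0
    res = rank_test(boosted, targets, sets)
    assert res.p == pytest.approx(1 / (res.n_sets + 1))
    assert res.observed == pytest.approx(boosted[targets].mean())


def test_rank_test_p_convention_and_bounds(setup):
    _, targets, sets, scores, _ = setup
    res = rank_test(scores, targets, sets)
    assert 1 / (res.n_sets + 1) <= res.p <= 1.0
    # brute-force recomputation of the p-value from the same inputs
    null = np.array([[scores[g] for g in row] for row in sets]).mean(axis=1)
    obs = scores[targets].mean()
    expect = (1 + (null >= obs).sum()) / (len(null) + 1)
    assert res.p == pytest.approx(expect)


def test_rank_test_lower_tail_mirrors(setup):
    _, targets, sets, scores, _ = setup
    up = rank_test(scores, targets, sets, tail="upper")
    lo = rank_test(scores, targets, sets, tail="lower")
    # with continuous scores (no ties), the two tail counts sum to R
    assert up.p + lo.p == pytest.approx((up.n_sets + 2) / (up.n_sets + 1))


def test_rank_test_exclusion_propagation(setup):
    _, targets, sets, scores, _ = setup
    holey = scores.copy()
    holey[targets[0]] = np.nan
    res = rank_test(holey, targets, sets)
    assert res.extras["n_targets_used"] == len(targets) - 1
    # equivalent to running on the reduced target list and its slots
    res2 = rank_test(holey, targets[1:], sets[:, 1:])
    assert res.p == pytest.approx(res2.p)


def test_rank_test_all_unscored(setup):
    _, targets, sets, scores, _ = setup
    empty = pd.Series(np.nan, index=scores.index)
    with pytest.raises(ValueError):
        rank_test(empty, targets, sets)


def test_rank_test_min_sets(setup):
    _, targets, sets, scores, _ = setup
    with pytest.raises(ValueError):
        rank_test(scores, targets, sets[:50], min_sets=100)


def _snp_setup(genes, rng, per_gene=20):
    gene_snps = {}
    scores = []
    for i, gid in enumerate(genes["gene_id"]):
        gene_snps[gid] = np.arange(i * per_gene, (i + 1) * per_gene)
        scores.append(rng.normal(size=per_gene))
    return gene_snps, np.concatenate(scores)


def test_proportion_test_literal_and_empirical(setup, rng):
    genes, targets, sets, _, _ = setup
    gene_snps, snp_scores = _snp_setup(genes, rng)
    lit = proportion_test(snp_scores, gene_snps, targets, sets, mode="literal")
    emp = proportion_test(snp_scores, gene_snps, targets, sets, mode="empirical")
    assert 0.0 <= lit.p <= 1.0
    assert emp.p >= 1 / (emp.n_sets + 1)
    assert lit.extras["nominal_tail"] == pytest.approx(0.01)


def test_proportion_test_detects_inflated_targets(setup, rng):
    genes, targets, sets, _, _ = setup
    gene_snps, snp_scores = _snp_setup(genes, rng)
    boosted = snp_scores.copy()
    for t in targets:
        boosted[gene_snps[t]] += 10.0
    res = proportion_test(boosted, gene_snps, targets, sets)
    assert res.observed > 0.5  # most target SNPs above every cutoff
    assert res.p == 0.0  # literal mode can reach zero (documented asymmetry)


def test_proportion_test_min_snps_guard(setup, rng):
    genes, targets, sets, _, _ = setup
    gene_snps, snp_scores = _snp_setup(genes, rng, per_gene=2)
    with pytest.raises(ValueError):
        # every set pools 6 genes x 2 SNPs = 12 < default min of 100
        proportion_test(snp_scores, gene_snps, targets, sets)


def test_sumstat_detects_enrichment_and_density_confound(setup):
    genes, targets, sets, scores, counts = setup
    boosted = scores.copy()
    boosted[targets] += 5.0
    res = sumstat_test(boosted, counts, targets, sets)
    assert res.p == pytest.approx(1 / (res.n_sets + 1))
    # a SNP-count-driven score alone must NOT look enriched after binning
    confounded = pd.Series(
        counts.to_numpy(float) / 50.0, index=counts.index
    )
    res2 = sumstat_test(confounded, counts, targets, sets)
    assert res2.p > 0.05


def test_sumstat_rank_standardization(setup):
    genes, targets, sets, scores, counts = setup
    # a wild outlier dominates z-scores but not rank-based standardization
    wild = scores.copy()
    ref = [g for g in wild.index if g not in targets]
    wild[ref[0]] = 1e6
    z = sumstat_test(wild, counts, targets, sets, standardization="z")
    r = sumstat_test(wild, counts, targets, sets, standardization="rank")
    assert np.isfinite(r.observed)
    assert abs(r.observed) < abs(z.observed) + 50  # rank version is bounded
    with pytest.raises(ValueError):
        sumstat_test(scores, counts, targets, sets, standardization="nope")


def test_sumstat_too_few_reference_genes(setup):
    _, targets, sets, scores, counts = setup
    tiny = scores.iloc[:5]
    with pytest.raises(ValueError):
        sumstat_test(tiny, counts, targets, sets)
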