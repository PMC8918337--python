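from __future__ import annotations

import numpy as np
import pytest

from polysel import SimConfig, sim_gene_metadata, sim_haplotype_region, sim_structured_genotypes


@pytest.fixture(scope="session")
def small_haps():
    """20 diploids, 40 SNPs over 200 kb — shared read-only haplotype region."""
    return sim_haplotype_region(
        SimConfig(seed=42, n_snps=40, n_pops=1, n_per_pop=(20,), region_length=200_000)
    )


@pytest.fixture(scope="session")
def two_pop_genotypes():
    cfg = SimConfig(seed=7, n_snps=200, n_per_pop=(30, 30), fst_target=0.1)
    return sim_structured_genotypes(cfg)


@pytest.fixture(scope="session")
def gene_table():
    return sim_gene_metadata(400, targets=6, seed=3, min_pool=20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
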