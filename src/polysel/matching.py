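"""Matched reference-gene pools and resampling null sets.

Each target gene gets a pool of reference genes that differ by less than
a tolerance (default 20%, relative to the target) in coding length, GC
fraction and recombination rate simultaneously. Null sets draw one pool
member per target slot, enforcing distinctness within a set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_matched_pool", "sample_matched_sets"]

COVARIATES = ["coding_length", "gc", "recomb_cm_mb"]


def build_matched_pool(
    targets: list[str],
    genes: pd.DataFrame,
    tol: float = 0.2,
    symmetric: bool = False,
) -> dict[str, list[str]]:
    """Pool of matched reference genes per target.

    Gene g matches target t iff |x_g - x_t| / x_t < tol for all three
    covariates (strict inequality; denominator is the target unless
    ``symmetric``, which uses max(|x_g|, |x_t|)). A target covariate of
    exactly zero falls back to an absolute comparison against
    tol x the pool median of that covariate. A target never enters its
    own pool. Raises if any target ends up with an empty pool.
    """
    g = genes.set_index("gene_id")
    for c in COVARIATES:
        if c not in g.columns:
            raise ValueError(f"gene table lacks covariate {c}")
        if not np.isfinite(g[c]).all() or (g[c] < 0).any():
            raise ValueError(f"covariate {c} must be finite and non-negative")
    X = g[COVARIATES].to_numpy(dtype=float)
    ids = np.asarray(g.index)
    medians = np.median(X, axis=0)
    target_set = set(targets)
    pools: dict[str, list[str]] = {}
    empty = []
    for t in targets:
        if t not in g.index:
            raise KeyError(f"target {t} absent from gene table")
        xt = g.loc[t, COVARIATES].to_numpy(dtype=float)
        diff = np.abs(X - xt)
        if symmetric:
            denom = np.maximum(np.abs(X), np.abs(xt))
        else:
            denom = np.broadcast_to(xt, X.shape).copy()
        # zero target covariate: absolute comparison against tol x pool median
        zero = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = diff / denom
        ok = np.where(zero, diff < tol * medians, rel < tol)
        match = np.all(ok, axis=1)
        pool = [i for i in ids[match] if i != t and i not in target_set]
        if not pool:
            empty.append(t)
        pools[t] = pool
    if empty:
        raise ValueError(f"empty matched pool for target(s): {empty}")
    return pools


def sample_matched_sets(
    pools: dict[str, list[str]],
    n_sets: int = 10_000,
    seed: int = 0,
    max_retries: int = 1000,
) -> np.ndarray:
    """Draw ``n_sets`` null sets, one matched gene per target slot.

    Returns an object array of shape (n_sets, n_targets) of gene ids,
    slot i matched to target i (dict insertion order). Each set's genes
    are pairwise distinct, enforced by rejection resampling of clashing
    slots; sets are independent given the seed.
    """
    rng = np.random.default_rng(seed)
    targets = list(pools)
    for t in targets:
        if len(pools[t]) == 0:
            raise ValueError(f"pool for {t} is empty")
    arrs = [np.asarray(pools[t], dtype=object) for t in targets]
    k = len(targets)
    out = np.empty((n_sets, k), dtype=object)
    for s in range(n_sets):
        row = [arrs[i][rng.integers(len(arrs[i]))] for i in range(k)]
        for _ in range(max_retries):
            seen: dict = {}
            clash = []
            for i, gid in enumerate(row):
                if gid in seen:
                    clash.append(i)
                else:
                    seen[gid] = i
            if not clash:
                break
            for i in clash:
                row[i] = arrs[i][rng.integers(len(arrs[i]))]
        else:
            raise RuntimeError(
                "could not draw a distinct matched set; pools overlap too "
                "heavily — consider a larger matching tolerance"
            )
        out[s] = row
    return out
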