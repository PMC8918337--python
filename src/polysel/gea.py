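"""Genotype-environment association with structure correction.

Each SNP contributes up to three binary genotype-state indicators
(hom-ref, het, hom-alt). Presence of a state is modelled by logistic
regression on the population-level environment value (individuals
inherit their population's value) with the first two genotype principal
components as structure covariates:

    logit P(presence) = alpha + beta * env + gamma1 * PC1 + gamma2 * PC2

The environmental coefficient is scored two ways: G = 2 (LL_full -
LL_null) against the model omitting env, and Wald = (beta / SE(beta))^2,
both referred to chi-square with 1 df. p-values are Benjamini-Hochberg
adjusted per score family; a genotype state is flagged significant when
both adjusted values pass (the conjunction is switchable). Spearman
correlations between per-population allele frequencies and environment
complete the module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

log = logging.getLogger(__name__)

__all__ = [
    "encode_genotype_presence",
    "compute_pcs",
    "GEAFit",
    "fit_gea_model",
    "gea_scan",
    "bh_adjust",
    "spearman_env",
]

STATE_NAMES = {0: "hom-ref", 1: "het", 2: "hom-alt"}


def encode_genotype_presence(genotypes: np.ndarray) -> dict[str, np.ndarray]:
    """Binary presence vector per genotype state observed at one SNP.

    ``genotypes`` are dosages 0/1/2 with -1 for missing. States absent
    from the sample are skipped; a state present in every called sample
    is flagged non-informative (constant) and skipped with a log line.
    Missing genotypes are encoded NaN so the fit can drop them.
    """
    g = np.asarray(genotypes)
    called = g >= 0
    out: dict[str, np.ndarray] = {}
    for state, name in STATE_NAMES.items():
        if not np.any(g[called] == state):
            continue
        vec = np.where(called, (g == state).astype(float), np.nan)
        if np.all(vec[called] == 1.0):
            log.info("encode_genotype_presence: state %s constant, skipped", name)
            continue
        out[name] = vec
    return out


def compute_pcs(G: np.ndarray, k: int = 2) -> np.ndarray:
    """Top-k genotype principal components (samples x k).

    Columns (SNPs) are mean-centred and scaled by sqrt(p(1-p)); the
    decomposition is deterministic up to sign, fixed by making each
    component's largest-magnitude loading positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(G, dtype=float).T  # samples x snps
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNP for PCA")
    X = (X - 2 * p) / np.sqrt(p * (1 - p))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    pcs = U[:, :k] * s[:k]
    for j in range(k):
        if pcs[np.argmax(np.abs(pcs[:, j])), j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


@dataclass
class GEAFit:
    beta_env: float
    g_score: float
    wald: float
    p_g: float
    p_wald: float
    n: int
    converged: bool


def fit_gea_model(
    presence: np.ndarray,
    env: np.ndarray,
    pcs: np.ndarray | None,
    tol: float = 1e-8,
    maxiter: int = 50,
    min_n: int = 20,
) -> GEAFit:
    """Logistic genotype-presence fit; G and Wald scores for environment.

    The null model omits env but keeps the PCs. Non-convergence or
    (quasi-)separation marks the fit unusable (``converged`` False) so it
    can be excluded from multiple-testing correction.
    """
    presence = np.asarray(presence, dtype=float)
    env = np.asarray(env, dtype=float)
    ok = ~np.isnan(presence)
    y = presence[ok]
    e = env[ok]
    n = int(y.size)
    if n < min_n:
        raise ValueError(f"only {n} informative individuals (< {min_n})")
    if np.all(y == y[0]):
        raise ValueError("presence vector is constant")
    if np.ptp(e) == 0:
        raise ValueError("environment has no variance across individuals")
    cols = [np.ones(n), e]
    if pcs is not None:
        cols += [np.asarray(pcs)[ok, j] for j in range(np.asarray(pcs).shape[1])]
    X = np.column_stack(cols)
    X0 = np.delete(X, 1, axis=1)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation/convergence surfaced via flags
            full = Logit(y, X).fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
            nullm = Logit(y, X0).fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
        converged = bool(full.mle_retvals["converged"] and nullm.mle_retvals["converged"])
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return GEAFit(np.nan, np.nan, np.nan, np.nan, np.nan, n, False)
    beta = float(full.params[1])
    se = float(full.bse[1])
    g = float(2.0 * (full.llf - nullm.llf))
    g = max(g, 0.0)  # guard tiny negative values from convergence tolerance
    wald = (beta / se) ** 2 if se > 0 else np.nan
    p_g = float(sps.chi2.sf(g, df=1))
    p_wald = float(sps.chi2.sf(wald, df=1)) if np.isfinite(wald) else np.nan
    if not np.isfinite(se) or se > 1e3:
        converged = False  # quasi-separation: absurd standard error
    return GEAFit(beta, g, wald, p_g, p_wald, n, converged)


def gea_scan(
    G: np.ndarray,
    panel: pd.DataFrame,
    env_table: pd.DataFrame,
    pcs: np.ndarray | None = None,
    q_max: float = 0.05,
    require_both: bool = True,
    snp_ids: list | None = None,
) -> pd.DataFrame:
    """Fit every genotype state of every SNP and BH-adjust the two families."""
    env_map = dict(zip(env_table["population"], env_table["zinc_deficiency_pct"]))
    env = panel["population"].map(env_map).to_numpy(dtype=float)
    rows = []
    for j in range(G.shape[0]):
        for state, vec in encode_genotype_presence(G[j]).items():
            try:
                fit = fit_gea_model(vec, env, pcs)
            except ValueError:
                continue
            rows.append(
                {
                    "snp": snp_ids[j] if snp_ids is not None else j,
                    "genotype_state": state,
                    "n": fit.n,
                    "beta_env": fit.beta_env,
                    "G": fit.g_score,
                    "Wald": fit.wald,
                    "p_G": fit.p_g,
                    "p_Wald": fit.p_wald,
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    fit_ok = df["converged"] & df["p_G"].notna() & df["p_Wald"].notna()
    df["q_G"] = np.nan
    df["q_Wald"] = np.nan
    if fit_ok.any():
        qg, _ = bh_adjust(df.loc[fit_ok, "p_G"].to_numpy(), q_max)
        qw, _ = bh_adjust(df.loc[fit_ok, "p_Wald"].to_numpy(), q_max)
        df.loc[fit_ok, "q_G"] = qg
        df.loc[fit_ok, "q_Wald"] = qw
    if require_both:
        df["significant"] = (df["q_G"] <= q_max) & (df["q_Wald"] <= q_max)
    else:
        df["significant"] = (df["q_G"] <= q_max) | (df["q_Wald"] <= q_max)
    df["significant"] = df["significant"].fillna(False)
    return df


def bh_adjust(p: np.ndarray, q_max: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted values and significance flags."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= q_max


def spearman_env(
    freqs: np.ndarray,
    env: np.ndarray,
    pop_sizes: np.ndarray | None = None,
    min_n: int = 10,
    min_pops: int = 5,
    exact_below: int = 9,
) -> tuple[float, float]:
    """Spearman rho between per-population allele frequency and environment.

    Populations with ``pop_sizes`` <= ``min_n`` are excluded. Ties get
    average ranks. The two-sided p-value uses the exact permutation
    distribution of rho for fewer than ``exact_below`` populations and
    the t approximation on n-2 df otherwise.
    """
    freqs = np.asarray(freqs, dtype=float)
    env = np.asarray(env, dtype=float)
    if pop_sizes is not None:
        keep = np.asarray(pop_sizes) > min_n
        freqs, env = freqs[keep], env[keep]
    n = freqs.size
    if n < min_pops:
        raise ValueError(f"only {n} usable populations (< {min_pops})")
    rho = float(sps.spearmanr(freqs, env).statistic)
    if n < exact_below:
        rx = sps.rankdata(freqs)
        ry = sps.rankdata(env)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx[list(perm)], ry)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)
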