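"""Independent brute-force reference implementations.

Deliberately written in the most literal way possible (scalar loops,
explicit pair counting, textbook formulas) and sharing no code with the
package, so agreement with the package implementations is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def wc_theta_oracle(n1: float, p1: float, h1: float, n2: float, p2: float, h2: float) -> float:
    """Scalar Weir & Cockerham (1984) theta for two populations."""
    r = 2
    ns = [n1, n2]
    ps = [p1, p2]
    hs = [h1, h2]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    if s2 == 0 and pbar * (1 - pbar) == 0:
        return float("nan")
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def tajimas_d_oracle(hap_matrix: np.ndarray) -> float:
    """Tajima's D from a full 0/1 haplotype matrix (sites x chromosomes).

    pi comes from explicit pairwise sequence comparison, not allele
    counts; constants follow Tajima (1989) term by term.
    """
    m = np.asarray(hap_matrix)
    n = m.shape[1]
    seg = []
    for row in m:
        s = int(row.sum())
        if 0 < s < n:
            seg.append(row)
    S = len(seg)
    if S == 0:
        return float("nan")
    seg_m = np.asarray(seg)
    diffs = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((seg_m[:, i] != seg_m[:, j]).sum())
            pairs += 1
    pi = diffs / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def ehh_oracle(alleles: np.ndarray, core: int, allele: int, upto: int) -> float:
    """EHH at marker index ``upto`` by explicit haplotype-pair comparison.

    Carriers of ``allele`` at ``core``; two carriers count as homozygous
    when identical at every marker between ``core`` and ``upto``
    inclusive.
    """
    lo, hi = (core, upto) if upto >= core else (upto, core)
    carriers = [h for h in range(alleles.shape[1]) if alleles[core, h] == allele]
    n = len(carriers)
    if n < 2:
        raise ValueError("needs >= 2 carriers")
    same = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if all(
                alleles[k, carriers[i]] == alleles[k, carriers[j]] for k in range(lo, hi + 1)
            ):
                same += 1
    return same / total


def ld_r2_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype r^2 by explicit haplotype-combination counting."""
    n = len(x)
    n11 = sum(1 for a, b in zip(x, y) if a == 1 and b == 1)
    pa = sum(x) / n
    pb = sum(y) / n
    if pa in (0, 1) or pb in (0, 1):
        return float("nan")
    D = n11 / n - pa * pb
    return D * D / (pa * (1 - pa) * pb * (1 - pb))


def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted values by literal step-up with a loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = pvals[i] * m / rank_from_end
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


def _avg_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties, by explicit comparison counting."""
    n = len(values)
    ranks = np.empty(n)
    for i in range(n):
        less = sum(1 for v in values if v < values[i])
        equal = sum(1 for v in values if v == values[i])
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_rho_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho = Pearson correlation of average ranks, from scratch."""
    rx = _avg_ranks(np.asarray(x, dtype=float))
    ry = _avg_ranks(np.asarray(y, dtype=float))
    mx, my = rx.mean(), ry.mean()
    num = float(((rx - mx) * (ry - my)).sum())
    den = math.sqrt(float(((rx - mx) ** 2).sum()) * float(((ry - my) ** 2).sum()))
    return num / den
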