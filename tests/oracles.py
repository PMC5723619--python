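"""Independent brute-force oracles used to check the package's estimators.

Everything here is deliberately written in the most literal way possible
(explicit loops, exact integer arithmetic, full enumeration) and shares no
code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def ols_slope_oracle(x, y) -> float:
    """Closed-form OLS slope sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)."""
    x = list(map(float, x))
    y = list(map(float, y))
    xbar = sum(x) / len(x)
    ybar = sum(y) / len(y)
    num = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    den = sum((xi - xbar) ** 2 for xi in x)
    return num / den


def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact conditional HWE p-value by full enumeration with rational arithmetic."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return Fraction(1)
    weights = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        weights[h] = (
            math.factorial(n)
            // (math.factorial(hom_min) * math.factorial(h) * math.factorial(hom_maj))
            * 2**h
        )
    total = sum(weights.values())
    w_obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)


def by_stepup_oracle(pvals, alpha: float, method: str = "BY"):
    """Naive sort-and-scan Benjamini-Yekutieli/Hochberg step-up rejection set."""
    p = list(map(float, pvals))
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    c_m = sum(1.0 / i for i in range(1, m + 1)) if method == "BY" else 1.0
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * alpha / (m * c_m):
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    if k_star:
        p_cut = p[order[k_star - 1]]
        for i in range(m):
            if p[i] <= p_cut:
                reject[i] = True
    return reject


def wc_fst_oracle(groups):
    """Weir-Cockerham theta from per-group genotype counts, computed longhand.

    ``groups``: list of (n_hom_A, n_het, n_hom_a) triples. Returns (theta, He)
    with He = 2*pbar*(1-pbar), pbar sample-size weighted. Groups with < 2
    diploids are skipped.
    """
    ns, ps, hs = [], [], []
    for aa, ab, bb in groups:
        n = aa + ab + bb
        if n < 2:
            continue
        ns.append(n)
        ps.append((2 * aa + ab) / (2 * n))
        hs.append(ab / n)
    r = len(ns)
    assert r >= 2
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    theta = a / (a + b + c)
    return theta, 2 * pbar * (1 - pbar)


def genotypic_distance_oracle(calls_i, calls_j, n_loci: int):
    """Smouse-Peakall squared distance between two samples, loop + dict counting.

    ``calls_*`` are sequences of allele pairs or None (missing). Pairwise
    deletion with rescaling by n_loci / n_shared. Returns None if no shared
    called locus.
    """
    total = 0.0
    shared = 0
    for gi, gj in zip(calls_i, calls_j):
        if gi is None or gj is None:
            continue
        shared += 1
        counts_i: dict = {}
        counts_j: dict = {}
        for a in gi:
            counts_i[a] = counts_i.get(a, 0) + 1
        for a in gj:
            counts_j[a] = counts_j.get(a, 0) + 1
        alleles = set(counts_i) | set(counts_j)
        total += 0.5 * sum(
            (counts_i.get(a, 0) - counts_j.get(a, 0)) ** 2 for a in alleles
        )
    if shared == 0:
        return None
    return total * n_loci / shared


def nearest_genes_oracle(position, chrom, genes, window: int, k: int):
    """All-pairs scan for the k nearest genes within the window (inclusive)."""
    hits = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if position < g.start:
            d = g.start - position
        elif position > g.end:
            d = position - g.end
        else:
            d = 0
        if d <= window:
            hits.append((d, g.start, g.gene_id))
    hits.sort()
    return hits[:k]
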