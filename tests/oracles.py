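"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain-Python dynamic programming,
exhaustive enumeration, union-find — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def sw_score(a: str, b: str, match: float = 1.0, mismatch: float = -2.0,
             gap_open: float = 4.0, gap_extend: float = 1.0) -> float:
    """Exhaustive Gotoh local-alignment score.

    A gap of length L costs gap_open + L * gap_extend.  N never matches
    anything, itself included.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    first = -(gap_open + gap_extend)  # cost of the first gap column

    def sub(x: str, y: str) -> float:
        return match if (x == y and x != "N") else mismatch

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] + first)
            Y[i][j] = max(M[i][j - 1] + first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] + first)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + sub(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def spliced_length(exons) -> int:
    """Per-base enumeration of a transcript's spliced length."""
    bases = set()
    for e in exons:
        for pos in range(e.start, e.end + 1):
            bases.add((e.chrom, pos))
    return len(bases)


def union_find_components(edges) -> set[frozenset]:
    """Connected components of an undirected edge list."""
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict = {}
    for node in list(parent):
        groups.setdefault(find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by probability-mass enumeration."""
    from math import comb

    pmf = [comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(m for m in pmf if m <= obs * (1 + 1e-12)))


def permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int,
                  rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for a difference in means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(perm[: a.size].mean() - perm[a.size:].mean())
        if diff >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def lncrna_filter_oracle(length: int, biotype: str, fpkms, scores,
                         min_length: int = 201, min_fpkm: float = 0.1,
                         max_score: float = 0.0) -> bool:
    """Unordered re-check of the four retention predicates."""
    checks = [
        biotype != "coding",
        length >= min_length,
        max(fpkms) >= min_fpkm,
        all(s < max_score for s in scores),
    ]
    return all(checks)


def nearest_genes_oracle(mid: float, genes, k: int = 5):
    """All-gene distance sort (tie: lower start) — nearest-k ids."""
    ranked = sorted(genes, key=lambda g: (abs((g.start + g.end) / 2 - mid),
                                          g.start))
    return [g.id for g in ranked[:k]]
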