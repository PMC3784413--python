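"""Independent brute-force oracles for the rank statistics.

Every routine here recomputes a statistic from first principles — manual
average ranking by sorting, alternative algebraic identities (rank-ANOVA for
Kruskal-Wallis, Conover's T1 form for Friedman), and exhaustive sign-pattern
enumeration for the Wilcoxon test — sharing no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def manual_ranks(values) -> list[float]:
    """Average ranks computed by explicit sorting (no scipy)."""
    x = list(values)
    n = len(x)
    order = sorted(range(n), key=lambda i: x[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h_oracle(groups) -> float:
    """Tie-robust H via the rank-ANOVA identity H=(N-1)*SSbetween/SStotal."""
    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    r = manual_ranks(pooled)
    n = len(pooled)
    rbar = sum(r) / n
    ss_total = sum((ri - rbar) ** 2 for ri in r)
    if ss_total == 0.0:
        return 0.0
    ss_between = 0.0
    start = 0
    for m in sizes:
        rj = r[start : start + m]
        ss_between += m * (sum(rj) / m - rbar) ** 2
        start += m
    return (n - 1) * ss_between / ss_total


def friedman_oracle(block_matrix) -> float:
    """Tie-corrected Friedman statistic in Conover's T1 form."""
    m = np.asarray(block_matrix, dtype=float)
    n, k = m.shape
    r = np.array([manual_ranks(row) for row in m])
    a = float(np.sum(r**2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:
        return 0.0
    col_sums = r.sum(axis=0)
    return (k - 1) * (float(np.sum(col_sums**2)) - n * c) / (a - c)


def dunn_oracle(groups, n_pairs_adjust: bool = True):
    """Pairwise Dunn z and Bonferroni-adjusted p from manually computed ranks."""
    from scipy.stats import norm

    sizes = [len(g) for g in groups]
    pooled = [v for g in groups for v in g]
    r = manual_ranks(pooled)
    n = len(pooled)
    mean_ranks = []
    start = 0
    for m in sizes:
        mean_ranks.append(sum(r[start : start + m]) / m)
        start += m
    # tie term by counting duplicates explicitly
    tie = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie += t**3 - t
    var_unit = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = (var_unit * (1.0 / sizes[i] + 1.0 / sizes[j])) ** 0.5
        z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * float(norm.sf(abs(z)))
        if n_pairs_adjust:
            p = min(1.0, n_pairs * p)
        out.append((i, j, z, p))
    return out


def wilcoxon_p_oracle(a, b) -> float:
    """Two-sided exact p by full enumeration of all 2^n sign patterns."""
    d = [x - y for x, y in zip(a, b) if x != y]
    ranks = manual_ranks([abs(v) for v in d])
    w_obs = sum(r for v, r in zip(d, ranks) if v > 0)
    mu = sum(ranks) / 2.0
    hits = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total
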