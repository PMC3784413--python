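"""Nonparametric rank statistics implemented from their defining formulas.

Kruskal-Wallis (tie-corrected H, chi-square approximation), Dunn's pairwise
post-hoc z tests on mean ranks (Bonferroni family adjustment, optional),
Friedman's within-block rank test (tie-corrected), the Wilcoxon signed-rank
test (exact enumeration for n <= 15, normal approximation with continuity
correction beyond), and censoring-aware descriptive summaries for truncated
latency data (mean ± SEM; median and IQR with censored entries at the cap).

Only the chi-square and normal reference distributions come from scipy; the
statistics themselves are computed here and are cross-checked in the test
suite against independent brute-force oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata

__all__ = [
    "TestResult",
    "SummaryStats",
    "kruskal_wallis",
    "dunn_posthoc",
    "friedman",
    "wilcoxon_signed_rank",
    "summarize",
]


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: int | None = None
    n: int | None = None
    degenerate: bool = False
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for g in gs:
        r_sum = ranks[start : start + g.size].sum()
        h += r_sum**2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction == 0.0:  # every pooled value identical
        return TestResult("kruskal-wallis", 0.0, 1.0, df=len(gs) - 1, n=n_total, degenerate=True)
    h /= correction
    h = max(h, 0.0)  # guard tiny negative rounding
    df = len(gs) - 1
    return TestResult("kruskal-wallis", h, float(_chi2.sf(h, df)), df=df, n=n_total)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> TestResult:
    """Dunn's pairwise z tests on mean ranks after an omnibus test.

    ``adjust`` is "bonferroni" (family-wise over all pairs) or "none".  The
    returned ``pairwise`` table carries z, raw and adjusted p, and a
    significance flag at ``alpha``.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("dunn_posthoc needs >= 2 groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("dunn_posthoc: empty group")
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = _rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    tie_adj = _tie_term(pooled) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_unit = n_total * (n_total + 1) / 12.0 - tie_adj
    n_pairs = len(gs) * (len(gs) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * _norm.sf(abs(z)))
        p_adj = min(1.0, n_pairs * p_raw) if adjust == "bonferroni" else p_raw
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "z": float(z),
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["p_adjusted"].idxmin()]
    return TestResult(
        f"dunn ({adjust})",
        float(best["z"]),
        float(best["p_adjusted"]),
        n=n_total,
        pairwise=table,
    )


def friedman(block_matrix: np.ndarray) -> TestResult:
    """Friedman chi-square on an n_blocks x k_treatments matrix of complete blocks.

    Within-block average ranks for ties; tie-corrected statistic; p from
    chi-square with k-1 df.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("block_matrix must be 2-D (blocks x treatments)")
    n, k = m.shape
    if k < 2 or n < 2:
        raise ValueError("friedman needs >= 2 treatments and >= 2 blocks")
    if np.isnan(m).any():
        raise ValueError("friedman requires complete blocks (no missing cells)")
    ranks = np.apply_along_axis(_rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    tie_sum = sum(_tie_term(row) for row in m)
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction == 0.0:  # all treatments tie within every block
        return TestResult("friedman", 0.0, 1.0, df=k - 1, n=n, degenerate=True)
    stat = max(stat / correction, 0.0)
    return TestResult("friedman", stat, float(_chi2.sf(stat, k - 1)), df=k - 1, n=n)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ by dynamic programming over sign patterns.

    Works with tied (half-integer) ranks by doubling to integers.  The
    distribution of W+ over the 2^n equiprobable sign assignments is
    symmetric about mu = sum(ranks)/2; the two-sided p is
    P(|W+ - mu| >= |w_obs - mu|).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    support = np.arange(total + 1)
    mu = total / 2.0
    dev = abs(2.0 * w_plus - mu)  # observed |2W+ - mu| on the doubled scale
    return float(counts[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    exact_max_n: int = 15,
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  For n <= ``exact_max_n`` the p-value is
    exact (enumeration of all sign patterns, ties in |d| handled via average
    ranks); beyond that a normal approximation with tie correction and
    continuity correction is used.  The reported statistic is
    W = min(W+, W-).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon signed-rank", 0.0, 1.0, n=0, degenerate=True)
    if n < 3:
        raise ValueError("wilcoxon needs >= 3 non-zero differences")
    ranks = _rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        # variance with tie correction: sum(r^2)/4
        sigma = np.sqrt(np.sum(ranks**2) / 4.0)
        z = (abs(w_plus - mu) - 0.5) / sigma
        p = float(2.0 * _norm.sf(max(z, 0.0)))
    return TestResult("wilcoxon signed-rank", w, min(p, 1.0), n=n)


@dataclass
class SummaryStats:
    mean: float
    sem: float
    median: float
    iqr_lo: float
    iqr_hi: float
    n: int
    n_censored: int
    median_is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if not (self.iqr_lo <= self.median <= self.iqr_hi):
            raise ValueError("IQR must bracket the median")
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")


def summarize(
    values: Sequence[float],
    censored_flags: Sequence[bool] | None = None,
    cap: float | None = None,
) -> SummaryStats:
    """Censoring-aware descriptive summary.

    Censored entries enter at the cap (as they do in a truncated latency
    assay); quantiles use linear interpolation between order statistics.  The
    median is flagged as a lower bound when more than half the cell is
    censored.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize needs at least one value")
    if censored_flags is None:
        cen = np.zeros(v.size, dtype=bool)
    else:
        cen = np.asarray(censored_flags, dtype=bool)
        if cen.size != v.size:
            raise ValueError("censored_flags length mismatch")
        if cen.any():
            if cap is None:
                raise ValueError("cap required when any value is censored")
            if not np.allclose(v[cen], cap):
                raise ValueError("censored values must equal the cap")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    n_cen = int(cen.sum())
    return SummaryStats(
        mean=mean,
        sem=sem,
        median=float(q50),
        iqr_lo=float(q25),
        iqr_hi=float(q75),
        n=int(v.size),
        n_censored=n_cen,
        median_is_lower_bound=n_cen > v.size / 2,
    )
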