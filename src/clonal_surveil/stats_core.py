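"""Exact small-sample nonparametric tests and multiplicity corrections.

Group comparisons in small animal cohorts (5-16 per arm) sit right at the
boundary where normal approximations of rank tests become unreliable, so each
test here switches to full enumeration of the permutation null when the
sample sizes permit it:

* Mann-Whitney: all C(n+m, n) assignments of the pooled mid-ranks,
* Wilcoxon signed rank: all 2^n sign patterns of the absolute-rank vector,
* Fisher's exact: all 2x2 tables with the observed margins.

Above the enumeration threshold the tests fall back to the standard
tie-corrected normal (or chi-square) approximations.  Every report records
which method produced its p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestReport",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "paired_t",
    "ratio_paired_t",
    "fisher_exact",
    "kruskal_wallis",
    "dunn_pairwise",
    "bh_fdr",
]

#: Largest combined sample size for which Mann-Whitney enumerates the full
#: permutation null (C(12,6) = 924 assignments).
DEFAULT_EXACT_THRESHOLD = 12

_EPS = 1e-12


@dataclass
class TestReport:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "chi2_approx" | "t" | "degenerate"
    n_per_group: tuple[int, ...]
    tails: str = "two"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "n_per_group": list(self.n_per_group),
            "tails": self.tails,
            **self.extras,
        }


def mann_whitney(x, y, exact_threshold: int = DEFAULT_EXACT_THRESHOLD) -> TestReport:
    """Two-tailed Mann-Whitney U test.

    Exact when ``len(x) + len(y) <= exact_threshold``: the U distribution is
    built by enumerating every assignment of the pooled mid-ranks, which
    handles ties exactly.  The two-tailed p-value is the permutation
    probability of a U at least as far from nm/2 as observed (U1 + U2 = nm,
    so the enumerated distribution is symmetric about nm/2 even with ties).
    Otherwise: tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n].sum() - n * (n + 1) / 2.0
    mid = n * m / 2.0
    dev = abs(u1 - mid)

    if n + m <= exact_threshold:
        total = math.comb(n + m, n)
        hits = 0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
            if abs(u - mid) >= dev - _EPS:
                hits += 1
        return TestReport("mann_whitney", u1, hits / total, "exact", (n, m))

    # tie-corrected normal approximation
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return TestReport("mann_whitney", u1, 1.0, "degenerate", (n, m))
    z = (dev - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestReport("mann_whitney", u1, p, "normal_approx", (n, m), extras={"z": z})


def wilcoxon_signed_rank(x, y=None, exact_threshold: int = DEFAULT_EXACT_THRESHOLD) -> TestReport:
    """Two-tailed Wilcoxon matched-pairs signed rank test.

    Accepts either paired samples ``(x, y)`` or a vector of differences.
    Zero differences are dropped (count reported).  Exact for n <= threshold
    by enumerating all 2^n sign patterns; tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestReport(
            "wilcoxon_signed_rank", 0.0, 1.0, "degenerate", (n,),
            extras={"n_zero_dropped": n_zero, "degenerate": True},
        )
    r = sps.rankdata(np.abs(d))
    w = r[d > 0].sum()
    s = r.sum()
    mid = s / 2.0
    dev = abs(w - mid)

    if n <= exact_threshold:
        hits = 0
        total = 1 << n
        for pattern in range(total):
            wp = sum(r[i] for i in range(n) if pattern >> i & 1)
            if abs(wp - mid) >= dev - _EPS:
                hits += 1
        return TestReport(
            "wilcoxon_signed_rank", w, hits / total, "exact", (n,),
            extras={"n_zero_dropped": n_zero},
        )

    sigma2 = (r**2).sum() / 4.0
    if sigma2 <= 0:
        return TestReport("wilcoxon_signed_rank", w, 1.0, "degenerate", (n,),
                          extras={"n_zero_dropped": n_zero})
    z = max(0.0, (dev - 0.5) / math.sqrt(sigma2))
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestReport(
        "wilcoxon_signed_rank", w, p, "normal_approx", (n,),
        extras={"n_zero_dropped": n_zero, "z": z},
    )


def paired_t(x, y) -> TestReport:
    """Two-tailed paired t test on the pairwise differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    if n < 2 or np.allclose(d, d.mean(), rtol=1e-9, atol=1e-12):
        # constant differences: zero variance, t undefined
        if np.allclose(d, 0):
            return TestReport("paired_t", 0.0, 1.0, "degenerate", (n,),
                              extras={"degenerate": True})
        return TestReport("paired_t", math.inf * np.sign(d.mean()), 0.0,
                          "degenerate", (n,), extras={"degenerate": True})
    res = sps.ttest_rel(x, y)
    return TestReport("paired_t", float(res.statistic), float(res.pvalue), "t", (n,))


def ratio_paired_t(x, y) -> TestReport:
    """Ratio-paired t test: paired t on log-transformed values.

    Both samples must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("ratio-paired t requires strictly positive values")
    rep = paired_t(np.log(x), np.log(y))
    rep.test_name = "ratio_paired_t"
    return rep


def fisher_exact(table) -> TestReport:
    """Two-tailed Fisher's exact test on a 2x2 contingency table.

    Two-tailed by the point-probability method: sum of hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's.  A zero margin makes the table
    degenerate (p = 1, flagged).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integers")
    t = t.astype(np.int64)
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    N = t.sum()
    odds = math.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c else math.nan)
    if 0 in (r1, r2, c1, c2):
        return TestReport("fisher_exact", odds, 1.0, "degenerate", (int(r1), int(r2)),
                          extras={"degenerate": True, "reason": "zero margin"})
    hg = sps.hypergeom(N, r1, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hg.pmf(ks)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if p > 1.0 - 1e-12:  # every table qualified; exact answer is 1
        p = 1.0
    return TestReport("fisher_exact", odds, min(1.0, p), "exact", (int(r1), int(r2)))


def kruskal_wallis(groups) -> TestReport:
    """Kruskal-Wallis H test with tie correction (chi-square approximation)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start:start + len(g)].sum()
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
    if correction == 0:
        return TestReport("kruskal_wallis", 0.0, 1.0, "degenerate",
                          tuple(len(g) for g in groups), extras={"degenerate": True})
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestReport("kruskal_wallis", h, p, "chi2_approx",
                      tuple(len(g) for g in groups), extras={"df": df})


def dunn_pairwise(groups, labels=None, adjust: str = "bh"):
    """Dunn's z post-hoc pairwise comparisons after Kruskal-Wallis.

    Returns a pandas DataFrame with one row per pair and raw/adjusted
    two-sided p-values.  ``adjust`` is ``"bh"`` (default) or ``"holm"``.
    """
    import pandas as pd

    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        se = math.sqrt((N * (N + 1) / 12.0 - tie_term)
                       * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_value": p})
    df = pd.DataFrame(rows)
    if adjust == "bh":
        df["p_adjusted"] = bh_fdr(df["p_value"].to_numpy())
    elif adjust == "holm":
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        df["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
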