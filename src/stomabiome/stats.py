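"""Shared statistical primitives.

All group comparisons in the pipeline funnel through these functions, so
their behaviour (exact vs asymptotic paths, tie handling, degenerate
inputs) is pinned down here and verified against brute-force oracles in
the test suite.  SciPy provides the numerical back-ends.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_1d(x, name):
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when ``len(a) * len(b) <= 400`` and there are no
    ties across the pooled data; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    exact = no_ties and (a.size * b.size <= 400)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"mann_whitney_{method}")


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    p is the sum of hypergeometric probabilities, over tables with the same
    margins, that do not exceed the observed table's probability (relative
    tie tolerance 1e-12).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    t = np.round(t).astype(int)
    r1, r2 = t.sum(axis=1)
    c1, _ = t.sum(axis=0)
    n = t.sum()
    if n == 0:
        return TestResult(np.nan, 1.0, "fisher_exact", degenerate=True)
    # condition on margins: k = t[0, 0] ~ Hypergeom(n, r1, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(t[0, 0], n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    odds = np.inf if t[0, 1] * t[1, 0] == 0 else (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return TestResult(float(odds), min(p, 1.0), "fisher_exact")


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t test with Satterthwaite df (two-sided)."""
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return TestResult(np.nan, 1.0, "welch_t", degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch_t")


def chi_square(table) -> TestResult:
    """Pearson's chi-squared test of independence, (r-1)(c-1) df, no Yates."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(np.nan, 1.0, "chi_square", degenerate=True)
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), "chi_square")


def benjamini_hochberg(p):
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def cohens_d(a, b) -> float:
    """Cohen's d with (n-1)-weighted pooled SD; sign is mean(a) - mean(b).

    By the pipeline's convention the first argument is the stoma group.
    Returns NaN when the pooled SD is zero (degenerate).
    """
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
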