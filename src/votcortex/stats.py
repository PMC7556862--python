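"""Shared nonparametric statistics used across the analysis modules.

Conventions follow common neurophysiology practice: Spearman correlations
with midrank ties and a t-approximation p-value, Mann-Whitney rank-sum
reported as a tie-corrected normal-approximation z (no continuity
correction), and Wilcoxon signed-rank tests that are exact for small samples
and normal-approximate otherwise.  Bootstrap confidence regions are 95%
highest-density intervals (the shortest contiguous interval covering 95% of
the resampled statistics).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "spearman",
    "correlation_t",
    "mann_whitney_z",
    "RankSumResult",
    "SignedRankResult",
    "signed_rank",
    "hdi",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A rank correlation with its t-statistic and (approximate) p-value."""

    rho: float
    n: int
    t_statistic: float
    p_value: float


def correlation_t(rho: float, n: int) -> float:
    """t = rho * sqrt(n-2) / sqrt(1 - rho^2); +/-inf at |rho| = 1."""
    if np.isnan(rho):
        return np.nan
    if abs(rho) >= 1.0:
        return np.inf * np.sign(rho)
    return rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho**2)


def spearman(x, y, *, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with midrank ties.

    ``method='t'`` (default) computes the p-value from the t-approximation
    with n-2 degrees of freedom; ``method='exact'`` enumerates all
    permutations of one variable (only feasible for n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return CorrelationResult(np.nan, n, np.nan, np.nan)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    t = correlation_t(rho, n)
    if method == "t":
        if np.isinf(t):
            p = 0.0
        else:
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    elif method == "exact":
        if n > 8:
            raise ValueError("exact permutation p-value limited to n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho, n, float(t), p)


@dataclass(frozen=True)
class RankSumResult:
    u: float
    z: float
    p_value: float
    n1: int
    n2: int


def mann_whitney_z(x, y) -> RankSumResult:
    """Mann-Whitney rank-sum z for group ``x`` vs group ``y``.

    U counts, for the first group, pairs won over the second (via the rank
    sum); z is the tie-corrected normal approximation without continuity
    correction, so e.g. [1,2,3] vs [4,5,6] gives U = 0, z = -1.964.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return RankSumResult(float(u1), 0.0, 1.0, n1, n2)
    z = (u1 - mean_u) / np.sqrt(var_u)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return RankSumResult(float(u1), float(z), p, n1, n2)


@dataclass(frozen=True)
class SignedRankResult:
    w_plus: float
    z: float
    p_value: float
    n_used: int
    method: str


def _signed_rank_z(w_plus: float, ranks: np.ndarray) -> float:
    n = len(ranks)
    mean_w = n * (n + 1) / 4.0
    # tie correction on the signed-rank variance
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var_w -= ((counts**3 - counts) / 48.0).sum()
    if var_w <= 0:
        return 0.0
    return (w_plus - mean_w) / np.sqrt(var_w)


def signed_rank(values, mu: float = 0.0) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank test of ``values`` against ``mu``.

    Zeros are dropped.  The null is exact for n <= 25 without tied absolute
    differences (scipy's counting algorithm) and by direct enumeration of
    sign assignments for tied samples up to n = 12; larger samples use the
    tie-corrected normal approximation.  The normal-approximation z is
    reported in every case.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return SignedRankResult(np.nan, np.nan, np.nan, 0, "undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    z = _signed_rank_z(w_plus, ranks)

    has_ties = len(np.unique(ranks)) < n
    if n <= 25 and not has_ties:
        res = sps.wilcoxon(d, method="exact")
        return SignedRankResult(w_plus, z, float(res.pvalue), n, "exact")
    if n <= 12:
        # exact two-sided p by enumerating all 2^n sign assignments
        mean_w = ranks.sum() / 2.0
        obs_dev = abs(w_plus - mean_w) - 1e-12
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            count += abs(w - mean_w) >= obs_dev
        return SignedRankResult(w_plus, z, count / 2**n, n, "exact-ties")
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return SignedRankResult(w_plus, z, p, n, "normal")


def hdi(values, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    if k == n:
        return float(v[0]), float(v[-1])
    widths = v[k - 1 :] - v[: n - k + 1]
    i = int(np.argmin(widths))
    return float(v[i]), float(v[i + k - 1])
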