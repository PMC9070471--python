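"""Rank-based group comparisons with multiplicity adjustment.

Three-group tissue comparisons (false lumen vs flap vs true lumen) use the
Kruskal-Wallis H test followed by Dunn's pairwise z tests on the joint mean
ranks, with Holm step-down adjustment of the pairwise p-values within each
variable.  Two-group comparisons between identified false-lumen clusters
use the Mann-Whitney U test, exact by enumeration at small sample sizes and
normal-approximated (with tie correction) otherwise.  All tests are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    groups: tuple
    n_per_group: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")


def _split_groups(values, group_labels):
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if values.shape != group_labels.shape:
        raise ValueError("values and group_labels must have equal length")
    names = sorted(set(group_labels.tolist()))
    groups = [values[group_labels == g] for g in names]
    for name, g in zip(names, groups):
        if g.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return names, groups


def kruskal_wallis(values, group_labels) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    names, groups = _split_groups(values, group_labels)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in groups) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(np.concatenate(groups)) == 0:
        # all values identical: H = 0 by full tie correction
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*groups)
    return TestResult(
        statistic=float(H),
        p_raw=float(p),
        p_adjusted=float(p),
        method="kruskal-wallis",
        groups=tuple(names),
        n_per_group=tuple(g.size for g in groups),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity by running maximum, cap at 1, restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(adjusted), 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def dunn_posthoc(values, group_labels, adjust: str = "holm") -> list[TestResult]:
    """Dunn's pairwise mean-rank z tests after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    with tie term T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided
    normal p-values, adjusted across the pairwise family (Holm by default).
    """
    names, groups = _split_groups(values, group_labels)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    all_values = np.concatenate(groups)
    N = all_values.size
    ranks = sps.rankdata(all_values)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(all_values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(names)), 2))
    zs, ps = [], []
    for i, j in pairs:
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    if adjust == "holm":
        adj = holm_adjust(ps)
    elif adjust in (None, "none"):
        adj = np.asarray(ps)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        TestResult(
            statistic=float(z),
            p_raw=float(p),
            p_adjusted=float(pa),
            method=f"dunn ({adjust})",
            groups=(names[i], names[j]),
            n_per_group=(sizes[i], sizes[j]),
        )
        for (i, j), z, p, pa in zip(pairs, zs, ps, adj)
    ]


def _exact_mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates all C(n_a + n_b, n_a) splits of the pooled values, computes
    the U statistic of the first group for each, and doubles the smaller
    tail of the permutation distribution (capped at 1).  Valid with ties.
    """
    pooled = np.concatenate([a, b])
    n = pooled.size
    na = a.size
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    count_le = count_ge = 0
    total = comb(n, na)
    for idx in combinations(range(n), na):
        u = float(ranks[list(idx)].sum() - na * (na + 1) / 2.0)
        if u <= u_obs + 1e-9:
            count_le += 1
        if u >= u_obs - 1e-9:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(p, 1.0)


def mann_whitney(values_a, values_b, exact_max_n: int = 8) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Reports U = min(U_a, U_b).  Exact p by full enumeration when both
    groups have at most ``exact_max_n`` observations; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    u_b = na * nb - u_a
    u = min(u_a, u_b)
    if na <= exact_max_n and nb <= exact_max_n:
        p = _exact_mann_whitney_p(a, b)
        method = "mann-whitney (exact)"
    else:
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = na + nb
        tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * ((n + 1) - tie_corr)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_a - na * nb / 2.0) - 0.5) / np.sqrt(sigma2)
            p = 2.0 * sps.norm.sf(max(z, 0.0))
        p = min(p, 1.0)
        method = "mann-whitney (normal approx)"
    return TestResult(
        statistic=float(u),
        p_raw=float(p),
        p_adjusted=float(p),
        method=method,
        groups=("a", "b"),
        n_per_group=(na, nb),
    )
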