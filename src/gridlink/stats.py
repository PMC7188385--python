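"""Nonparametric group comparison and correlation pipeline.

Kruskal-Wallis omnibus tests (tie-corrected H, chi-square
approximation) with a mean-rank multiple-comparison post hoc, Spearman
rank correlations, first-order partial Spearman correlations
controlling for a covariate, and the pooled difficulty-vs-solving-time
rank correlation. Ties take average ranks throughout; all procedures
are invariant under strictly monotone transformations of the inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    def __init__(self, label: str, values: Sequence[float]):
        if len(values) < 1:
            raise StatsError(f"group {label!r} needs at least one observation")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", tuple(float(v) for v in values))


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    rank_diff: float  # |mean rank i - mean rank j|
    critical: float  # critical difference at the familywise alpha
    significant: bool
    p_adj: float  # adjusted p, capped at 1.000


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def _pooled_ranks(samples: Sequence[GroupSample]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate([s.values for s in samples])
    ranks = sps.rankdata(pooled)  # average ranks for ties
    out, i = [], 0
    for s in samples:
        out.append(ranks[i : i + len(s.values)])
        i += len(s.values)
    return ranks, out


def kruskal_wallis(samples: Sequence[GroupSample]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with k-1 df chi-square p-value.

    All observations identical is degenerate, not an error: H = 0,
    p = 1.
    """
    if len(samples) < 2:
        raise StatsError("need at least two groups")
    pooled = np.concatenate([s.values for s in samples])
    n_total = len(pooled)
    if n_total < 3:
        raise StatsError("need at least three observations in total")
    df = len(samples) - 1
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, df=df, p_value=1.0)
    ranks, group_ranks = _pooled_ranks(samples)
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        len(r) * (r.mean() - (n_total + 1) / 2.0) ** 2 for r in group_ranks
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    h /= tie_term
    return TestResult(statistic=float(h), df=df, p_value=float(sps.chi2.sf(h, df)))


def posthoc_pairwise(samples: Sequence[GroupSample], alpha: float = 0.05) -> TestResult:
    """Mean-rank multiple comparisons after a Kruskal-Wallis omnibus.

    Each pair's observed mean-rank difference is compared with a
    critical difference at familywise ``alpha`` (normal approximation,
    Bonferroni-style correction over the k*(k-1)/2 pairs); adjusted
    p-values are capped at 1.000.
    """
    if len(samples) < 2:
        raise StatsError("post hoc comparison needs at least two groups")
    result = kruskal_wallis(samples)
    _, group_ranks = _pooled_ranks(samples)
    n_total = sum(len(s.values) for s in samples)
    k = len(samples)
    n_pairs = k * (k - 1) // 2
    z_crit = float(sps.norm.ppf(1.0 - alpha / (k * (k - 1))))
    for i in range(k):
        for j in range(i + 1, k):
            ri, rj = group_ranks[i], group_ranks[j]
            diff = abs(float(ri.mean() - rj.mean()))
            se = np.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / len(ri) + 1.0 / len(rj)))
            critical = z_crit * se
            p_adj = min(1.0, 2.0 * float(sps.norm.sf(diff / se)) * n_pairs) if se > 0 else 1.0
            result.pairwise.append(
                PairwiseComparison(
                    samples[i].label,
                    samples[j].label,
                    rank_diff=diff,
                    critical=float(critical),
                    significant=bool(diff > critical),
                    p_adj=p_adj,
                )
            )
    return result


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks; t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("spearman needs two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input vector: Spearman rho undefined")
        return (float("nan"), float("nan"))
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float]:
    """First-order partial Spearman correlation controlling a covariate.

    rho_xy.z = (rho_xy - rho_xz * rho_yz) / sqrt((1 - rho_xz^2) *
    (1 - rho_yz^2)) on the Spearman correlations; p from a
    t-approximation with n - 3 degrees of freedom. A constant covariate
    falls back to the simple correlation (with a warning); a covariate
    perfectly correlated with x or y leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise StatsError("partial_spearman needs three equal-length vectors with n >= 4")
    if np.all(z == z[0]):
        warnings.warn("constant covariate: falling back to simple Spearman correlation")
        return spearman(x, y)
    r_xy, _ = spearman(x, y)
    r_xz, _ = spearman(x, z)
    r_yz, _ = spearman(y, z)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-12:
        warnings.warn("covariate perfectly correlated with x or y: partial rho undefined")
        return (float("nan"), float("nan"))
    rho = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    n = len(x)
    df = n - 3
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return rho, p


def difficulty_time_correlation(
    records: Sequence[tuple[str, int, float]],
    min_points: int = 3,
) -> dict[str, tuple[float, float, int]]:
    """Per-group Spearman correlation of difficulty rank vs. TST.

    ``records`` holds (group, level_rank, tst) tuples pooled over the
    participants of each group; unsolved levels (tst None/NaN) are
    excluded, and groups with fewer than ``min_points`` usable points
    are skipped with a warning.
    """
    by_group: dict[str, list[tuple[int, float]]] = {}
    for group, rank, tst in records:
        if tst is None or (isinstance(tst, float) and np.isnan(tst)):
            continue
        by_group.setdefault(group, []).append((rank, tst))
    out: dict[str, tuple[float, float, int]] = {}
    for group, pts in by_group.items():
        if len(pts) < min_points:
            warnings.warn(f"group {group!r}: fewer than {min_points} points, skipped")
            continue
        ranks = [r for r, _ in pts]
        tsts = [t for _, t in pts]
        rho, p = spearman(ranks, tsts)
        out[group] = (rho, p, len(pts))
    return out
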