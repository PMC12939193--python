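"""Two-group inference on fractional occupancy.

Per state: an unpaired two-sided label-permutation test on scan-level FO
values (difference of group means as the statistic), Hedges' g with the
small-sample bias correction, and a three-tier multiple-comparison
classification against the nominal, within-K Bonferroni, and global
Bonferroni thresholds (the global family is every state of every K, 209
states for K = 2..20).

The permutation test permutes scan-level group labels.  When the number of
distinct relabelings C(n_a + n_b, n_a) does not exceed the permutation
budget the test enumerates them exhaustively and reports the exact p;
otherwise it Monte-Carlo samples relabelings and reports the add-one
smoothed estimate (1 + b) / (1 + n_perm), which can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .metrics import StateOccupancyTable
from ._seeds import derive_seed

__all__ = [
    "GroupComparison",
    "permutation_pvalue",
    "hedges_g",
    "significance_tier",
    "compare_all_states",
    "percent_change",
]

#: Tolerance when comparing permuted |statistics| against the observed one,
#: so exact ties are counted as ties despite float round-off.
_TIE_TOL = 1e-12

TIERS = ("global", "within_K", "nominal", "ns")


@dataclass
class GroupComparison:
    """One state's group contrast: FO means, permutation p, effect size, tier."""

    K: int
    state: int
    mean_FO_A: float
    mean_FO_B: float
    diff: float
    p_perm: float
    n_permutations: int
    hedges_g: float
    g_CI: tuple[float, float]
    tier: str


def permutation_pvalue(
    a: np.ndarray, b: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> float:
    """Two-sided label-permutation p-value for mean(a) - mean(b).

    Exhaustive when C(|a|+|b|, |a|) <= n_perm (exact proportion of
    relabelings with |stat| >= |observed|, the observed split included);
    Monte-Carlo with add-one smoothing otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    obs = abs(a.mean() - b.mean())
    total_sum = pooled.sum()

    def diff_from_group_a_sum(sum_a: np.ndarray) -> np.ndarray:
        return sum_a / n_a - (total_sum - sum_a) / (n - n_a)

    if comb(n, n_a) <= n_perm:
        sums = np.fromiter(
            (pooled[list(idx)].sum() for idx in combinations(range(n), n_a)),
            dtype=float,
        )
        stats = np.abs(diff_from_group_a_sum(sums))
        return float(np.count_nonzero(stats >= obs - _TIE_TOL) / stats.size)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    stats = np.abs(diff_from_group_a_sum(perms[:, :n_a].sum(axis=1)))
    exceed = int(np.count_nonzero(stats >= obs - _TIE_TOL))
    return (1 + exceed) / (1 + n_perm)


def hedges_g(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Bias-corrected standardized mean difference with a 95% CI.

    ``g = J (mean_a - mean_b) / s_pooled`` with ``J = 1 - 3/(4 n - 9)``,
    ``n = n_a + n_b``, ``s_pooled`` the pooled standard deviation.  The CI
    is the normal approximation ``g +/- 1.96 sqrt(n/(n_a n_b) + g^2/(2 n))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValidationError("Hedges' g needs at least 2 values per group")
    n = n_a + n_b
    diff = a.mean() - b.mean()
    s2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n - 2)
    if s2 <= 0:
        if diff == 0:
            g = 0.0
        else:
            raise ValidationError(
                "zero pooled variance with unequal means: effect size infinite"
            )
    else:
        J = 1.0 - 3.0 / (4.0 * n - 9.0)
        g = J * diff / np.sqrt(s2)
    se = np.sqrt(n / (n_a * n_b) + g**2 / (2.0 * n))
    return float(g), (float(g - 1.96 * se), float(g + 1.96 * se))


def significance_tier(
    p: float, K: int, total_states: int = 209, alpha: float = 0.05
) -> str:
    """Classify a p-value against the three Bonferroni tiers.

    ``global`` : p < alpha / total_states (survives correction over every
    state of every K); ``within_K`` : p < alpha / K; ``nominal`` : p <
    alpha; ``ns`` otherwise.
    """
    if not (0.0 < p <= 1.0):
        raise ValidationError("p must be in (0, 1]")
    if K < 2:
        raise ValidationError("K must be >= 2")
    if p < alpha / total_states:
        return "global"
    if p < alpha / K:
        return "within_K"
    if p < alpha:
        return "nominal"
    return "ns"


def percent_change(baseline_mean: float, other_mean: float) -> float:
    """Percent change of ``other_mean`` relative to ``baseline_mean``."""
    if baseline_mean == 0:
        raise ValidationError("baseline mean must be non-zero")
    return 100.0 * (other_mean - baseline_mean) / baseline_mean


def compare_all_states(
    fo_tables: dict[int, StateOccupancyTable],
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Group contrast for every state of every K in the pyramid.

    ``diff = mean_FO_A - mean_FO_B`` where (A, B) follow ``group_order``
    (sorted unique labels by default).  Each state gets an independent
    permutation stream derived from ``(seed, K, state)``.  The global
    Bonferroni family size is the total number of states across all K.

    Returns a DataFrame with one row per (K, state): K, state, mean_FO_A,
    mean_FO_B, diff, p, g, g_lo, g_hi, tier.
    """
    if not fo_tables:
        raise ValidationError("no FO tables given")
    total_states = sum(fo_tables)
    rows = []
    for K in sorted(fo_tables):
        table = fo_tables[K]
        groups = np.asarray(table.groups)
        uniq = sorted(set(table.groups))
        if len(uniq) != 2:
            raise ValidationError(f"need exactly 2 groups, found {uniq}")
        ga, gb = group_order if group_order is not None else (uniq[0], uniq[1])
        mask_a = groups == ga
        mask_b = groups == gb
        if not mask_a.any() or not mask_b.any():
            raise ValidationError(f"group_order {ga, gb} not present in tables")
        for state in range(1, K + 1):
            fo = table.FO[:, state - 1]
            a, b = fo[mask_a], fo[mask_b]
            p = permutation_pvalue(
                a, b, n_perm=n_perm, seed=derive_seed(seed, "perm", K, state)
            )
            g, (g_lo, g_hi) = hedges_g(a, b)
            rows.append(
                {
                    "K": K,
                    "state": state,
                    "mean_FO_A": a.mean(),
                    "mean_FO_B": b.mean(),
                    "diff": a.mean() - b.mean(),
                    "p": p,
                    "g": g,
                    "g_lo": g_lo,
                    "g_hi": g_hi,
                    "tier": significance_tier(p, K, total_states, alpha),
                }
            )
    return pd.DataFrame(rows)
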