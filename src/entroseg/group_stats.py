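"""Group-comparison statistics for per-image quantification scores.

One-way ANOVA with the classical between/within sum-of-squares
decomposition, followed by pairwise post-hoc comparisons:

* LSD (least significant difference): unadjusted two-sided t tests on
  each pair, using the pooled within-group mean square and its degrees
  of freedom.
* Tukey HSD: the same pairwise differences referred to the studentized
  range distribution with ``k`` groups, which controls the family-wise
  error rate.  Unbalanced designs use the Tukey-Kramer standard error.

Pairwise standard errors are ``sqrt(ms_within * (1/n_i + 1/n_j))``; the
Tukey statistic divides by the same quantity over ``sqrt(2)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaTable",
    "PairwiseComparison",
    "one_way_anova",
    "anova_from_sums",
    "lsd_comparisons",
    "tukey_comparisons",
    "multiple_comparisons",
    "format_p",
]


@dataclass(frozen=True)
class AnovaTable:
    """One-way ANOVA decomposition (between / within / total)."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_statistic: float
    p_value: float
    degenerate: bool = False  # zero within-group variance: F undefined

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


@dataclass(frozen=True)
class PairwiseComparison:
    """One pair's mean difference with LSD and/or Tukey p-values."""

    group_i: str
    group_j: str
    mean_diff: float
    std_error: float
    p_lsd: float | None = None
    p_tukey: float | None = None


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    out: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError(f"group {name!r} is empty")
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite scores")
        out[str(name)] = arr
    return out


def anova_from_sums(
    ss_between: float, df_between: int, ss_within: float, df_within: int
) -> AnovaTable:
    """Complete an ANOVA table from its sums of squares and df."""
    if df_between < 1 or df_within < 1:
        raise ValueError("degrees of freedom must be positive")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    if ms_w <= 0:
        return AnovaTable(
            ss_between, ss_within, df_between, df_within,
            ms_b, ms_w, float("nan"), float("nan"), degenerate=True,
        )
    f = ms_b / ms_w
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaTable(ss_between, ss_within, df_between, df_within, ms_b, ms_w, f, p)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaTable:
    """Between/within decomposition and F test over labelled score groups.

    Requires residual degrees of freedom (``N > k``); a design with one
    observation per group has none and raises.
    """
    data = _validate_groups(groups)
    k = len(data)
    n_total = sum(a.size for a in data.values())
    if n_total <= k:
        raise ValueError("no residual degrees of freedom (need N > k)")
    grand = np.concatenate(list(data.values())).mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in data.values()))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in data.values()))
    return anova_from_sums(ss_between, k - 1, ss_within, n_total - k)


def pairwise_std_error(ms_within: float, n_i: int, n_j: int) -> float:
    """Standard error of a pairwise mean difference from the pooled MS."""
    return float(np.sqrt(ms_within * (1.0 / n_i + 1.0 / n_j)))


def _pairs(data: dict[str, np.ndarray]):
    for (ni, ai), (nj, aj) in itertools.combinations(data.items(), 2):
        yield ni, ai, nj, aj


def lsd_comparisons(
    groups: Mapping[str, Sequence[float]],
    ms_within: float,
    df_within: int,
) -> list[PairwiseComparison]:
    """Unadjusted pairwise t tests (LSD) using the pooled within MS."""
    if ms_within <= 0:
        raise ValueError("ms_within must be positive")
    data = _validate_groups(groups)
    out = []
    for ni, ai, nj, aj in _pairs(data):
        diff = float(ai.mean() - aj.mean())
        se = pairwise_std_error(ms_within, ai.size, aj.size)
        t = abs(diff) / se
        p = float(2.0 * stats.t.sf(t, df_within))
        out.append(PairwiseComparison(ni, nj, diff, se, p_lsd=p))
    return out


def tukey_comparisons(
    groups: Mapping[str, Sequence[float]],
    ms_within: float,
    df_within: int,
) -> list[PairwiseComparison]:
    """Tukey HSD pairwise comparisons via the studentized range tail.

    ``q = |diff| / sqrt(ms_within/2 * (1/n_i + 1/n_j))`` (Tukey-Kramer
    for unequal sizes); ``p = P(Q_{k, df} > q)``.
    """
    if ms_within <= 0:
        raise ValueError("ms_within must be positive")
    data = _validate_groups(groups)
    k = len(data)
    out = []
    for ni, ai, nj, aj in _pairs(data):
        diff = float(ai.mean() - aj.mean())
        se = pairwise_std_error(ms_within, ai.size, aj.size)
        q = abs(diff) / (se / np.sqrt(2.0))
        p = float(stats.studentized_range.sf(q, k, df_within))
        out.append(PairwiseComparison(ni, nj, diff, se, p_tukey=min(p, 1.0)))
    return out


def multiple_comparisons(
    groups: Mapping[str, Sequence[float]],
) -> tuple[AnovaTable, list[PairwiseComparison]]:
    """ANOVA plus merged LSD and Tukey p-values for every pair."""
    table = one_way_anova(groups)
    if table.degenerate:
        raise ValueError("zero within-group variance; post-hoc tests undefined")
    lsd = lsd_comparisons(groups, table.ms_within, table.df_within)
    tukey = tukey_comparisons(groups, table.ms_within, table.df_within)
    merged = [replace(a, p_tukey=b.p_tukey) for a, b in zip(lsd, tukey)]
    return table, merged


def format_p(p: float, decimals: int = 3) -> str:
    """Render a p-value the way stats packages print post-hoc tables."""
    if not np.isfinite(p):
        return "nan"
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"< {floor:.{decimals}f}"
    return f"{p:.{decimals}f}"
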