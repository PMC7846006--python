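"""Cohort statistics on hot-spot carrier status.

Carrier status is presence/absence of the heteroplasmy in a subject (its
frequency plays no role).  For each SNP and pair of groups a 2x2 table
(carriers / non-carriers) yields the cross-product odds ratio and a
two-sided Fisher exact p-value.

Numerical conventions, stated because implementations differ:

* the two-sided Fisher p is the point-probability method — the sum of
  hypergeometric probabilities of all tables with the observed margins whose
  point probability does not exceed the observed one (with the customary
  1 + 1e-7 relative tolerance on the comparison); it is accumulated in
  log-space;
* the odds ratio is the raw cross-product (a*d)/(b*c) with no
  continuity/Haldane correction — a zero cross-cell raises
  :class:`UndefinedStatisticError` instead of being silently corrected;
* no multiple-testing adjustment is applied by default; an optional
  Benjamini-Hochberg flag is available on :func:`compare_groups`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

SnpKey = tuple[int, str, str]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """(group1 carriers, group1 non-carriers, group2 carriers, group2 non-carriers)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")


@dataclass
class CohortPresence:
    """Per-group sizes and per-(group, SNP) carrier counts."""

    groups: dict[str, int]
    carriers: dict[tuple[str, SnpKey], int]

    def __post_init__(self) -> None:
        for (group, snp), k in self.carriers.items():
            if group not in self.groups:
                raise ValidationError(f"carrier count for unknown group {group!r}")
            if not 0 <= k <= self.groups[group]:
                raise ValidationError(
                    f"carriers {k} outside 0..{self.groups[group]} for {group}/{snp}"
                )

    def table(self, snp: SnpKey, group1: str, group2: str) -> ContingencyTable2x2:
        for g in (group1, group2):
            if g not in self.groups:
                raise ValidationError(f"unknown group {g!r}")
        a = self.carriers.get((group1, snp), 0)
        c = self.carriers.get((group2, snp), 0)
        return ContingencyTable2x2(a, self.groups[group1] - a, c, self.groups[group2] - c)


@dataclass(frozen=True)
class GroupComparison:
    """OR and Fisher p for one SNP and one group pair."""

    snp: SnpKey
    group_pair: tuple[str, str]
    odds_ratio: float | None  # None when a cross-cell is zero
    p_two_sided: float
    table: ContingencyTable2x2
    p_adjusted: float | None = None


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Cross-product odds ratio (a*d)/(b*c), unrounded."""
    if t.b == 0 or t.c == 0:
        raise UndefinedStatisticError(
            f"odds ratio undefined for zero cross-cell in {t} (no continuity correction)"
        )
    return (t.a * t.d) / (t.b * t.c)


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the point-probability method, in log-space."""
    row1 = t.a + t.b
    col1 = t.a + t.c
    n = t.a + t.b + t.c + t.d
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0  # degenerate margins: only one table is possible
    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    log_pmf = stats.hypergeom.logpmf(support, n, row1, col1)
    log_obs = log_pmf[support == t.a][0]
    include = log_pmf <= log_obs + math.log1p(1e-7)
    # log-sum-exp over the included tables
    m = np.max(log_pmf[include])
    p = math.exp(m) * float(np.sum(np.exp(log_pmf[include] - m)))
    return min(1.0, p)


def compare_groups(
    cohort: CohortPresence,
    snps: list[SnpKey],
    group_pairs: list[tuple[str, str]],
    adjust: bool = False,
) -> list[GroupComparison]:
    """One comparison per (SNP, group pair); zero-cross-cell ORs become None.

    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values across all
    comparisons made in this call (off by default).
    """
    out: list[GroupComparison] = []
    for snp in snps:
        for g1, g2 in group_pairs:
            t = cohort.table(snp, g1, g2)
            try:
                or_ = odds_ratio(t)
            except UndefinedStatisticError:
                or_ = None
            out.append(
                GroupComparison(
                    snp=snp,
                    group_pair=(g1, g2),
                    odds_ratio=or_,
                    p_two_sided=fisher_exact_two_sided(t),
                    table=t,
                )
            )
    if adjust and out:
        ps = np.array([c.p_two_sided for c in out])
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, ps[idx] * m / rank)
            adj[idx] = running
        out = [
            GroupComparison(
                snp=c.snp,
                group_pair=c.group_pair,
                odds_ratio=c.odds_ratio,
                p_two_sided=c.p_two_sided,
                table=c.table,
                p_adjusted=float(adj[i]),
            )
            for i, c in enumerate(out)
        ]
    return out


def tissue_count_ttest(counts_x, counts_y) -> float:
    """Two-tailed paired t-test p-value on per-subject count vectors."""
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and of equal length")
    if len(x) < 2:
        raise UndefinedStatisticError("paired t-test needs at least two pairs")
    if np.var(x - y) == 0:
        raise UndefinedStatisticError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.pvalue)
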