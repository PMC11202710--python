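"""One-way ANOVA, Tukey HSD and compact-letter displays.

All reporting modules funnel their group comparisons through this module.
The ANOVA runs from summary statistics (label, n, mean, sd) because the
published tables expose only those; raw data are first reduced to the same
summaries, which makes the two entry points agree exactly.

Tukey's HSD is computed from the studentized-range distribution, uniformly
for any number of groups (with two groups it reduces to the pooled-variance
two-sample comparison via q = t*sqrt(2)). Pairwise significances are
summarized as compact letters: groups share a letter if and only if they
are not significantly different.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "GroupSummary",
    "TukeyResult",
    "anova_oneway",
    "compact_letters",
    "tukey_hsd",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary statistics: labels with (n, mean, sd)."""

    labels: tuple[str, ...]
    ns: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.ns) == len(self.means) == len(self.sds) == k):
            raise ValueError("labels, ns, means, sds must have equal length")
        if k < 2:
            raise ValueError("need at least 2 groups")
        if any(n < 1 for n in self.ns):
            raise ValueError("group sizes must be >= 1")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be >= 0")

    @classmethod
    def from_raw(cls, groups: Mapping[str, Sequence[float]]) -> "GroupSummary":
        """Summarize raw per-group observations (sd with ddof=1)."""
        labels, ns, means, sds = [], [], [], []
        for label, values in groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size < 1:
                raise ValueError(f"group {label!r} is empty")
            labels.append(str(label))
            ns.append(int(arr.size))
            means.append(float(arr.mean()))
            sds.append(float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        return cls(tuple(labels), tuple(ns), tuple(means), tuple(sds))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    undefined: bool = False  # all sds zero and means equal: no test possible


def _as_summary(data: GroupSummary | Mapping[str, Sequence[float]]) -> GroupSummary:
    return data if isinstance(data, GroupSummary) else GroupSummary.from_raw(data)


def anova_oneway(data: GroupSummary | Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from summaries or raw data.

    Between/within sums of squares are reconstructed from the summaries:
    SSB = sum n_i (mean_i - grand)^2, SSW = sum (n_i - 1) sd_i^2. The
    p-value is exact from the F distribution. When every sd is zero the
    within-group mean square vanishes: with unequal means F is infinite
    (p = 0); with equal means the test is undefined and flagged.
    """
    s = _as_summary(data)
    ns = np.asarray(s.ns, dtype=float)
    means = np.asarray(s.means, dtype=float)
    sds = np.asarray(s.sds, dtype=float)
    n_total = ns.sum()
    k = len(s.labels)
    df1 = k - 1
    df2 = int(n_total) - k
    if df2 < 1:
        raise ValueError("need total residual degrees of freedom >= 1 (more replication)")
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(F=math.nan, df1=df1, df2=df2, p=math.nan, undefined=True)
        return AnovaResult(F=math.inf, df1=df1, df2=df2, p=0.0)
    f_stat = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    return AnovaResult(F=f_stat, df1=df1, df2=df2, p=p)


@dataclass
class TukeyResult:
    labels: tuple[str, ...]
    q: dict[tuple[str, str], float]
    p_adj: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    alpha: float

    def significance_matrix(self) -> np.ndarray:
        """Symmetric boolean matrix in label order (True = significant)."""
        k = len(self.labels)
        m = np.zeros((k, k), dtype=bool)
        for (a, b), sig in self.significant.items():
            i, j = self.labels.index(a), self.labels.index(b)
            m[i, j] = m[j, i] = sig
        return m


def tukey_hsd(
    data: GroupSummary | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey HSD pairwise comparisons from summaries or raw data.

    The studentized-range statistic for a pair is
    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))
    (the Tukey–Kramer form for unequal n), with the adjusted p-value from
    the studentized-range distribution at k groups and the ANOVA residual
    degrees of freedom. With zero pooled variance, unequal means are
    reported as p = 0 and equal means as p = 1.
    """
    s = _as_summary(data)
    anova = anova_oneway(s)
    k = len(s.labels)
    ns = np.asarray(s.ns, dtype=float)
    sds = np.asarray(s.sds, dtype=float)
    msw = float(((ns - 1) * sds**2).sum()) / anova.df2

    q: dict[tuple[str, str], float] = {}
    p_adj: dict[tuple[str, str], float] = {}
    significant: dict[tuple[str, str], bool] = {}
    for i, j in itertools.combinations(range(k), 2):
        pair = (s.labels[i], s.labels[j])
        diff = abs(s.means[i] - s.means[j])
        if msw == 0.0:
            q[pair] = math.inf if diff > 0 else 0.0
            p_adj[pair] = 0.0 if diff > 0 else 1.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q[pair] = diff / se
            p_adj[pair] = float(sps.studentized_range.sf(q[pair], k, anova.df2))
        significant[pair] = p_adj[pair] <= alpha
    return TukeyResult(labels=s.labels, q=q, p_adj=p_adj, significant=significant, alpha=alpha)


def compact_letters(
    significant: np.ndarray | Mapping[tuple[str, str], bool],
    labels: Sequence[str] | None = None,
    means: Sequence[float] | None = None,
) -> dict[str, str]:
    """Compact-letter display by insert-and-absorb.

    Input is a symmetric pairwise significance matrix (or pair dict).
    Guarantee: two groups share at least one letter iff their difference is
    NOT significant. Letters are assigned in descending-mean order when
    means are given (the best group gets "a"), else in label order.
    """
    if isinstance(significant, Mapping):
        if labels is None:
            labels = sorted({g for pair in significant for g in pair})
        k = len(labels)
        sig = np.zeros((k, k), dtype=bool)
        for (a, b), flag in significant.items():
            i, j = labels.index(a), labels.index(b)
            sig[i, j] = sig[j, i] = bool(flag)
    else:
        sig = np.asarray(significant, dtype=bool)
        if sig.shape[0] != sig.shape[1] or not np.array_equal(sig, sig.T):
            raise ValueError("significance matrix must be square and symmetric")
        if labels is None:
            labels = [str(i) for i in range(sig.shape[0])]
    k = len(labels)
    order = list(range(k))
    if means is not None:
        order = sorted(order, key=lambda i: -means[i])

    # Insert-and-absorb: start with one column holding every group; for each
    # significant pair occupying a shared column, split that column so the
    # pair separates; drop columns that become subsets of others.
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        columns = [
            c for c in columns if not any(c < other for other in columns)
        ]
        # dedupe exact duplicates
        unique: list[set[int]] = []
        for c in columns:
            if c not in unique:
                unique.append(c)
        columns = unique

    # Order columns by the best-ranked member so "a" goes to the top group.
    rank = {g: pos for pos, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[int, list[str]] = {g: [] for g in range(k)}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    return {labels[g]: "".join(sorted(letters[g])) for g in range(k)}
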