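"""Nonparametric group-comparison tests and significance annotation.

Implements the statistical layer used to compare focus-mobility and
nuclear-metric distributions between cell types:

* :func:`steel_dwass` — rank-based all-pairs multiple comparison
  (nonparametric analogue of Tukey's HSD).
* :func:`steel_control` — rank-based many-to-one comparison of every
  treatment group against a single control group (Dunnett-type).
* :func:`pearson` / :func:`student_t` — the parametric companions used
  by the genomics arm.
* :func:`annotate_stars` — conventional significance stars.

Both Steel variants compute, for each comparison, a Wilcoxon rank-sum
statistic on the two groups alone (mid-ranks for ties), standardized with
the tie-corrected variance

    V = n1*n2 / (N*(N-1)) * (sum(r_i^2) - N*(N+1)^2/4),

and refer it to a multiplicity-adjusted reference distribution: the
studentized range (k groups, infinite df, statistic scaled by sqrt(2)) for
the all-pairs procedure, and a multivariate-normal many-to-one maximum for
the control procedure.  For small samples an exact permutation distribution
of the pairwise rank statistic replaces the asymptotic reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupData",
    "TestResult",
    "annotate_stars",
    "steel_dwass",
    "steel_control",
    "pearson",
    "student_t",
]

# combinations(N, n) at or below this bound trigger the exact permutation
# branch of the rank tests
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class GroupData:
    """Labelled numeric samples for a multi-group comparison."""

    labels: list[str]
    samples: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.samples):
            raise ValueError("labels and samples must have equal length")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        for lab, s in zip(self.labels, self.samples):
            if s.ndim != 1 or s.size < 2:
                raise ValueError(f"group {lab!r} needs >=2 one-dimensional values")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"group {lab!r} contains non-finite values")

    @classmethod
    def from_dict(cls, groups: dict[str, Sequence[float]]) -> "GroupData":
        return cls(list(groups.keys()), [np.asarray(v, float) for v in groups.values()])


@dataclass
class TestResult:
    """One pairwise comparison: standardized statistic, p-value, stars."""

    comparison: tuple[str, str]
    statistic: float
    p: float
    stars: str = field(default="")

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = annotate_stars(self.p)


def annotate_stars(p: float) -> str:
    """Map a p-value to the conventional significance labels.

    ``***`` for p < 0.001, ``**`` for p < 0.01, ``*`` for p < 0.05 and
    ``N.S.`` (not significant) otherwise.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def _rank_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized tie-corrected two-sample rank-sum statistic.

    Positive when group ``a`` tends to larger values.  Returns 0 when all
    pooled values are tied (zero variance).
    """
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    n = na + nb
    ranks = stats.rankdata(pooled)
    r_a = ranks[:na].sum()
    expect = na * (n + 1) / 2.0
    var = na * nb / (n * (n - 1.0)) * (np.sum(ranks**2) - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0.0:
        return 0.0
    return float((r_a - expect) / math.sqrt(var))


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p of the pairwise rank-sum statistic.

    Enumerates all assignments of the pooled values to the two groups;
    ties handled by mid-ranks (the rank vector is a permutation invariant,
    so |R_a - E| orders assignments identically to |T|).
    """
    na = len(a)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    expect = na * (n + 1) / 2.0
    obs = abs(ranks[:na].sum() - expect)
    hits = 0
    total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - expect) >= obs - 1e-12:
            hits += 1
    return hits / total


def steel_dwass(
    data: GroupData | dict[str, Sequence[float]],
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> list[TestResult]:
    """All-pairs rank comparison with studentized-range reference.

    For each unordered pair of groups the tie-corrected standardized
    rank-sum statistic ``t`` is computed on that pair alone, and the
    two-sided p-value is ``P(Q >= |t|*sqrt(2))`` where ``Q`` follows the
    studentized range distribution with ``k`` groups and infinite degrees
    of freedom.  When the pair is small enough to enumerate
    (``C(n1+n2, n1) <= exact_limit``) an exact permutation p-value of the
    pairwise statistic is reported instead (without the studentized-range
    multiplicity adjustment; documented limitation for tiny samples).
    """
    if isinstance(data, dict):
        data = GroupData.from_dict(data)
    k = len(data.labels)
    results: list[TestResult] = []
    for (i, j) in combinations(range(k), 2):
        a, b = data.samples[i], data.samples[j]
        t = _rank_statistic(a, b)
        if math.comb(len(a) + len(b), len(a)) <= exact_limit:
            p = _exact_ranksum_p(a, b)
        else:
            p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, np.inf))
        p = min(max(p, 0.0), 1.0)
        results.append(TestResult((data.labels[i], data.labels[j]), t, p))
    return results


def _manyone_correlation(n_control: int, n_treat: Sequence[int]) -> np.ndarray:
    """Correlation matrix of the many-to-one rank statistics.

    rho_ij = sqrt(n_i * n_j / ((n_i + n0) * (n_j + n0))); equals 0.5 for
    equal group sizes.
    """
    n = np.asarray(n_treat, dtype=float)
    denom = n + n_control
    rho = np.sqrt(np.outer(n, n) / np.outer(denom, denom))
    np.fill_diagonal(rho, 1.0)
    return rho


def _manyone_sf(c: float, corr: np.ndarray) -> float:
    """P(max_j |Z_j| >= c) for Z ~ MVN(0, corr)."""
    m = corr.shape[0]
    if m == 1:
        return 2.0 * stats.norm.sf(c)
    inside = stats.multivariate_normal.cdf(
        np.full(m, c), mean=np.zeros(m), cov=corr, lower_limit=np.full(m, -c)
    )
    return float(min(max(1.0 - inside, 0.0), 1.0))


def steel_control(
    data: GroupData | dict[str, Sequence[float]],
    control: str,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> list[TestResult]:
    """Many-to-one rank comparison of every treatment against a control.

    Each treatment is ranked jointly with the control group only; the
    standardized statistics are referred to the maximum of a correlated
    multivariate normal (pairwise correlation from group sizes), two-sided.
    With a single small treatment group the exact permutation p-value of
    the rank-sum statistic is used instead.
    """
    if isinstance(data, dict):
        data = GroupData.from_dict(data)
    if control not in data.labels:
        raise ValueError(f"control group {control!r} not found in {data.labels}")
    ctrl_idx = data.labels.index(control)
    ctrl = data.samples[ctrl_idx]
    treat_idx = [i for i in range(len(data.labels)) if i != ctrl_idx]
    if not treat_idx:
        raise ValueError("need at least one treatment group")
    corr = _manyone_correlation(len(ctrl), [len(data.samples[i]) for i in treat_idx])
    results = []
    for pos, i in enumerate(treat_idx):
        treat = data.samples[i]
        t = _rank_statistic(treat, ctrl)
        single_small = len(treat_idx) == 1 and math.comb(
            len(treat) + len(ctrl), len(treat)
        ) <= exact_limit
        if single_small:
            p = _exact_ranksum_p(treat, ctrl)
        else:
            p = _manyone_sf(abs(t), corr)
        results.append(TestResult((data.labels[i], control), t, p))
    return results


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional with equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def student_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t test, two-sided.

    Returns ``(t, p)``.  Identical degenerate samples (zero pooled variance,
    zero mean difference) give ``(0.0, 1.0)``; zero pooled variance with a
    nonzero mean difference is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
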