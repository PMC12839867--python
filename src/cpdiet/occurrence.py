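"""Occurrence statistics: regional summaries, nonparametric tests, correlation.

Regional comparisons use the Kruskal-Wallis H test and pairwise two-sample
Wilcoxon rank-sum (Mann-Whitney) tests with Benjamini-Hochberg FDR
adjustment; SCCP/MCCP association uses Pearson or Spearman correlation with
a Fisher-z 95% confidence interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .dataio import (
    AnalyteClass,
    AnalyteConstants,
    ConcentrationRecord,
    DEFAULT_CONSTANTS,
)

__all__ = [
    "RegionSummary",
    "TestResult",
    "CorrelationResult",
    "summarize_regions",
    "pooled_mean",
    "kruskal_wallis",
    "kruskal_wallis_exact_p",
    "pairwise_wilcoxon_bh",
    "bh_adjust",
    "correlation_with_ci",
]


@dataclass(frozen=True)
class RegionSummary:
    """Descriptive statistics of class-total concentrations in one region."""

    region: str
    analyte_class: AnalyteClass
    n: int
    n_detected: int
    detection_rate: float
    mean: float    # ng/g ww
    sd: float
    min: float
    max: float
    sd_undefined: bool = False  # single observation: sd reported as 0, flagged

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"{self.region}/{self.analyte_class.value}: min <= mean <= max violated"
            )
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in [0, 1]")
        if self.n_detected > self.n:
            raise ValueError("n_detected cannot exceed n")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    raw_p: float
    method: str
    groups: tuple[str, ...]
    adjusted_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.raw_p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.raw_p - 1e-12:
            raise ValueError("adjusted p below raw p")


def summarize_regions(
    records: Iterable[ConcentrationRecord],
    constants: Optional[Mapping[AnalyteClass, AnalyteConstants]] = None,
) -> list[RegionSummary]:
    """Per region x analyte class summary of class-total concentrations.

    Detection means the class total exceeds the class MDL. Regions are
    returned in first-appearance order, SCCP before MCCP within a region.
    """
    constants = constants or DEFAULT_CONSTANTS
    by_region: dict[str, list[ConcentrationRecord]] = {}
    for rec in records:
        by_region.setdefault(rec.region, []).append(rec)
    if not by_region:
        raise ValueError("no concentration records supplied")

    summaries = []
    for region, recs in by_region.items():
        for ac in AnalyteClass:
            totals = np.array([r.class_total(ac) for r in recs])
            n = len(totals)
            detected = int((totals > constants[ac].mdl).sum())
            single = n == 1
            summaries.append(
                RegionSummary(
                    region=region,
                    analyte_class=ac,
                    n=n,
                    n_detected=detected,
                    detection_rate=detected / n,
                    mean=float(totals.mean()),
                    sd=0.0 if single else float(totals.std(ddof=1)),
                    min=float(totals.min()),
                    max=float(totals.max()),
                    sd_undefined=single,
                )
            )
    return summaries


def pooled_mean(summaries: Sequence[RegionSummary]) -> float:
    """Sample-size-weighted mean over regional summaries of one class."""
    if not summaries:
        raise ValueError("no summaries to pool")
    classes = {s.analyte_class for s in summaries}
    if len(classes) != 1:
        raise ValueError(f"summaries mix analyte classes: {classes}")
    total_n = sum(s.n for s in summaries)
    if total_n == 0:
        raise ValueError("zero total sample size")
    return math.fsum(s.n * s.mean for s in summaries) / total_n


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie_correction == 0.0:  # all values identical
        return 0.0
    return h / tie_correction


def kruskal_wallis_exact_p(groups: Sequence[Sequence[float]]) -> float:
    """Exact permutation p-value for the Kruskal-Wallis H test.

    Enumerates all assignments of the pooled observations to the group
    sizes; intended for total n <= 10.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    if n > 12:
        raise ValueError("exact permutation test limited to total n <= 12")
    sizes = [len(g) for g in arrays]
    h_obs = _kw_statistic(arrays)

    indices = set(range(n))
    count = 0
    total = 0

    def recurse(remaining: frozenset, size_idx: int, chosen: list) -> None:
        nonlocal count, total
        if size_idx == len(sizes):
            perm_groups = [pooled[list(c)] for c in chosen]
            total += 1
            if _kw_statistic(perm_groups) >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(sorted(remaining), sizes[size_idx]):
            recurse(remaining - set(combo), size_idx + 1, chosen + [combo])

    recurse(frozenset(indices), 0, [])
    return count / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    exact: bool = False,
) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups.

    The p-value comes from the chi-square approximation with k-1 df;
    ``exact=True`` (total n <= 10) uses the permutation distribution
    instead. Identical data across all observations yields H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    labels = tuple(labels) if labels else tuple(
        f"group{i + 1}" for i in range(len(groups))
    )

    h = _kw_statistic(arrays)
    if exact:
        if sum(map(len, arrays)) > 10:
            raise ValueError("exact p only supported for total n <= 10")
        p = kruskal_wallis_exact_p(arrays)
        method = "kruskal-wallis (exact permutation)"
    else:
        p = 1.0 if h == 0.0 else float(stats.chi2.sf(h, df=len(arrays) - 1))
        method = "kruskal-wallis (chi-square)"
    return TestResult(statistic=float(h), raw_p=min(p, 1.0),
                      method=method, groups=labels)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_(i) * m / i with running-minimum monotonicity from the largest p
    down, capped at 1; order-preserving and idempotent.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted.tolist()


def pairwise_wilcoxon_bh(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> list[TestResult]:
    """All pairwise two-sample rank-sum tests with BH-FDR adjustment.

    Uses the exact Mann-Whitney null when both groups have n <= 25 and the
    pooled data is tie-free, otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    labels = list(labels) if labels else [
        f"group{i + 1}" for i in range(len(groups))
    ]

    raw: list[tuple[float, float, str, tuple[str, str]]] = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        a, b = arrays[i], arrays[j]
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        if len(a) <= 25 and len(b) <= 25 and no_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        raw.append(
            (float(res.statistic), float(res.pvalue),
             f"wilcoxon rank-sum ({method})", (labels[i], labels[j]))
        )

    adjusted = bh_adjust([r[1] for r in raw])
    return [
        TestResult(statistic=stat, raw_p=p, adjusted_p=min(adj, 1.0),
                   method=method, groups=pair)
        for (stat, p, method, pair), adj in zip(raw, adjusted)
    ]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    n: int
    degenerate_ci: bool = False  # |r| = 1: CI collapsed to (r, r)


def correlation_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    confidence: float = 0.95,
) -> CorrelationResult:
    """Correlation with a Fisher-z confidence interval.

    The Spearman variant applies the Fisher transform to the rank
    correlation with variance 1.06/(n-3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")

    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        var = 1.0 / (n - 3)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        var = 1.06 / (n - 3)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    r = float(r)
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(r, r, r, float(p), method, n,
                                 degenerate_ci=True)
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + confidence / 2.0) * math.sqrt(var)
    return CorrelationResult(
        r=r,
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        p=float(p),
        method=method,
        n=n,
    )
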