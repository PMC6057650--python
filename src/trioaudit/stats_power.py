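"""Rank-based group comparisons and the Poisson detection-power model.

The two rank tests mirror R's ``kruskal.test`` and ``wilcox.test`` exactly,
because the published per-group DNM-count comparisons were run with those
functions and the Wilcoxon W statistic is convention-dependent:

* ``kruskal_wallis`` computes H on midranks with the tie correction
  ``H / (1 - sum(t^3 - t) / (N^3 - N))`` and a chi-squared(k-1) p-value.
* ``wilcoxon_rank_sum`` reports W = (rank-sum of the first sample) -
  n1(n1+1)/2, i.e. the Mann-Whitney U of the first group.  The p-value is
  exact (full enumeration of the null rank-sum distribution) when there are
  no ties and both samples are small, otherwise a normal approximation with
  tie-corrected variance and a 0.5 continuity correction.  Two-sided
  throughout.

The detection-power model treats the number of variant-supporting reads at
a mosaic locus as Poisson with mean ``vaf * depth`` and asks for the
probability that the read count reaches the minimum implied by the VAF
calling threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    method: str  # "kruskal_wallis" or "wilcoxon_rank_sum"
    statistic: float
    p_value: float
    df: int | None = None
    groups: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "groups": self.groups,
        }


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> TestResult:
    """Kruskal-Wallis rank-sum test over two or more groups of counts."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    offset = 0
    for size in sizes:
        rsum = ranks[offset : offset + size].sum()
        h += rsum * rsum / size
        offset += size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - float(((ties**3 - ties).sum())) / (n_total**3 - n_total)
    if correction == 0.0:
        # every observation identical: no evidence of any difference
        h, p = 0.0, 1.0
    else:
        h = h / correction
        p = float(sps.chi2.sf(h, df=len(groups) - 1))
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        df=len(groups) - 1,
        p_value=p,
        groups={lab: size for lab, size in zip(labels, sizes)},
    )


def _exact_rank_sum_counts(n: int, total: int) -> np.ndarray:
    """Number of n-subsets of ranks {1..total} per rank-sum value.

    counts[s] = number of size-n subsets with rank-sum s; standard dynamic
    programme over ranks (coefficients of the Gaussian binomial generating
    function).
    """
    max_sum = n * total
    table = np.zeros((n + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for rank in range(1, total + 1):
        for k in range(min(rank, n), 0, -1):
            table[k, rank:] += table[k - 1, : max_sum + 1 - rank]
    return table[n]


def exact_wilcoxon_pvalue(w: float, n_x: int, n_y: int) -> float:
    """Two-sided exact p-value for the Mann-Whitney U statistic ``w`` of the
    first sample, by full enumeration of the null distribution (no ties)."""
    counts = _exact_rank_sum_counts(n_x, n_x + n_y)
    # shift rank-sums to U = ranksum - n_x(n_x+1)/2
    low = n_x * (n_x + 1) // 2
    u_counts = counts[low:]
    total = u_counts.sum()
    u = int(round(w))
    cdf = u_counts[: u + 1].sum() / total
    sf = u_counts[u:].sum() / total  # P(U >= u)
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
    exact_max_n: int = 50,
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, R convention."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size == 0 or y_arr.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x_arr.size, y_arr.size
    pooled = np.concatenate([x_arr, y_arr])
    ranks = _midranks(pooled)
    w = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)
    ties = _tie_counts(pooled)
    has_ties = bool((ties > 1).any())
    if not has_ties and n_x < exact_max_n and n_y < exact_max_n:
        p = exact_wilcoxon_pvalue(w, n_x, n_y)
    else:
        n_total = n_x + n_y
        tie_term = float((ties**3 - ties).sum()) / (n_total * (n_total - 1))
        sigma = math.sqrt(n_x * n_y / 12.0 * ((n_total + 1) - tie_term))
        if sigma == 0.0:
            p = 1.0
        else:
            z = w - n_x * n_y / 2.0
            z = (z - math.copysign(0.5, z) if z != 0 else z) / sigma
            p = min(1.0, 2.0 * min(sps.norm.cdf(z), sps.norm.sf(z)))
    return TestResult(
        method="wilcoxon_rank_sum",
        statistic=w,
        df=None,
        p_value=float(p),
        groups={labels[0]: n_x, labels[1]: n_y},
    )


def bonferroni_gate(
    p_values: Sequence[float], family_alpha: float = 0.05
) -> list[tuple[float, bool]]:
    """Bonferroni family-wise gate: per test, (critical value, significant?).

    significant iff p < family_alpha / m.
    """
    m = len(p_values)
    if not (1 <= m <= 100):
        raise ValueError("bonferroni_gate expects between 1 and 100 p-values")
    critical = family_alpha / m
    return [(critical, p < critical) for p in p_values]


@dataclass
class PowerQuery:
    depth: float  # mean sequencing depth (reads)
    vaf: float  # effect-size allele fraction of the mosaic mutation
    min_vaf: float  # VAF threshold the calling pipeline requires

    def __post_init__(self) -> None:
        if self.depth <= 0 or not (0 <= self.vaf <= 1) or not (0 < self.min_vaf <= 1):
            raise ValueError("invalid power query")


@dataclass
class PowerResult:
    lam: float  # Poisson mean of variant-supporting reads
    min_alt_reads: int  # reads needed to clear the VAF threshold
    detect_probability: float

    @property
    def miss_probability(self) -> float:
        return 1.0 - self.detect_probability


def poisson_detect_power(q: PowerQuery, integer_lambda: bool = True) -> PowerResult:
    """Probability of detecting a mosaic mutation at the given depth and VAF.

    The variant-read count is modelled as Poisson with mean vaf*depth
    (rounded to the nearest integer by default, matching the convention of
    quoting "11 variant reads out of 39.5"); detection requires at least
    ceil(min_vaf * floor(depth)) variant reads.
    """
    lam = q.vaf * q.depth
    if integer_lambda:
        lam = float(round(lam))
    min_alt = max(1, math.ceil(q.min_vaf * math.floor(q.depth)))
    if lam == 0.0:
        detect = 0.0
    else:
        detect = float(sps.poisson.sf(min_alt - 1, lam))
    return PowerResult(lam=lam, min_alt_reads=min_alt, detect_probability=detect)


def summarize_cohort(table) -> dict[str, dict[str, float]]:
    """Median and range per numeric column of a per-sample counts table.

    ``table`` is a pandas DataFrame; non-numeric columns are ignored and NaN
    entries (e.g. parents without DNM counts) are dropped per column.  The
    median uses the midpoint convention (mean of the central pair for even n).
    """
    import pandas as pd

    if len(table) < 1:
        raise ValueError("empty table")
    out: dict[str, dict[str, float]] = {}
    for col in table.columns:
        series = pd.to_numeric(table[col], errors="coerce").dropna()
        if series.empty:
            continue
        out[col] = {
            "median": float(series.median()),
            "min": float(series.min()),
            "max": float(series.max()),
            "n": int(series.size),
        }
    return out
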