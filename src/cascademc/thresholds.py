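"""KS-based detection of input-activity impact thresholds.

Given a simulated ensemble, the replicate distribution of a node's response
at each input level is compared with the distributions at the lowest and
highest input levels using the two-sample Kolmogorov-Smirnov test with the
asymptotic critical value

    reject  iff  D_{n,m} > c(alpha) * sqrt((n + m) / (n * m)),
    c(alpha) = sqrt(-0.5 * ln(alpha / 2)).

Scanning upward from the minimum input, the first level whose distribution
rejects against the minimum-input distribution is the lower threshold;
scanning downward from the maximum, the first level rejecting against the
maximum-input distribution is the upper threshold.  Inputs below the lower
bound have essentially no impact on the node, inputs above the upper bound a
strong one, and the region between the bounds a weak but statistically
significant impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble

__all__ = [
    "KSComparison",
    "ThresholdResult",
    "ks_statistic",
    "ks_critical",
    "find_thresholds",
]


def ks_statistic(a, b) -> float:
    """Two-sample KS statistic: sup_t |F_a(t) - F_b(t)| over the pooled support.

    Empirical CDFs are right-continuous; ties across samples are handled by
    evaluating both CDFs at every pooled sample point.  Symmetric in (a, b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    support = np.concatenate([a_sorted, b_sorted])
    fa = np.searchsorted(a_sorted, support, side="right") / a.size
    fb = np.searchsorted(b_sorted, support, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_critical(alpha: float, n: int, m_size: int) -> float:
    """Asymptotic two-sample KS rejection threshold c(alpha)*sqrt((n+m)/(n*m))."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n < 1 or m_size < 1:
        raise ValueError("sample sizes must be positive")
    c_alpha = math.sqrt(-0.5 * math.log(alpha / 2.0))
    return c_alpha * math.sqrt((n + m_size) / (n * m_size))


@dataclass(frozen=True)
class KSComparison:
    """One two-sample KS test outcome."""

    D: float
    n: int
    m_size: int
    alpha: float
    critical: float
    reject: bool


@dataclass(frozen=True)
class ScanRecord:
    """KS outcomes for one grid point against both reference distributions."""

    input: float
    D_vs_low: float
    D_vs_high: float
    critical: float
    reject_low: bool
    reject_high: bool


@dataclass(frozen=True)
class ThresholdResult:
    """Lower/upper input-activity bounds of significant impact for one node.

    Either bound is ``None`` when the corresponding scan never rejects
    (e.g. a flat response).  When both are defined, lower <= upper and both
    are members of the input grid.
    """

    node: str
    alpha: float
    lower: float | None
    upper: float | None
    scan: tuple[ScanRecord, ...]


def compare_samples(a, b, alpha: float) -> KSComparison:
    """Run one two-sample KS test at level alpha."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    D = ks_statistic(a, b)
    crit = ks_critical(alpha, a.size, b.size)
    return KSComparison(
        D=D, n=a.size, m_size=b.size, alpha=alpha, critical=crit, reject=D > crit
    )


def find_thresholds(ensemble: Ensemble, node: str, alpha: float = 0.05) -> ThresholdResult:
    """Sequential KS scan for the impact thresholds of one node.

    Every non-reference grid point is compared with the minimum-input and
    maximum-input replicate distributions.  The lower bound is the smallest
    grid value rejecting against the minimum-input reference (scanning
    upward, starting at the grid point adjacent to the reference); the upper
    bound is the largest grid value rejecting against the maximum-input
    reference (scanning downward).
    """
    if node not in ensemble.values:
        raise ValueError(f"node {node!r} not present in ensemble ({list(ensemble.values)})")
    grid = ensemble.input_grid
    if len(grid) < 3:
        raise ValueError("need at least 3 grid points to scan for thresholds")
    mat = ensemble.values[node]
    low_ref = mat[:, 0]
    high_ref = mat[:, -1]
    crit = ks_critical(alpha, mat.shape[0], mat.shape[0])

    records = []
    for j in range(len(grid)):
        col = mat[:, j]
        d_low = ks_statistic(col, low_ref) if j != 0 else 0.0
        d_high = ks_statistic(col, high_ref) if j != len(grid) - 1 else 0.0
        records.append(
            ScanRecord(
                input=float(grid[j]),
                D_vs_low=d_low,
                D_vs_high=d_high,
                critical=crit,
                reject_low=j != 0 and d_low > crit,
                reject_high=j != len(grid) - 1 and d_high > crit,
            )
        )

    lower = next((r.input for r in records[1:] if r.reject_low), None)
    upper = next((r.input for r in reversed(records[:-1]) if r.reject_high), None)
    return ThresholdResult(
        node=node, alpha=alpha, lower=lower, upper=upper, scan=tuple(records)
    )
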