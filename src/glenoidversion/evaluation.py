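"""Per-method summary statistics and between-method agreement.

Mirrors the descriptive analysis style used when comparing version
measurement methods on a patient cohort: mean, sample standard deviation and
range per method, plus Pearson correlation (with a two-sided p value) between
two measurement series on the same cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

__all__ = ["SummaryStats", "CorrelationResult", "summarize", "pearson"]


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n-1 denominator; None when n < 2), min and max, degrees."""

    n: int
    mean_deg: float
    sd_deg: Optional[float]
    min_deg: float
    max_deg: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


def summarize(values: Sequence[float]) -> SummaryStats:
    """Sample mean, SD (n-1), min and max of a measurement series."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    return SummaryStats(
        n=int(x.size),
        mean_deg=float(np.mean(x)),
        sd_deg=sd,
        min_deg=float(np.min(x)),
        max_deg=float(np.max(x)),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r between paired series, with the two-sided p value from the
    t transform ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("series must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for a zero-variance series")
    xm = xa - xa.mean()
    ym = ya - ya.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _st.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_two_sided=p, n=int(n))
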