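"""Condition-level statistics: Welch comparisons and order trends."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import ValidationError


@dataclass
class ComparisonResult:
    metric: str
    labels: tuple[str, str]
    n: tuple[int, int]
    t: float
    df: float
    p: float
    d: Optional[float]  # Cohen's d; None when undefined (no variance, equal means)
    direction: str  # which label has the larger mean, or "equal"


@dataclass
class TrendResult:
    metric: str
    n: int
    r: float
    p: float


def cohens_d(a: np.ndarray, b: np.ndarray, hedges: bool = False) -> Optional[float]:
    """Pooled-SD Cohen's d (n-1 weights); optional Hedges small-sample correction."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled == 0:
        if a.mean() == b.mean():
            return None
        return math.inf if a.mean() > b.mean() else -math.inf
    d = (a.mean() - b.mean()) / math.sqrt(pooled)
    if hedges:
        dof = na + nb - 2
        d *= 1.0 - 3.0 / (4.0 * dof - 1.0)
    return float(d)


def welch_compare(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    labels: tuple[str, str] = ("a", "b"),
    hedges: bool = False,
) -> ComparisonResult:
    """Welch's t-test between two samples with Cohen's d effect size."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("samples must be finite")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        df = float(a.size + b.size - 2)
    else:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    if a.mean() > b.mean():
        direction = labels[0]
    elif a.mean() < b.mean():
        direction = labels[1]
    else:
        direction = "equal"
    t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return ComparisonResult(
        metric=metric,
        labels=labels,
        n=(int(a.size), int(b.size)),
        t=t,
        df=float(df),
        p=p,
        d=cohens_d(a, b, hedges=hedges),
        direction=direction,
    )


def order_trend(metric: Sequence[float], order_index: Sequence[int], name: str = "") -> TrendResult:
    """Pearson correlation of a per-trial metric with trial order."""
    x = np.asarray(order_index, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("order trend needs >= 3 paired values")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return TrendResult(metric=name, n=int(x.size), r=float("nan"), p=float("nan"))
    r, p = sps.pearsonr(y, x)
    return TrendResult(metric=name, n=int(x.size), r=float(r), p=float(p))
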