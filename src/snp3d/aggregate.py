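"""Disease-association (DA) score aggregation: medians, fractions, quantile/IQR summaries.

Quantiles use linear interpolation between order statistics throughout (the
``linear`` method of ``numpy.quantile``), exposed as a parameter for
sensitivity checks. Outliers for violin-style reporting follow the 1.5*IQR
convention; they affect only the whisker min/max, never the quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["DistributionSummary", "median_da", "fraction_da", "summarize"]


@dataclass(frozen=True)
class DistributionSummary:
    """Quantile summary of one group of values (one violin / table column)."""

    n: int
    q1: float
    q2: float
    q3: float
    iqr: float
    whisker_low: float   # min excluding outliers
    whisker_high: float  # max excluding outliers
    outliers: tuple[float, ...] = field(default_factory=tuple)


def _scores(items: Iterable) -> list[float]:
    out = []
    for it in items:
        score = getattr(it, "da_score", it)
        if score is None or not isinstance(score, (int, float, np.floating, np.integer)):
            raise ValueError(f"missing numeric da_score on {it!r}")
        out.append(float(score))
    return out


def median_da(elements_or_genes: Iterable) -> Optional[float]:
    """Median DA score of elements/genes; ``None`` for an empty group.

    Every member must carry a numeric score — score-less TFs belong in
    :func:`fraction_da` instead. Accepts objects with a ``da_score`` attribute
    or bare numbers.
    """
    scores = _scores(elements_or_genes)
    if not scores:
        return None
    return float(np.median(scores))


def fraction_da(tfs: Iterable) -> Optional[float]:
    """Fraction of TFs flagged disease-associated; ``None`` for an empty group."""
    flags = []
    for tf in tfs:
        flag = getattr(tf, "disease_associated", tf)
        if flag is None or not isinstance(flag, (bool, np.bool_)):
            raise ValueError(f"missing disease_associated flag on {tf!r}")
        flags.append(bool(flag))
    if not flags:
        return None
    return sum(flags) / len(flags)


def summarize(values: Sequence[float], method: str = "linear") -> DistributionSummary:
    """Quantile/IQR summary of one distribution, with 1.5*IQR outlier fences.

    ``method`` is any quantile method accepted by ``numpy.quantile``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty distribution")
    q1, q2, q3 = (float(np.quantile(arr, q, method=method)) for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = arr[(arr >= lo) & (arr <= hi)]
    outliers = arr[(arr < lo) | (arr > hi)]
    return DistributionSummary(
        n=int(arr.size),
        q1=q1,
        q2=q2,
        q3=q3,
        iqr=iqr,
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=tuple(sorted(float(x) for x in outliers)),
    )
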