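"""ICC(A,1): absolute-agreement intraclass correlation for single measures.

The reliability of macrostructure indices between two scorers is measured
with the two-way, single-measure, absolute-agreement intraclass correlation
(McGraw-Wong ICC(A,1)).  From the two-way ANOVA without replication on an
n-subject x k-rater table,

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE)),

where MSR, MSC and MSE are the subject, rater and residual mean squares.
Unlike the consistency form ICC(C,1), a constant offset between raters
lowers ICC(A,1): absolute agreement penalises systematic bias.

Qualitative interpretation follows the conventional reliability bands:
< 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good, [0.9, 1] excellent
(exact boundary values are assigned upward and flagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InsufficientDataError",
    "IccResult",
    "icc_value",
    "icc_a1",
    "average_pairwise_icc",
    "interpret_icc",
]


class InsufficientDataError(ValueError):
    """Fewer than two complete subjects remain after dropping missing rows."""


@dataclass(frozen=True)
class IccResult:
    icc: float  # NaN when the denominator vanishes
    msr: float
    msc: float
    mse: float
    n: int  # subjects used
    k: int  # raters
    dropped: int  # subjects excluded for missing values
    interpretation: str | None  # poor/moderate/good/excellent, None if NaN
    boundary: bool = False  # value sits exactly on a band boundary


def _icc_a1_value(x: np.ndarray) -> tuple[float, float, float, float]:
    """(icc, msr, msc, mse) for a complete (n, k) table; NaN-safe denominator."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)  # clip FP negatives
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0.0 else math.nan
    return icc, msr, msc, mse


def icc_value(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """ICC(A,1) of two paired rating vectors, as a bare float.

    Rows where either rating is missing are dropped; returns NaN when fewer
    than two complete rows remain or the denominator vanishes.  This is the
    allocation-free path used inside bootstrap resampling loops;
    :func:`icc_a1` is the full-featured front end.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 2:
        return math.nan
    return _icc_a1_value(np.column_stack((x[keep], y[keep])))[0]


def icc_a1(ratings: Sequence[Sequence[float]] | np.ndarray) -> IccResult:
    """ICC(A,1) for an n-subject x k-rater table of real-valued ratings.

    Rows containing any missing value (NaN) are dropped and counted; at
    least two complete rows are required.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a 2-D table with >= 2 rater columns")
    complete = ~np.isnan(x).any(axis=1)
    dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError(f"only {n} complete subjects (need >= 2)")
    icc, msr, msc, mse = _icc_a1_value(x)
    interp, boundary = (None, False) if math.isnan(icc) else _interpret(icc)
    return IccResult(icc, msr, msc, mse, n, k, dropped, interp, boundary)


def _interpret(value: float) -> tuple[str, bool]:
    boundary = value in (0.5, 0.75, 0.9)
    if value < 0.5:
        return "poor", boundary
    if value < 0.75:
        return "moderate", boundary
    if value < 0.9:
        return "good", boundary
    return "excellent", boundary


def interpret_icc(value: float) -> str | None:
    """Reliability band for an ICC value (None for NaN).

    Half-open bands with exact boundaries assigned upward: 0.75 -> good,
    0.9 -> excellent.
    """
    if value is None or math.isnan(value):
        return None
    if value > 1.0:
        raise ValueError("ICC cannot exceed 1")
    return _interpret(value)[0]


def average_pairwise_icc(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[float, int]:
    """Mean pairwise ICC(A,1) between two scorer groups on one index.

    ``table`` has one row per recording and one column per scorer.  For the
    within-panel mode pass the same group twice: all unordered pairs inside
    the group are used (ICC is symmetric in column order, so ordered pairs
    would duplicate).  Between two distinct groups every cross pair of
    distinct scorers is used.  Pairs whose ICC is undefined, or which have
    fewer than two complete recordings, are skipped; the skipped count is
    returned alongside the mean (NaN if every pair was skipped).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("scorer groups must be non-empty")
    if group_a == group_b:
        pairs = list(combinations(group_a, 2))
    else:
        pairs = [(a, b) for a, b in product(group_a, group_b) if a != b]
    values: list[float] = []
    skipped = 0
    for a, b in pairs:
        try:
            r = icc_a1(table[[a, b]].to_numpy(dtype=float))
        except InsufficientDataError:
            skipped += 1
            continue
        if math.isnan(r.icc):
            skipped += 1
        else:
            values.append(r.icc)
    if not values:
        return math.nan, skipped
    return float(np.mean(values)), skipped
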