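"""Epoch-level agreement statistics between sleep scorers.

All statistics derive from a pooled 5x5 confusion matrix over the scoring
vocabulary (W, N1, N2, N3, R), rows indexed by the reference scorer and
columns by the test scorer:

* OPA   -- overall percent agreement, trace / N;
* kappa -- Cohen's chance-corrected agreement, (po - pe) / (1 - pe);
* per stage s: PPA = TP/ref_s (sensitivity), NPA = TN/(N - ref_s)
  (specificity), PPV = TP/test_s, with TP = counts[s, s],
  TN = N - ref_s - test_s + TP.

Ratios with zero denominators (and kappa when pe = 1) are *undefined* and
propagate as NaN, never silently as 0; panel averages skip undefined values
and report how many contributors were skipped.

Directionality matters for PPA/NPA/PPV: the agreement of scorer A referenced
on B differs from B referenced on A.  Within-panel averages therefore run
over all ordered rater pairs (six for three raters), while a machine scorer
is always the test column with each manual rater as reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hypnogram import STAGES, UNSCORED, StagingSet

__all__ = [
    "STAT_NAMES",
    "ConfusionMatrix",
    "AgreementStats",
    "build_confusion",
    "overall_percent_agreement",
    "cohens_kappa",
    "per_stage_stats",
    "agreement_stats",
    "stats_vector",
    "directional_panel_averages",
]

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: Flat ordering of the 17 agreement statistics, used by the bootstrap layer.
STAT_NAMES: tuple[str, ...] = ("opa", "kappa") + tuple(
    f"{s}_{m}" for s in STAGES for m in ("ppa", "npa", "ppv")
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pooled reference-vs-test epoch counts over the five-stage vocabulary."""

    counts: np.ndarray  # (5, 5) int64, rows = reference, cols = test
    labels: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError(f"counts must be {len(self.labels)}x{len(self.labels)}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    @property
    def T(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts.T.copy(), self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        return df


def build_confusion(
    reference: Sequence[str], test: Sequence[str], labels: tuple[str, ...] = STAGES
) -> ConfusionMatrix:
    """Cross-tabulate two equal-length stage sequences (reference rows)."""
    if len(reference) != len(test):
        raise ValueError(f"length mismatch: {len(reference)} vs {len(test)}")
    if len(reference) == 0:
        raise ValueError("sequences must be non-empty")
    idx = {s: i for i, s in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, t in zip(reference, test):
        if r == UNSCORED or t == UNSCORED:
            raise ValueError("U stage in agreement input; filter upstream")
        counts[idx[r], idx[t]] += 1
    return ConfusionMatrix(counts, labels)


def overall_percent_agreement(m: ConfusionMatrix) -> float:
    """Fraction of epochs on the diagonal (proportion in [0, 1])."""
    n = m.grand_total
    if n < 1:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m.counts)) / n


def cohens_kappa(m: ConfusionMatrix) -> float:
    """Chance-corrected agreement; NaN when expected agreement pe = 1.

    pe = 1 only when both scorers are constant on the same single stage, in
    which case kappa has no information to correct and is undefined rather
    than 0 or 1.
    """
    n = m.grand_total
    if n < 1:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(m.counts)) / n
    pe = float(m.row_totals @ m.col_totals) / (n * n)
    if pe >= 1.0:
        return math.nan
    return (po - pe) / (1.0 - pe)


def per_stage_stats(m: ConfusionMatrix, stage: str) -> dict[str, float]:
    """PPA/NPA/PPV for one stage; NaN where the denominator is zero."""
    s = m.labels.index(stage)
    n = m.grand_total
    tp = float(m.counts[s, s])
    ref_s = float(m.row_totals[s])
    test_s = float(m.col_totals[s])
    ppa = tp / ref_s if ref_s > 0 else math.nan
    ppv = tp / test_s if test_s > 0 else math.nan
    npa = (n - ref_s - test_s + tp) / (n - ref_s) if n - ref_s > 0 else math.nan
    return {"ppa": ppa, "npa": npa, "ppv": ppv}


@dataclass(frozen=True)
class AgreementStats:
    """The full statistic set for one reference/test pair (or an average)."""

    opa: float
    kappa: float
    per_stage: dict[str, dict[str, float]]
    n_undefined: dict[str, int] | None = None  # stat name -> skipped contributors

    def to_vector(self) -> np.ndarray:
        vals = [self.opa, self.kappa]
        for s in STAGES:
            st = self.per_stage[s]
            vals.extend((st["ppa"], st["npa"], st["ppv"]))
        return np.array(vals, dtype=float)

    @classmethod
    def from_vector(
        cls, v: np.ndarray, n_undefined: dict[str, int] | None = None
    ) -> "AgreementStats":
        per_stage = {
            s: {"ppa": float(v[2 + 3 * i]), "npa": float(v[3 + 3 * i]), "ppv": float(v[4 + 3 * i])}
            for i, s in enumerate(STAGES)
        }
        return cls(float(v[0]), float(v[1]), per_stage, n_undefined)


def agreement_stats(m: ConfusionMatrix) -> AgreementStats:
    """OPA, kappa and all per-stage statistics from one confusion matrix."""
    return AgreementStats(
        opa=overall_percent_agreement(m),
        kappa=cohens_kappa(m),
        per_stage={s: per_stage_stats(m, s) for s in STAGES},
    )


def stats_vector(counts: np.ndarray) -> np.ndarray:
    """Vectorised statistic set from a raw (5, 5) count array.

    Same quantities as :func:`agreement_stats`, in :data:`STAT_NAMES` order,
    computed without intermediate objects -- this is the bootstrap hot path.
    """
    c = counts.astype(float)
    n = c.sum()
    ref = c.sum(axis=1)
    test = c.sum(axis=0)
    tp = np.diag(c)
    po = tp.sum() / n
    pe = float(ref @ test) / (n * n)
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else math.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ppa = np.where(ref > 0, tp / ref, np.nan)
        ppv = np.where(test > 0, tp / test, np.nan)
        npa = np.where(n - ref > 0, (n - ref - test + tp) / (n - ref), np.nan)
    out = np.empty(2 + 3 * len(STAGES))
    out[0] = po
    out[1] = kappa
    out[2::3] = ppa
    out[3::3] = npa
    out[4::3] = ppv
    return out


def _nanmean_with_counts(vectors: list[np.ndarray]) -> tuple[np.ndarray, dict[str, int]]:
    stacked = np.vstack(vectors)
    defined = (~np.isnan(stacked)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(defined > 0, np.nansum(stacked, axis=0) / np.maximum(defined, 1), np.nan)
    skipped = {
        name: int(len(vectors) - defined[i])
        for i, name in enumerate(STAT_NAMES)
        if defined[i] < len(vectors)
    }
    return mean, skipped


def directional_panel_averages(
    panel: StagingSet, machine_column: str | None = None
) -> tuple[AgreementStats, AgreementStats | None]:
    """Averaged agreement statistics within a manual panel and machine-vs-panel.

    Within-panel: every ordered (reference, test) pair of manual raters is
    evaluated and each statistic averaged over all ordered pairs -- six
    values for three raters, both orders of each pair.  Machine-vs-panel:
    the machine is always the test scorer, each manual rater in turn the
    reference (three values for three raters).  Averages skip undefined
    (NaN) contributors, reporting the skipped count per statistic.
    """
    manual = [s for s in panel.scorer_ids if s != machine_column]
    if len(manual) < 2:
        raise ValueError("need at least two manual raters")
    cols = {s: panel.column(s) for s in panel.scorer_ids}

    within_vecs = [
        stats_vector(build_confusion(cols[a], cols[b]).counts)
        for a in manual
        for b in manual
        if a != b
    ]
    within_mean, within_skipped = _nanmean_with_counts(within_vecs)
    within = AgreementStats.from_vector(within_mean, within_skipped)

    machine_stats: AgreementStats | None = None
    if machine_column is not None:
        machine_vecs = [
            stats_vector(build_confusion(cols[a], cols[machine_column]).counts) for a in manual
        ]
        mean, skipped = _nanmean_with_counts(machine_vecs)
        machine_stats = AgreementStats.from_vector(mean, skipped)
    return within, machine_stats
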