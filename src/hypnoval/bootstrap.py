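"""Recording-level (cluster) bootstrap for agreement and reliability statistics.

Epochs within a recording are strongly dependent, so resampling individual
epochs would understate uncertainty.  The engine instead resamples *whole
recordings* with replacement: each of the ``n_resamples`` replicates draws
as many recordings as observed, re-pools their epochs (or index tables) and
re-evaluates the statistic.  The point estimate is the median of the
resample distribution and the confidence interval its 2.5th/97.5th
percentiles (linear interpolation); for a difference statistic, significance
is declared when both CI bounds share a sign.

Differences are always *paired*: one resample drives both statistics, so the
CI reflects the sampling variability of the difference, not of two
independently resampled quantities.

Statistics may return a scalar or a fixed-length vector (one resample pass
then summarises many table cells at once).  Resamples where a component is
undefined (NaN -- e.g. a stage absent from every resampled recording) are
dropped from that component's distribution with the count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "cluster_bootstrap",
    "bootstrap_difference",
    "classify_significance",
]


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 10_000
    ci_lower_pct: float = 2.5
    ci_upper_pct: float = 97.5
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if not (0.0 < self.ci_lower_pct < self.ci_upper_pct < 100.0):
            raise ValueError("need 0 < ci_lower_pct < ci_upper_pct < 100")


@dataclass(frozen=True)
class BootstrapResult:
    """Summary of one resample distribution (scalar or per-component vectors).

    ``significant`` is populated only for difference statistics: per
    component, "positive" if the whole CI is above 0, "negative" if below,
    else "none".
    """

    point: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_defined: np.ndarray
    n_resamples: int
    names: tuple[str, ...] | None = None
    significant: tuple[str, ...] | None = None

    @property
    def is_scalar(self) -> bool:
        return self.point.size == 1

    def scalar(self) -> tuple[float, float, float]:
        """(point, ci_lower, ci_upper) for a scalar statistic."""
        if not self.is_scalar:
            raise ValueError("statistic is vector-valued")
        return float(self.point[0]), float(self.ci_lower[0]), float(self.ci_upper[0])

    def component(self, name: str) -> dict:
        i = self.names.index(name)
        out = {
            "point": float(self.point[i]),
            "ci_lower": float(self.ci_lower[i]),
            "ci_upper": float(self.ci_upper[i]),
            "n_defined": int(self.n_defined[i]),
        }
        if self.significant is not None:
            out["significant"] = self.significant[i]
        return out


def classify_significance(ci_lower: float, ci_upper: float) -> str:
    """CI-sign rule: significant iff both bounds share a sign."""
    if np.isnan(ci_lower) or np.isnan(ci_upper):
        return "none"
    if ci_lower > 0:
        return "positive"
    if ci_upper < 0:
        return "negative"
    return "none"


def _summarise(
    draws: np.ndarray,
    config: BootstrapConfig,
    names: tuple[str, ...] | None,
    difference: bool,
) -> BootstrapResult:
    n_defined = (~np.isnan(draws)).sum(axis=0)
    point = np.full(draws.shape[1], np.nan)
    lo = np.full(draws.shape[1], np.nan)
    hi = np.full(draws.shape[1], np.nan)
    ok = n_defined > 0
    if ok.any():
        with np.errstate(invalid="ignore"):
            point[ok] = np.nanmedian(draws[:, ok], axis=0)
            lo[ok] = np.nanpercentile(draws[:, ok], config.ci_lower_pct, axis=0)
            hi[ok] = np.nanpercentile(draws[:, ok], config.ci_upper_pct, axis=0)
    significant = (
        tuple(classify_significance(l, h) for l, h in zip(lo, hi)) if difference else None
    )
    return BootstrapResult(
        point=point, ci_lower=lo, ci_upper=hi, n_defined=n_defined,
        n_resamples=config.n_resamples, names=names, significant=significant,
    )


def _run(
    data: Sequence,
    statistic: Callable[[list], float | np.ndarray],
    config: BootstrapConfig,
    names: tuple[str, ...] | None,
    difference: bool,
) -> BootstrapResult:
    if len(data) < 1:
        raise ValueError("need at least one recording")
    rng = np.random.default_rng(config.seed)
    n = len(data)
    data = list(data)
    first = np.atleast_1d(np.asarray(statistic(data), dtype=float))
    d = first.size
    if names is not None and len(names) != d:
        raise ValueError("names length does not match statistic dimension")
    draws = np.empty((config.n_resamples, d), dtype=float)
    for b in range(config.n_resamples):
        idx = rng.integers(0, n, size=n)
        draws[b] = statistic([data[i] for i in idx])
    result = _summarise(draws, config, names, difference)
    if result.n_defined.max(initial=0) == 0:
        raise ValueError("statistic undefined in every resample")
    return result


def cluster_bootstrap(
    data: Sequence,
    statistic: Callable[[list], float | np.ndarray],
    config: BootstrapConfig | None = None,
    names: tuple[str, ...] | None = None,
) -> BootstrapResult:
    """Bootstrap a statistic by resampling whole recordings with replacement.

    ``data`` is any sequence of per-recording objects; ``statistic`` maps a
    resampled list (repeats allowed) to a scalar or fixed-length vector.
    Deterministic under a fixed ``config.seed``.
    """
    return _run(data, statistic, config or BootstrapConfig(), names, difference=False)


def bootstrap_difference(
    data: Sequence,
    statistic_a: Callable[[list], float | np.ndarray],
    statistic_b: Callable[[list], float | np.ndarray],
    config: BootstrapConfig | None = None,
    names: tuple[str, ...] | None = None,
) -> BootstrapResult:
    """Paired bootstrap of ``statistic_a - statistic_b``.

    Both statistics see the *same* resampled recordings, so the resulting CI
    supports the sign test for "is A systematically larger than B".
    """

    def diff(items: list) -> np.ndarray:
        a = np.atleast_1d(np.asarray(statistic_a(items), dtype=float))
        b = np.atleast_1d(np.asarray(statistic_b(items), dtype=float))
        return a - b

    return _run(data, diff, config or BootstrapConfig(), names, difference=True)
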