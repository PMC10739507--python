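"""Sleep macrostructure indices derived from a single hypnogram.

All indices are epoch-count arithmetic at 0.5 min per epoch over the lights
window the hypnogram spans:

* TIB   -- time in bed, 0.5 x number of epochs;
* TST   -- total sleep time, minutes in {N1, N2, N3, R};
* SL    -- sleep latency, lights-off to the first sleep epoch;
* REML  -- REM latency, sleep onset to the first R epoch;
* SE    -- sleep efficiency, 100 x TST / TIB (percent);
* WASO  -- wake after sleep onset, W (and U) minutes from onset to lights-on,
           terminal wake included.

Conventions for degenerate cases: a recording with no sleep epoch has
SL/REML/WASO *missing* (NaN), not zero -- a zero would fabricate agreement
downstream.  U epochs count toward TIB, toward the latency region before
onset and toward WASO after onset, never toward TST; with those rules the
identity SL + TST + WASO = TIB holds exactly whenever SL is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hypnogram import EPOCH_SECONDS, SLEEP_STAGES, STAGES, UNSCORED, Hypnogram

__all__ = ["MACRO_INDEX_NAMES", "MacroIndices", "compute_macro"]

#: Order of the ten study indices in tables and vectors.
MACRO_INDEX_NAMES: tuple[str, ...] = (
    "tst", "sl", "reml", "se", "waso",
    "time_w", "time_n1", "time_n2", "time_n3", "time_r",
)

_MIN_PER_EPOCH = EPOCH_SECONDS / 60.0


@dataclass(frozen=True)
class MacroIndices:
    """Macrostructure summary of one hypnogram (minutes unless noted)."""

    tib: float
    tst: float
    sl: float  # NaN if no sleep epoch
    reml: float  # NaN if no REM epoch (or no onset)
    se: float  # percent in [0, 100]
    waso: float  # NaN if no sleep onset
    time_in_stage: dict[str, float]  # W/N1/N2/N3/R minutes
    u_time: float

    def to_vector(self) -> np.ndarray:
        """The ten study indices in :data:`MACRO_INDEX_NAMES` order."""
        t = self.time_in_stage
        return np.array(
            [self.tst, self.sl, self.reml, self.se, self.waso,
             t["W"], t["N1"], t["N2"], t["N3"], t["R"]],
            dtype=float,
        )


def compute_macro(h: Hypnogram) -> MacroIndices:
    """Compute all macrostructure indices for one scorer's hypnogram."""
    stages = h.stages
    n = len(stages)
    if n == 0:
        raise ValueError("empty hypnogram")
    tib = n * _MIN_PER_EPOCH
    time_in = {s: stages.count(s) * _MIN_PER_EPOCH for s in STAGES}
    u_time = stages.count(UNSCORED) * _MIN_PER_EPOCH
    tst = sum(time_in[s] for s in ("N1", "N2", "N3", "R"))
    se = 100.0 * tst / tib

    onset = next((i for i, s in enumerate(stages) if s in SLEEP_STAGES), None)
    if onset is None:
        sl = reml = waso = math.nan
    else:
        sl = onset * _MIN_PER_EPOCH
        first_rem = next((i for i, s in enumerate(stages) if s == "R"), None)
        reml = (first_rem - onset) * _MIN_PER_EPOCH if first_rem is not None else math.nan
        waso = sum(1 for s in stages[onset:] if s not in SLEEP_STAGES) * _MIN_PER_EPOCH
    return MacroIndices(
        tib=tib, tst=tst, sl=sl, reml=reml, se=se, waso=waso,
        time_in_stage=time_in, u_time=u_time,
    )
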