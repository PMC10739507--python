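"""Majority-vote consensus staging across a panel of manual raters.

An epoch receives a consensus stage when a strict plurality of at least two
raters agree on it; with three raters this is the usual "at least two of
three" rule.  Epochs where every rater chose a different stage -- or, for
panels of four or more, where the top vote count is tied between stages --
carry no consensus and are excluded from consensus-based agreement analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .hypnogram import STAGES, UNSCORED, StagingSet

__all__ = ["NONCONSENSUS", "ConsensusResult", "majority_vote"]

#: Marker used for non-consensus epochs when exporting a consensus hypnogram.
NONCONSENSUS: str = UNSCORED


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus sequence plus agreement bookkeeping.

    ``consensus_stages`` holds one entry per input epoch: a stage code, or
    ``None`` for non-consensus epochs.  Full agreement means every rater
    chose the same stage; partial means a plurality >= 2 short of unanimity.
    """

    consensus_stages: tuple[str | None, ...]
    n_full_agreement: int
    n_partial_agreement: int
    n_nonconsensus: int

    @property
    def n_epochs(self) -> int:
        return len(self.consensus_stages)

    @property
    def retained_stages(self) -> tuple[str, ...]:
        """Consensus stages with non-consensus epochs dropped."""
        return tuple(s for s in self.consensus_stages if s is not None)

    def as_hypnogram_codes(self) -> tuple[str, ...]:
        """Exportable sequence with ``U`` marking non-consensus epochs."""
        return tuple(s if s is not None else NONCONSENSUS for s in self.consensus_stages)


def majority_vote(panel: StagingSet) -> ConsensusResult:
    """Assign per-epoch majority-vote stages over a rater panel.

    Parameters
    ----------
    panel
        Aligned, U-filtered stage matrix restricted to the manual raters.
        U filtering happens upstream; a U cell here is a contract violation.

    Raises
    ------
    ValueError
        If any cell contains U (filtering belongs upstream).
    """
    n_raters = len(panel.scorer_ids)
    consensus: list[str | None] = []
    n_full = n_partial = n_non = 0
    for row in panel.aligned_stages:
        if UNSCORED in row:
            raise ValueError("U stage in consensus input; run align_and_filter first")
        counts = Counter(row)
        (top_stage, top_count), *rest = counts.most_common()
        tied = rest and rest[0][1] == top_count
        if top_count >= 2 and not tied:
            consensus.append(top_stage)
            if top_count == n_raters:
                n_full += 1
            else:
                n_partial += 1
        else:
            consensus.append(None)
            n_non += 1
    return ConsensusResult(
        consensus_stages=tuple(consensus),
        n_full_agreement=n_full,
        n_partial_agreement=n_partial,
        n_nonconsensus=n_non,
    )
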