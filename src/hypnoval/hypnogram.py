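"""Epoch-level sleep-stage annotations: data model, file I/O, alignment.

A hypnogram is one scorer's per-epoch stage sequence for one overnight
recording, staged in fixed 30-second epochs over the lights-off to lights-on
window.  Stages follow the standard five-class vocabulary -- W (wake), N1,
N2, N3 (non-REM depth levels) and R (REM) -- plus U for epochs the scorer
could not classify.  U is bookkeeping only: it never enters agreement
statistics, which operate on the five-stage vocabulary.

On-disk format is one CSV per recording per scorer with header
``epoch_index,stage`` and dense 0-based epoch indices; recording identity,
scorer roles and lights times live in a study manifest (see
:mod:`hypnoval.manifest`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STAGES",
    "UNSCORED",
    "ALL_STAGES",
    "SLEEP_STAGES",
    "EPOCH_SECONDS",
    "DEFAULT_ALIASES",
    "HypnogramFormatError",
    "EmptyStagingError",
    "Hypnogram",
    "StagingSet",
    "normalize_stage",
    "read_hypnogram",
    "write_hypnogram",
    "align_and_filter",
]

#: The five-stage scoring vocabulary used in all agreement statistics.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: Marker for an epoch the scorer declined to classify.
UNSCORED: str = "U"

ALL_STAGES: tuple[str, ...] = STAGES + (UNSCORED,)

#: Stages that count as sleep for macrostructure arithmetic.
SLEEP_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3", "R"})

#: Epoch duration is fixed by scoring convention; macrostructure arithmetic
#: (0.5 min per epoch) depends on it, so it is deliberately not configurable.
EPOCH_SECONDS: int = 30

# Common hypnogram export dialects, matched case-insensitively.
DEFAULT_ALIASES: dict[str, str] = {
    "wake": "W", "w": "W", "0": "W",
    "n1": "N1", "1": "N1",
    "n2": "N2", "2": "N2",
    "n3": "N3", "3": "N3",
    "rem": "R", "r": "R", "5": "R",
    "u": "U", "?": "U", "9": "U",
}


class HypnogramFormatError(ValueError):
    """A hypnogram file violates the format contract (bad token, gap, empty)."""


class EmptyStagingError(ValueError):
    """Alignment/filtering retained zero epochs for a recording."""


def normalize_stage(token: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a raw stage token to one of the six admissible codes.

    Raises
    ------
    HypnogramFormatError
        If the token is not in the alias table (e.g. the legacy "N4").
    """
    table = DEFAULT_ALIASES if aliases is None else aliases
    code = table.get(token.strip().lower())
    if code is None or code not in ALL_STAGES:
        raise HypnogramFormatError(f"unknown stage code {token!r}")
    return code


@dataclass(frozen=True)
class Hypnogram:
    """One scorer's stage sequence for one recording.

    ``stages`` holds one code per 30-s epoch, ordered from lights-off.
    ``lights_off``/``lights_on`` are informational clock strings ("HH:MM:SS");
    all index arithmetic uses epoch counts only.
    """

    recording_id: str
    scorer_id: str
    stages: tuple[str, ...]
    lights_off: str | None = None
    lights_on: str | None = None

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"invalid stage codes: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_minutes(self) -> float:
        return self.n_epochs * EPOCH_SECONDS / 60.0


@dataclass(frozen=True)
class StagingSet:
    """Epoch-aligned stage sequences from several scorers of one recording.

    Produced by :func:`align_and_filter`; rows are epochs retained after
    end-truncation to the shortest scorer and removal of epochs any scorer
    marked U, so no cell contains U.
    """

    recording_id: str
    scorer_ids: tuple[str, ...]
    aligned_stages: tuple[tuple[str, ...], ...]  # row-major: epoch x scorer
    retained_epoch_indices: tuple[int, ...]

    @property
    def n_epochs(self) -> int:
        return len(self.aligned_stages)

    def column(self, scorer_id: str) -> tuple[str, ...]:
        """The retained stage sequence for one scorer."""
        j = self.scorer_ids.index(scorer_id)
        return tuple(row[j] for row in self.aligned_stages)

    def restrict(self, scorer_ids: Sequence[str]) -> "StagingSet":
        """A view on a subset of scorers (same retained epochs)."""
        cols = [self.scorer_ids.index(s) for s in scorer_ids]
        return StagingSet(
            recording_id=self.recording_id,
            scorer_ids=tuple(scorer_ids),
            aligned_stages=tuple(tuple(row[j] for j in cols) for row in self.aligned_stages),
            retained_epoch_indices=self.retained_epoch_indices,
        )


def read_hypnogram(
    path: str | Path,
    *,
    aliases: Mapping[str, str] | None = None,
    recording_id: str | None = None,
    scorer_id: str | None = None,
    lights_off: str | None = None,
    lights_on: str | None = None,
) -> Hypnogram:
    """Read a per-scorer hypnogram CSV (``epoch_index,stage``).

    Epoch indices must be dense from 0; stage tokens are mapped through the
    alias table.  Identity and lights metadata normally come from the study
    manifest and are passed in here; defaults fall back to the file stem.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise HypnogramFormatError(f"{path}: empty hypnogram file")
    start = 1 if lines[0].lower().replace(" ", "").startswith("epoch_index") else 0
    stages: list[str] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split(",")
        if len(parts) != 2:
            raise HypnogramFormatError(f"{path}:{lineno}: expected 'epoch_index,stage', got {line!r}")
        idx_token, stage_token = parts
        try:
            idx = int(idx_token)
        except ValueError:
            raise HypnogramFormatError(f"{path}:{lineno}: bad epoch index {idx_token!r}") from None
        if idx != len(stages):
            raise HypnogramFormatError(
                f"{path}:{lineno}: non-dense epoch index {idx} (expected {len(stages)})"
            )
        try:
            stages.append(normalize_stage(stage_token, aliases))
        except HypnogramFormatError as err:
            raise HypnogramFormatError(f"{path}:{lineno}: {err}") from None
    if not stages:
        raise HypnogramFormatError(f"{path}: no epochs found")
    return Hypnogram(
        recording_id=recording_id or path.stem,
        scorer_id=scorer_id or path.stem,
        stages=tuple(stages),
        lights_off=lights_off,
        lights_on=lights_on,
    )


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`read_hypnogram` (round-trip exact)."""
    path = Path(path)
    rows = "\n".join(f"{i},{s}" for i, s in enumerate(h.stages))
    path.write_text("epoch_index,stage\n" + rows + "\n")


def align_and_filter(hypnograms: Sequence[Hypnogram], drop_u: bool = True) -> StagingSet:
    """Align several scorers of one recording onto a common retained epoch set.

    Scorers may stop staging a few epochs before one another at the end of a
    recording, so sequences are first truncated (at the end only) to the
    shortest scorer.  Then, if ``drop_u``, every epoch where any scorer
    assigned U is removed: each analysis uses only epochs staged by all
    scorers it considers.

    Raises
    ------
    ValueError
        Fewer than two hypnograms, or mismatched recording ids.
    EmptyStagingError
        No epoch survives filtering.
    """
    if len(hypnograms) < 2:
        raise ValueError("alignment requires at least two hypnograms")
    rec_ids = {h.recording_id for h in hypnograms}
    if len(rec_ids) != 1:
        raise ValueError(f"hypnograms from different recordings: {sorted(rec_ids)}")
    n = min(h.n_epochs for h in hypnograms)
    rows: list[tuple[str, ...]] = []
    kept: list[int] = []
    for i in range(n):
        row = tuple(h.stages[i] for h in hypnograms)
        if drop_u and UNSCORED in row:
            continue
        rows.append(row)
        kept.append(i)
    if not rows:
        raise EmptyStagingError(
            f"recording {hypnograms[0].recording_id}: no epochs retained after filtering"
        )
    return StagingSet(
        recording_id=hypnograms[0].recording_id,
        scorer_ids=tuple(h.scorer_id for h in hypnograms),
        aligned_stages=tuple(rows),
        retained_epoch_indices=tuple(kept),
    )
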