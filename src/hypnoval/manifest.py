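"""Study manifest: scorer roles, per-recording files and lights windows.

A validation study bundles, for each recording, hypnogram CSVs from one
automatic scorer, two or more manual scorers and optionally a clinical
reference scorer.  The manifest (YAML or JSON) ties them together::

    scorers:
      machine: automatic
      tech1: manual
      tech2: manual
      tech3: manual
      clinical: clinical
    bootstrap:
      n_resamples: 10000
      seed: 1234
    recordings:
      - recording_id: rec001
        lights_off: "22:14:30"
        lights_on: "05:45:30"
        files:
          machine: hypnograms/rec001_machine.csv
          ...

File paths are resolved relative to the manifest location.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .hypnogram import Hypnogram, read_hypnogram

__all__ = ["ManifestError", "RecordingEntry", "StudyManifest", "load_manifest"]

VALID_ROLES = ("automatic", "manual", "clinical")


class ManifestError(ValueError):
    """The manifest is structurally inconsistent."""


@dataclass(frozen=True)
class RecordingEntry:
    recording_id: str
    lights_off: str | None
    lights_on: str | None
    files: dict[str, Path]  # scorer_id -> hypnogram CSV

    def load(self, scorer_id: str) -> Hypnogram:
        return read_hypnogram(
            self.files[scorer_id],
            recording_id=self.recording_id,
            scorer_id=scorer_id,
            lights_off=self.lights_off,
            lights_on=self.lights_on,
        )


@dataclass(frozen=True)
class StudyManifest:
    scorers: dict[str, str]  # scorer_id -> role
    recordings: tuple[RecordingEntry, ...]
    bootstrap: dict = field(default_factory=dict)

    @property
    def automatic_scorer(self) -> str:
        return self._by_role("automatic")[0]

    @property
    def manual_scorers(self) -> tuple[str, ...]:
        return tuple(self._by_role("manual"))

    @property
    def clinical_scorer(self) -> str | None:
        ids = self._by_role("clinical")
        return ids[0] if ids else None

    def _by_role(self, role: str) -> list[str]:
        return [s for s, r in self.scorers.items() if r == role]

    def validate(self) -> None:
        """Raise :class:`ManifestError` on any structural inconsistency."""
        for s, role in self.scorers.items():
            if role not in VALID_ROLES:
                raise ManifestError(f"scorer {s!r}: unknown role {role!r}")
        if len(self._by_role("automatic")) != 1:
            raise ManifestError("exactly one automatic scorer is required")
        if len(self.manual_scorers) < 2:
            raise ManifestError("at least two manual scorers are required")
        if len(self._by_role("clinical")) > 1:
            raise ManifestError("at most one clinical scorer is allowed")
        if not self.recordings:
            raise ManifestError("manifest lists no recordings")
        for rec in self.recordings:
            missing = set(self.scorers) - set(rec.files)
            if missing:
                raise ManifestError(
                    f"recording {rec.recording_id}: missing files for {sorted(missing)}"
                )
            for scorer, path in rec.files.items():
                if not Path(path).exists():
                    raise ManifestError(
                        f"recording {rec.recording_id}: file not found for {scorer}: {path}"
                    )


def load_manifest(path: str | Path) -> StudyManifest:
    """Load and structurally validate a YAML/JSON study manifest."""
    path = Path(path)
    text = path.read_text()
    raw: Mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping) or "scorers" not in raw or "recordings" not in raw:
        raise ManifestError(f"{path}: manifest must define 'scorers' and 'recordings'")
    base = path.parent
    recordings = []
    for entry in raw["recordings"]:
        recordings.append(
            RecordingEntry(
                recording_id=str(entry["recording_id"]),
                lights_off=entry.get("lights_off"),
                lights_on=entry.get("lights_on"),
                files={s: base / p for s, p in entry["files"].items()},
            )
        )
    manifest = StudyManifest(
        scorers=dict(raw["scorers"]),
        recordings=tuple(recordings),
        bootstrap=dict(raw.get("bootstrap", {})),
    )
    manifest.validate()
    return manifest
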