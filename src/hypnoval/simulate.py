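"""Synthetic multi-rater hypnogram cohorts.

The study data this pipeline targets -- overnight polysomnograms staged by an
automatic scorer, several technicians and a clinical reference -- are rarely
shareable, so the generator emulates their statistical structure end to end:

* *Truth*: a first-order Markov chain over {W, N1, N2, N3, R} at 30-s epochs,
  with sticky self-transitions (geometric stage bouts of ~3 min by default)
  and a stationary stage mix typical of clinical cohorts (~21% W, 8% N1,
  40% N2, 17% N3, 14% R).  Recording lengths are drawn around 7.5 h in bed.
* *Raters*: each scorer reports, independently per epoch, a draw from the
  confusion row of the true stage (default: symmetric error), occasionally
  an unclassifiable U epoch, and may leave the last few epochs of a
  recording unstaged -- technicians who are blinded to lights-on times stop
  staging at slightly different end points.

Default error rates: technicians eps = 0.09, which yields pairwise
technician-technician agreement near 0.83 and three-rater full consensus
near 0.75 -- the levels reported for experienced scorers; the automatic
scorer uses eps = 0.10 and the clinical staging eps = 0.11 with a 1e-4 U
rate.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .hypnogram import STAGES, UNSCORED, Hypnogram, write_hypnogram

__all__ = [
    "SleepModel",
    "RaterModel",
    "symmetric_confusion",
    "default_sleep_model",
    "default_raters",
    "simulate_truth",
    "simulate_rater",
    "simulate_study",
]

_N = len(STAGES)


def _check_stochastic(m: np.ndarray, what: str) -> None:
    if m.shape != (_N, _N):
        raise ValueError(f"{what} must be {_N}x{_N}")
    if (m < 0).any():
        raise ValueError(f"{what} has negative entries")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"{what} rows must sum to 1")


@dataclass(frozen=True)
class SleepModel:
    """Markov truth model for one cohort.

    ``epochs_range`` is the inclusive range of epochs per recording (30 s
    each); ``lights_off_clock``/``lights_off_jitter_min`` set the nominal
    lights-off time and its uniform jitter in minutes.
    """

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    epochs_range: tuple[int, int] = (780, 1020)  # 6.5-8.5 h in bed
    lights_off_clock: str = "22:20:00"
    lights_off_jitter_min: float = 25.0

    def __post_init__(self) -> None:
        p = np.asarray(self.initial_probs, dtype=float)
        t = np.asarray(self.transition_matrix, dtype=float)
        if p.shape != (_N,) or (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_probs must be a distribution over the 5 stages")
        _check_stochastic(t, "transition_matrix")
        if self.epochs_range[0] < 1 or self.epochs_range[0] > self.epochs_range[1]:
            raise ValueError("invalid epochs_range")
        object.__setattr__(self, "initial_probs", p)
        object.__setattr__(self, "transition_matrix", t)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        return v / v.sum()


@dataclass(frozen=True)
class RaterModel:
    """Per-epoch independent mis-scoring model for one scorer.

    With probability ``u_prob`` the scorer reports U; otherwise the reported
    stage is drawn from ``confusion[true_stage]`` (rows sum to 1, so each
    row combined with ``u_prob`` normalises to 1 overall).  ``truncation``
    is the distribution of end-of-recording epochs left unstaged, given as
    (values, probabilities).
    """

    confusion: np.ndarray
    u_prob: float = 0.0
    truncation: tuple[tuple[int, ...], tuple[float, ...]] = ((0,), (1.0,))

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion, dtype=float)
        _check_stochastic(c, "confusion")
        if not 0.0 <= self.u_prob < 1.0:
            raise ValueError("u_prob must be in [0, 1)")
        vals, probs = self.truncation
        if len(vals) != len(probs) or not np.isclose(sum(probs), 1.0, atol=1e-12):
            raise ValueError("truncation (values, probs) must align and probs sum to 1")
        if any(v < 0 for v in vals):
            raise ValueError("truncation values must be non-negative")
        object.__setattr__(self, "confusion", c)


def symmetric_confusion(eps: float) -> np.ndarray:
    """Confusion with 1-eps on the diagonal and eps spread evenly off it."""
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    m = np.full((_N, _N), eps / (_N - 1))
    np.fill_diagonal(m, 1.0 - eps)
    return m


def default_sleep_model() -> SleepModel:
    """Sticky Markov chain whose stationary stage mix matches clinical cohorts."""
    pi = np.array([0.21, 0.08, 0.40, 0.17, 0.14])
    stickiness = 0.85
    transition = stickiness * np.eye(_N) + (1.0 - stickiness) * pi[None, :]
    initial = np.array([0.95, 0.05, 0.0, 0.0, 0.0])  # recordings start awake
    return SleepModel(initial_probs=initial, transition_matrix=transition)


def default_raters() -> dict[str, tuple[str, RaterModel]]:
    """Default study panel: scorer_id -> (role, RaterModel)."""
    tech_trunc = ((0, 1, 2, 3), (0.5, 0.25, 0.15, 0.1))
    return {
        "machine": ("automatic", RaterModel(symmetric_confusion(0.10))),
        "tech1": ("manual", RaterModel(symmetric_confusion(0.09), truncation=tech_trunc)),
        "tech2": ("manual", RaterModel(symmetric_confusion(0.09), truncation=tech_trunc)),
        "tech3": ("manual", RaterModel(symmetric_confusion(0.09), truncation=tech_trunc)),
        "clinical": ("clinical", RaterModel(symmetric_confusion(0.11), u_prob=1e-4)),
    }


def _clock_str(seconds_of_day: float) -> str:
    s = int(round(seconds_of_day)) % 86400
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def _clock_seconds(clock: str) -> int:
    h, m, s = (int(x) for x in clock.split(":"))
    return h * 3600 + m * 60 + s


def _markov_sequence(model: SleepModel, n_epochs: int, rng: np.random.Generator) -> np.ndarray:
    cum_init = np.cumsum(model.initial_probs)
    cum_trans = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = np.searchsorted(cum_init, u[0])
    for i in range(1, n_epochs):
        states[i] = np.searchsorted(cum_trans[states[i - 1]], u[i])
    return states


def simulate_truth(
    model: SleepModel, n_recordings: int, seed: int | np.random.SeedSequence
) -> list[Hypnogram]:
    """Ground-truth Markov hypnograms; ids rec001, rec002, ... in order."""
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_recordings):
        lo, hi = model.epochs_range
        n_epochs = int(rng.integers(lo, hi + 1))
        jitter = rng.uniform(-model.lights_off_jitter_min, model.lights_off_jitter_min) * 60
        off_s = _clock_seconds(model.lights_off_clock) + jitter
        states = _markov_sequence(model, n_epochs, rng)
        out.append(
            Hypnogram(
                recording_id=f"rec{r + 1:03d}",
                scorer_id="truth",
                stages=tuple(STAGES[s] for s in states),
                lights_off=_clock_str(off_s),
                lights_on=_clock_str(off_s + n_epochs * 30),
            )
        )
    return out


def simulate_rater(
    truth: Hypnogram,
    rater: RaterModel,
    seed: int | np.random.SeedSequence,
    scorer_id: str = "rater",
) -> Hypnogram:
    """One scorer's noisy staging of a true hypnogram."""
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(STAGES)}
    true_codes = np.array([idx[s] for s in truth.stages])
    cum = np.cumsum(rater.confusion, axis=1)
    u = rng.random(true_codes.size)
    reported = (u[:, None] > cum[true_codes]).sum(axis=1)
    stages = [STAGES[c] for c in reported]
    if rater.u_prob > 0:
        u_mask = rng.random(true_codes.size) < rater.u_prob
        stages = [UNSCORED if m else s for s, m in zip(stages, u_mask)]
    vals, probs = rater.truncation
    k = int(rng.choice(vals, p=probs))
    if k >= len(stages):
        k = len(stages) - 1  # never truncate a recording away entirely
    if k:
        stages = stages[:-k]
    return Hypnogram(
        recording_id=truth.recording_id,
        scorer_id=scorer_id,
        stages=tuple(stages),
        lights_off=truth.lights_off,
        lights_on=truth.lights_on,
    )


def simulate_study(
    out_dir: str | Path,
    n_recordings: int = 40,
    model: SleepModel | None = None,
    raters: Mapping[str, tuple[str, RaterModel]] | None = None,
    seed: int = 0,
    n_resamples: int = 10_000,
    write_truth: bool = False,
) -> Path:
    """Write a complete on-disk study (hypnogram CSVs + manifest); return manifest path.

    The default panel mirrors the target study design: 40 recordings scored
    by one automatic scorer, three technicians and one clinical reference.
    """
    model = model or default_sleep_model()
    raters = dict(raters or default_raters())
    out_dir = Path(out_dir)
    hyp_dir = out_dir / "hypnograms"
    hyp_dir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    truth_ss, raters_ss, boot_ss = root_ss.spawn(3)
    truths = simulate_truth(model, n_recordings, truth_ss)
    rater_seeds = raters_ss.spawn(n_recordings * len(raters))

    entries = []
    for r, truth in enumerate(truths):
        files = {}
        for j, (scorer_id, (_role, rmodel)) in enumerate(raters.items()):
            h = simulate_rater(truth, rmodel, rater_seeds[r * len(raters) + j], scorer_id)
            rel = f"hypnograms/{truth.recording_id}_{scorer_id}.csv"
            write_hypnogram(h, out_dir / rel)
            files[scorer_id] = rel
        if write_truth:
            rel = f"hypnograms/{truth.recording_id}_truth.csv"
            write_hypnogram(truth, out_dir / rel)
        entries.append(
            {
                "recording_id": truth.recording_id,
                "lights_off": truth.lights_off,
                "lights_on": truth.lights_on,
                "files": files,
            }
        )

    manifest = {
        "scorers": {s: role for s, (role, _m) in raters.items()},
        "bootstrap": {
            "n_resamples": n_resamples,
            "seed": int(boot_ss.generate_state(1)[0] % (2**31)),
        },
        "recordings": entries,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
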