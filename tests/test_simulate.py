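"""Synthetic cohort generator: determinism, calibration, parameter recovery."""

import numpy as np
import pytest

from hypnoval.hypnogram import STAGES, UNSCORED
from hypnoval.manifest import load_manifest
from hypnoval.simulate import (
    RaterModel,
    SleepModel,
    default_raters,
    default_sleep_model,
    simulate_rater,
    simulate_study,
    simulate_truth,
    symmetric_confusion,
)

N = len(STAGES)


class TestTruthModel:
    def test_identity_transition_freezes_initial_stage(self):
        model = SleepModel(
            initial_probs=np.array([0, 0, 1.0, 0, 0]),
            transition_matrix=np.eye(N),
            epochs_range=(30, 30),
        )
        (h,) = simulate_truth(model, 1, seed=0)
        assert set(h.stages) == {"N2"}

    def test_uniform_transition_gives_uniform_frequencies(self):
        model = SleepModel(
            initial_probs=np.full(N, 0.2),
            transition_matrix=np.full((N, N), 0.2),
            epochs_range=(100_000, 100_000),
        )
        (h,) = simulate_truth(model, 1, seed=1)
        freqs = np.array([h.stages.count(s) for s in STAGES]) / h.n_epochs
        np.testing.assert_allclose(freqs, 0.2, atol=0.01)

    def test_same_seed_identical_cohorts(self):
        model = default_sleep_model()
        a = simulate_truth(model, 4, seed=9)
        b = simulate_truth(model, 4, seed=9)
        assert [h.stages for h in a] == [h.stages for h in b]
        assert [h.lights_off for h in a] == [h.lights_off for h in b]
        c = simulate_truth(model, 4, seed=10)
        assert [h.stages for h in a] != [h.stages for h in c]

    def test_default_model_stationary_mix(self):
        model = default_sleep_model()
        pi = model.stationary_distribution()
        np.testing.assert_allclose(pi, [0.21, 0.08, 0.40, 0.17, 0.14], atol=1e-9)

    def test_invalid_stochastic_matrix_rejected(self):
        bad = np.full((N, N), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            SleepModel(initial_probs=np.full(N, 0.2), transition_matrix=bad)
        with pytest.raises(ValueError, match="distribution"):
            SleepModel(initial_probs=np.full(N, 0.3), transition_matrix=np.eye(N))


class TestRaterModel:
    @pytest.fixture()
    def long_truth(self):
        model = default_sleep_model()
        model = SleepModel(
            initial_probs=model.initial_probs,
            transition_matrix=model.transition_matrix,
            epochs_range=(50_000, 50_000),
        )
        return simulate_truth(model, 1, seed=3)[0]

    def test_identity_confusion_is_exact_copy(self, long_truth):
        h = simulate_rater(long_truth, RaterModel(np.eye(N)), seed=0)
        assert h.stages == long_truth.stages

    def test_symmetric_error_rate_matches_analytic_opa(self, long_truth):
        h = simulate_rater(long_truth, RaterModel(symmetric_confusion(0.10)), seed=4)
        opa = np.mean([a == b for a, b in zip(long_truth.stages, h.stages)])
        assert opa == pytest.approx(0.90, abs=0.005)

    def test_u_injection_rate(self, long_truth):
        h = simulate_rater(long_truth, RaterModel(np.eye(N), u_prob=0.05), seed=5)
        u_rate = h.stages.count(UNSCORED) / h.n_epochs
        assert u_rate == pytest.approx(0.05, abs=0.005)

    def test_truncation_removes_trailing_epochs(self, long_truth):
        rater = RaterModel(np.eye(N), truncation=((3,), (1.0,)))
        h = simulate_rater(long_truth, rater, seed=6)
        assert h.n_epochs == long_truth.n_epochs - 3
        assert h.stages == long_truth.stages[:-3]

    def test_invalid_rater_models_rejected(self):
        with pytest.raises(ValueError):
            RaterModel(np.full((N, N), 0.1))
        with pytest.raises(ValueError):
            RaterModel(np.eye(N), u_prob=1.5)
        with pytest.raises(ValueError):
            RaterModel(np.eye(N), truncation=((1, 2), (0.4, 0.4)))

    def test_three_rater_full_consensus_matches_closed_form(self):
        """Under symmetric per-rater error eps, the chance all three raters
        report the same stage is (1-eps)^3 + 4*(eps/4)^3 regardless of the
        stage mix; at eps = 0.09 that is ~0.7536, near observed technician
        panels (~0.75)."""
        eps = 0.09
        closed_form = (1 - eps) ** 3 + 4 * (eps / 4) ** 3
        assert closed_form == pytest.approx(0.7536, abs=1e-4)

        model = default_sleep_model()
        truths = simulate_truth(
            SleepModel(model.initial_probs, model.transition_matrix,
                       epochs_range=(20_000, 20_000)),
            1, seed=12,
        )
        raters = [
            simulate_rater(truths[0], RaterModel(symmetric_confusion(eps)), seed=s)
            for s in (21, 22, 23)
        ]
        full = np.mean([
            len({a, b, c}) == 1
            for a, b, c in zip(*(r.stages for r in raters))
        ])
        # Monte Carlo at 20,000 epochs: 3 sigma ~ 0.009
        assert full == pytest.approx(closed_form, abs=0.01)


class TestStudyWriter:
    def test_written_study_loads_and_validates(self, tmp_path):
        manifest_path = simulate_study(tmp_path, n_recordings=3, seed=2,
                                       n_resamples=100)
        manifest = load_manifest(manifest_path)
        assert len(manifest.recordings) == 3
        assert manifest.automatic_scorer == "machine"
        assert manifest.manual_scorers == ("tech1", "tech2", "tech3")
        assert manifest.clinical_scorer == "clinical"
        h = manifest.recordings[0].load("tech1")
        assert h.n_epochs > 0
        assert manifest.bootstrap["n_resamples"] == 100

    def test_same_seed_reproduces_files_byte_identically(self, tmp_path):
        p1 = simulate_study(tmp_path / "a", n_recordings=2, seed=5)
        p2 = simulate_study(tmp_path / "b", n_recordings=2, seed=5)
        for f1 in sorted((tmp_path / "a").rglob("*.csv")):
            f2 = tmp_path / "b" / f1.relative_to(tmp_path / "a")
            assert f1.read_bytes() == f2.read_bytes()
        assert p1.read_text() == p2.read_text()

    def test_different_seeds_differ_with_same_schema(self, tmp_path):
        simulate_study(tmp_path / "a", n_recordings=2, seed=1)
        simulate_study(tmp_path / "b", n_recordings=2, seed=2)
        a = sorted(p.name for p in (tmp_path / "a" / "hypnograms").iterdir())
        b = sorted(p.name for p in (tmp_path / "b" / "hypnograms").iterdir())
        assert a == b  # same layout
        stages_a = (tmp_path / "a" / "hypnograms" / a[0]).read_text()
        stages_b = (tmp_path / "b" / "hypnograms" / a[0]).read_text()
        assert stages_a != stages_b

    def test_default_raters_roles(self):
        raters = default_raters()
        roles = [role for role, _ in raters.values()]
        assert roles.count("automatic") == 1
        assert roles.count("manual") == 3
        assert roles.count("clinical") == 1
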