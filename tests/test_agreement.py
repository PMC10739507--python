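"""Confusion matrices, OPA, kappa, PPA/NPA/PPV and panel averages."""

import math
from collections import Counter

import numpy as np
import pytest

from hypnoval.agreement import (
    STAT_NAMES,
    AgreementStats,
    ConfusionMatrix,
    agreement_stats,
    build_confusion,
    cohens_kappa,
    directional_panel_averages,
    overall_percent_agreement,
    per_stage_stats,
    stats_vector,
)
from hypnoval.hypnogram import STAGES, StagingSet


def _random_matrix(rng, max_count=30):
    return ConfusionMatrix(rng.integers(0, max_count, size=(5, 5)))


def _panel_from_columns(cols: dict):
    names = tuple(cols)
    n = len(next(iter(cols.values())))
    return StagingSet(
        recording_id="r",
        scorer_ids=names,
        aligned_stages=tuple(tuple(cols[s][i] for s in names) for i in range(n)),
        retained_epoch_indices=tuple(range(n)),
    )


class TestBuildConfusion:
    def test_basic_cross_tabulation(self):
        m = build_confusion(["W", "W", "N1"], ["W", "N1", "N1"])
        assert m.counts[0, 0] == 1 and m.counts[0, 1] == 1 and m.counts[1, 1] == 1
        assert m.grand_total == 3

    def test_identical_sequences_are_diagonal(self):
        seq = ["W", "N1", "N2", "N3", "R", "N2"]
        m = build_confusion(seq, seq)
        assert np.trace(m.counts) == len(seq)
        assert m.counts.sum() == np.trace(m.counts)

    def test_random_sequences_recounted_independently(self, rng):
        ref = rng.choice(STAGES, size=1000)
        test = rng.choice(STAGES, size=1000)
        m = build_confusion(ref, test)
        tally = Counter(zip(ref, test))
        for i, r in enumerate(STAGES):
            for j, t in enumerate(STAGES):
                assert m.counts[i, j] == tally[(r, t)]
        assert m.grand_total == 1000
        ref_freq = Counter(ref)
        assert all(m.row_totals[i] == ref_freq[s] for i, s in enumerate(STAGES))

    def test_length_mismatch_and_u_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_confusion(["W"], ["W", "N1"])
        with pytest.raises(ValueError, match="U stage"):
            build_confusion(["U"], ["W"])

    def test_pooling_equals_concatenation(self, rng):
        a_ref, a_test = rng.choice(STAGES, 200), rng.choice(STAGES, 200)
        b_ref, b_test = rng.choice(STAGES, 300), rng.choice(STAGES, 300)
        pooled = build_confusion(a_ref, a_test) + build_confusion(b_ref, b_test)
        concat = build_confusion(
            np.concatenate([a_ref, b_ref]), np.concatenate([a_test, b_test])
        )
        assert np.array_equal(pooled.counts, concat.counts)


class TestScalarStats:
    def test_opa_diagonal_is_one(self):
        m = ConfusionMatrix(np.diag([3, 1, 4, 1, 5]))
        assert overall_percent_agreement(m) == 1.0

    def test_opa_two_label_hand_value(self):
        m = ConfusionMatrix(np.array([[2, 1], [1, 6]]), labels=("A", "B"))
        assert overall_percent_agreement(m) == pytest.approx(0.8)

    def test_opa_from_published_pooled_counts(self, majority_reference):
        m = ConfusionMatrix(majority_reference["counts"])
        assert round(overall_percent_agreement(m), 4) == 0.8677

    def test_kappa_hand_value(self):
        m = ConfusionMatrix(np.array([[2, 1], [1, 6]]), labels=("A", "B"))
        # po = 0.8, pe = (3*3 + 7*7)/100 = 0.58 -> kappa = 0.22/0.42
        assert cohens_kappa(m) == pytest.approx(0.22 / 0.42)

    def test_kappa_perfect_agreement(self):
        assert cohens_kappa(ConfusionMatrix(np.diag([3, 1, 4, 1, 5]))) == pytest.approx(1.0)

    def test_kappa_degenerate_constant_scorers_is_undefined(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 50  # both scorers always W -> pe = 1
        assert math.isnan(cohens_kappa(ConfusionMatrix(counts)))

    def test_per_stage_hand_values(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 3  # TP for W
        counts[0, 1] = 1  # ref W total 4
        counts[1, 0] = 2  # test W total 5
        counts[2, 2] = 4  # N = 10
        st = per_stage_stats(ConfusionMatrix(counts), "W")
        assert st["ppa"] == pytest.approx(0.75)
        assert st["ppv"] == pytest.approx(0.6)
        assert st["npa"] == pytest.approx((10 - 4 - 5 + 3) / 6)

    def test_per_stage_undefined_on_zero_denominators(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[2, 2] = 10  # N2 only
        st = per_stage_stats(ConfusionMatrix(counts), "W")
        assert math.isnan(st["ppa"]) and math.isnan(st["ppv"])
        assert st["npa"] == pytest.approx(1.0)  # no W anywhere: all true negatives

    def test_perfect_two_label_matrix_all_ones(self):
        m = ConfusionMatrix(np.diag([4, 6]), labels=("A", "B"))
        for s in ("A", "B"):
            assert per_stage_stats(m, s) == {"ppa": 1.0, "npa": 1.0, "ppv": 1.0}


class TestInvariants:
    def test_transpose_duality_and_symmetry(self, rng):
        for _ in range(200):
            m = _random_matrix(rng)
            if m.grand_total == 0:
                continue
            t = m.T
            assert overall_percent_agreement(m) == pytest.approx(
                overall_percent_agreement(t))
            k1, k2 = cohens_kappa(m), cohens_kappa(t)
            assert (math.isnan(k1) and math.isnan(k2)) or k1 == pytest.approx(k2)
            for s in STAGES:
                a, b = per_stage_stats(m, s), per_stage_stats(t, s)
                for x, y in ((a["ppa"], b["ppv"]), (a["npa"], a["npa"])):
                    assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)

    def test_marginal_consistency_and_tp_bound(self, rng):
        for _ in range(100):
            m = _random_matrix(rng)
            assert m.row_totals.sum() == m.col_totals.sum() == m.grand_total
            for i in range(5):
                assert m.counts[i, i] <= min(m.row_totals[i], m.col_totals[i])

    def test_kappa_never_exceeds_one(self, rng):
        for _ in range(300):
            m = _random_matrix(rng)
            if m.grand_total == 0:
                continue
            k = cohens_kappa(m)
            assert math.isnan(k) or k <= 1.0 + 1e-12

    def test_kappa_is_rescaled_opa_under_uniform_marginals(self):
        # uniform marginals over L labels give pe = 1/L, so
        # kappa = (OPA - 1/L) / (1 - 1/L)
        counts = np.array([[2, 1], [1, 2]])
        m = ConfusionMatrix(counts, labels=("A", "B"))
        opa = overall_percent_agreement(m)
        assert cohens_kappa(m) == pytest.approx((opa - 0.5) / 0.5)

    def test_stats_vector_matches_objectwise_path(self, rng):
        for _ in range(50):
            m = _random_matrix(rng)
            if m.grand_total == 0 or (m.row_totals == 0).any():
                continue
            v = stats_vector(m.counts)
            w = agreement_stats(m).to_vector()
            np.testing.assert_allclose(v, w, equal_nan=True)
        assert len(STAT_NAMES) == 17


class TestPanelAverages:
    def test_identical_raters_average_to_one(self):
        seq = ["W", "N1", "N2", "N3", "R", "N2", "W"]
        panel = _panel_from_columns({"t1": seq, "t2": seq, "t3": seq, "m": seq})
        within, machine = directional_panel_averages(panel, machine_column="m")
        for stats in (within, machine):
            assert stats.opa == pytest.approx(1.0)
            assert stats.kappa == pytest.approx(1.0)
            for s in STAGES:
                for key in ("ppa", "npa", "ppv"):
                    assert stats.per_stage[s][key] == pytest.approx(1.0)

    def test_within_panel_ppa_equals_ppv_duality(self, rng):
        cols = {f"t{i}": rng.choice(STAGES, 400) for i in range(3)}
        within, _ = directional_panel_averages(_panel_from_columns(cols))
        for s in STAGES:
            # PPA of A referenced on B is PPV of B referenced on A, and the
            # ordered-pair average runs over both orders of every pair
            assert within.per_stage[s]["ppa"] == pytest.approx(
                within.per_stage[s]["ppv"])

    def test_constructed_pairwise_opas_average(self):
        cols = {
            "t1": ["W", "W", "W", "W"],
            "t2": ["W", "W", "W", "N1"],
            "t3": ["N2", "W", "N2", "N1"],
        }
        pair_opas = {
            (a, b): np.mean(np.array(cols[a]) == np.array(cols[b]))
            for a in cols for b in cols if a != b
        }
        assert sorted(set(pair_opas.values())) == [0.25, 0.5, 0.75]
        within, _ = directional_panel_averages(_panel_from_columns(cols))
        assert within.opa == pytest.approx(0.5)

    def test_undefined_contributors_skipped_and_reported(self):
        # no rater ever assigns N3: N3 PPA undefined for every ordered pair
        cols = {"t1": ["W", "N1"], "t2": ["W", "N2"], "t3": ["W", "N1"]}
        within, _ = directional_panel_averages(_panel_from_columns(cols))
        assert math.isnan(within.per_stage["N3"]["ppa"])
        assert within.n_undefined["N3_ppa"] == 6

    def test_machine_direction_is_test_column(self):
        # machine perfectly copies t1 -> machine-vs-panel equals the average
        # of each technician referenced against t1
        cols = {
            "t1": ["W", "N1", "N2", "R", "N3"],
            "t2": ["W", "N1", "N2", "N2", "N3"],
            "t3": ["W", "W", "N2", "R", "N3"],
        }
        cols["m"] = cols["t1"]
        _, machine = directional_panel_averages(
            _panel_from_columns(cols), machine_column="m")
        expected = np.nanmean(
            [stats_vector(build_confusion(cols[t], cols["t1"]).counts)
             for t in ("t1", "t2", "t3")], axis=0)
        np.testing.assert_allclose(machine.to_vector(), expected, equal_nan=True)
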