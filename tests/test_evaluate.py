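"""Cross-validation protocols, ablations, and compliance analytics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scrubstep import (
    HygieneSession,
    Instruction,
    LabelTrack,
    Mode,
    Placement,
    StepLabel,
    bootstrap_curve,
    compliance_matrix,
    duration_summary,
    frame_accuracy,
    learning_curve,
    lopo_cv,
    loso_cv,
    placement_sets,
    sensor_ablation,
)
from scrubstep.evaluate import FeatureCache, group_by_participant, placement_ablation
from scrubstep.labels import canonical_order

from conftest import fast_pipeline_config


class TestFrameAccuracy:
    def test_identical_streams(self):
        x = np.array([1, 2, 3])
        assert frame_accuracy(x, x) == 1.0

    def test_complementary_streams(self):
        assert frame_accuracy(np.array([1, 1]), np.array([2, 2])) == 0.0

    def test_none_windows_excluded_from_denominator(self):
        true = np.array([1, 2, 3, 4, int(StepLabel.NONE)])
        pred = np.array([1, 2, 3, 9, 9])
        assert frame_accuracy(pred, true) == 0.75

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            frame_accuracy(np.array([1]), np.array([1, 2]))


@pytest.fixture(scope="module")
def shared_cache():
    return FeatureCache()


class TestProtocols:
    def test_loso_fold_count_and_order_invariance(self, tiny_cohort, shared_cache):
        sessions = [s for s in tiny_cohort if s.participant_id == "P01"]
        cfg = fast_pipeline_config()
        rep = loso_cv(sessions, cfg, shared_cache)
        assert len(rep.per_unit) == len(sessions)
        rep2 = loso_cv(sessions[::-1], cfg, shared_cache)
        assert rep.mean_accuracy == pytest.approx(rep2.mean_accuracy)

    def test_loso_needs_two_sessions(self, tiny_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            loso_cv(tiny_cohort[:1], fast_pipeline_config())

    def test_lopo_one_fold_per_participant(self, tiny_cohort, shared_cache):
        rep = lopo_cv(tiny_cohort, fast_pipeline_config(), shared_cache)
        assert set(rep.per_unit) == {"P01", "P02"}
        assert 0.0 <= rep.mean_accuracy <= 1.0

    def test_confusion_row_sums_match_window_counts(self, tiny_cohort, shared_cache):
        rep = lopo_cv(tiny_cohort, fast_pipeline_config(), shared_cache)
        assert rep.confusion.sum() > 0
        assert np.all(rep.confusion >= 0)

    def test_end_to_end_determinism(self, tiny_cohort, shared_cache):
        sessions = [s for s in tiny_cohort if s.participant_id == "P02"]
        cfg = fast_pipeline_config(seed=9)
        a = loso_cv(sessions, cfg, shared_cache)
        b = loso_cv(sessions, cfg, shared_cache)
        assert a.per_unit == b.per_unit
        np.testing.assert_array_equal(a.confusion, b.confusion)


class TestBootstrap:
    def test_same_seed_gives_identical_curves(self, tiny_cohort, shared_cache):
        sessions = [s for s in tiny_cohort if s.participant_id == "P01"]
        cfg = fast_pipeline_config()
        a = bootstrap_curve(sessions, cfg, Ns=[1, 3], reps=2, seed=4,
                            cache=shared_cache)
        b = bootstrap_curve(sessions, cfg, Ns=[1, 3], reps=2, seed=4,
                            cache=shared_cache)
        assert a == b
        assert set(a) == {1, 3}

    def test_oversized_n_skipped_with_warning(self, tiny_cohort, shared_cache):
        sessions = [s for s in tiny_cohort if s.participant_id == "P01"]
        with pytest.warns(UserWarning, match="skipped"):
            out = bootstrap_curve(sessions, fast_pipeline_config(),
                                  Ns=[1, 99], reps=1, seed=0, cache=shared_cache)
        assert 99 not in out


class TestAblations:
    def test_placement_sets_enumerated(self):
        sets = placement_sets()
        assert len(sets) == 8
        assert (Placement.LF, Placement.RF) in sets

    def test_placement_ablation_structure(self, tiny_cohort, shared_cache):
        cfg = fast_pipeline_config(
            smooth_params={"R": 19, "min_size": 10})
        df = placement_ablation(tiny_cohort, cfg, protocol="lopo",
                                cache=shared_cache)
        assert df.shape == (8, 2)
        assert set(df.columns) == {"raw", "smoothed"}
        assert df.notna().all().all()

    def test_missing_placement_rejected(self, tiny_cohort):
        crippled = HygieneSession(
            participant_id="PX", mode=tiny_cohort[0].mode,
            instruction=tiny_cohort[0].instruction,
            devices={Placement.RF: tiny_cohort[0].devices[Placement.RF]},
            labels=tiny_cohort[0].labels,
        )
        with pytest.raises(ValueError, match="missing placements"):
            placement_ablation([crippled] + list(tiny_cohort),
                               fast_pipeline_config())

    def test_sensor_ablation_enumerates_six_combos(self, tiny_cohort, shared_cache):
        df = sensor_ablation(tiny_cohort, fast_pipeline_config(),
                             cache=shared_cache)
        assert list(df.index) == [
            "ACC", "GYRO", "EMG", "ACC+GYRO", "ACC+GYRO+ORI", "ACC+GYRO+ORI+EMG"]
        assert df["mean_accuracy"].between(0, 1).all()


def _track(labels, step_s=2.0):
    intervals = []
    t = 0.0
    for lab in labels:
        intervals.append((t, t + step_s, lab))
        t += step_s
    return LabelTrack(intervals)


class TestCompliance:
    def test_canonical_track_gives_identity_and_full_compliance(self):
        track = _track(canonical_order(Mode.HANDRUB))
        cm = compliance_matrix([track], Mode.HANDRUB)
        assert cm.compliance == 1.0
        diag = [cm.counts.loc[l.name, l.name] for l in canonical_order(Mode.HANDRUB)]
        assert diag == [1] * 11
        assert cm.counts.to_numpy().sum() == 11

    def test_swapped_symmetric_pair_shows_off_diagonal(self):
        steps = canonical_order(Mode.HANDRUB)
        i, j = steps.index(StepLabel.S6R_THUMB), steps.index(StepLabel.S6L_THUMB)
        steps[i], steps[j] = steps[j], steps[i]
        cm = compliance_matrix([_track(steps)], Mode.HANDRUB)
        assert cm.counts.loc["S6R_THUMB", "S6L_THUMB"] == 1
        assert cm.counts.loc["S6L_THUMB", "S6R_THUMB"] == 1
        assert cm.compliance == pytest.approx(9 / 11)

    def test_missed_step_lands_in_missed_column(self):
        steps = [s for s in canonical_order(Mode.HANDRUB)
                 if s is not StepLabel.S5L_KNUCKLES]
        cm = compliance_matrix([_track(steps)], Mode.HANDRUB)
        assert cm.counts.loc["S5L_KNUCKLES", "MISSED"] == 1
        assert cm.compliance == pytest.approx(10 / 11)

    def test_empty_track_counts_all_missed(self):
        cm = compliance_matrix([LabelTrack([])], Mode.HANDWASH)
        assert cm.counts["MISSED"].sum() == 13
        assert cm.compliance == 0.0

    def test_row_sums_equal_sessions_scored(self):
        tracks = [_track(canonical_order(Mode.HANDWASH)) for _ in range(5)]
        cm = compliance_matrix(tracks, Mode.HANDWASH)
        assert (cm.counts.sum(axis=1) == 5).all()


def _label_only_session(mode, instruction, total_s, index=0, pid="P01"):
    steps = canonical_order(mode)
    step_s = total_s / len(steps)
    return HygieneSession(
        participant_id=pid, mode=mode, instruction=instruction,
        devices={}, labels=_track(steps, step_s), meta={"session_index": index},
    )


class TestDurations:
    def test_single_session_known_span(self):
        s = _label_only_session(Mode.HANDRUB, Instruction.VIDEO, 33.0)
        df = duration_summary([s])
        row = df.iloc[0]
        assert row["mean_s"] == pytest.approx(33.0)
        assert row["sd_s"] == 0.0 and row["n"] == 1

    def test_empty_condition_omitted(self):
        s = _label_only_session(Mode.HANDRUB, Instruction.VIDEO, 30.0)
        df = duration_summary([s])
        assert len(df) == 1

    def test_simulated_handwash_video_mean_near_target(self):
        """Simulated durations, summarized per condition, reproduce the
        53.4 s handwash/video mean within 2 standard errors."""
        from scrubstep import SimulationConfig, sample_step_sequence

        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        sessions = []
        for i in range(200):
            seq = sample_step_sequence(Mode.HANDWASH, cfg, rng,
                                       instruction=Instruction.VIDEO)
            intervals, t = [], 0.0
            for lab, d in seq:
                intervals.append((t, t + d, lab))
                t += d
            sessions.append(HygieneSession(
                "P01", Mode.HANDWASH, Instruction.VIDEO, {},
                LabelTrack(intervals), {"session_index": i}))
        df = duration_summary(sessions)
        row = df.iloc[0]
        se = row["sd_s"] / np.sqrt(row["n"])
        assert abs(row["mean_s"] - 53.4) <= 2 * se


class TestLearningCurve:
    def test_single_participant_curve_is_per_session_compliance(self):
        s0 = _label_only_session(Mode.HANDRUB, Instruction.VIDEO, 30.0, index=0)
        steps = [s for s in canonical_order(Mode.HANDRUB)
                 if s is not StepLabel.S2_PALM]
        s1 = HygieneSession("P01", Mode.HANDRUB, Instruction.POSTER, {},
                            _track(steps), {"session_index": 1})
        curve = learning_curve([s0, s1])
        assert curve[0] == 1.0
        assert curve[1] == pytest.approx(10 / 11)

    def test_empty_cohort_gives_empty_curve(self):
        assert learning_curve([]) == {}

    def test_constant_rates_give_flat_curve(self, tiny_cohort):
        curve = learning_curve(tiny_cohort)
        vals = np.array(list(curve.values()))
        assert vals.min() >= 0.5  # no trend, high compliance throughout
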