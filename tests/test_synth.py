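"""Simulator: grammars, calibration, signal structure, reproducibility."""

import numpy as np
import pytest

from scrubstep import (
    HANDRUB_ORDER,
    Mode,
    ParticipantProfile,
    Placement,
    SimulationConfig,
    StepLabel,
    default_signal_models,
    generate_cohort,
    position_match_rate,
    sample_step_sequence,
    synthesize_channels,
    validate_session,
)
from scrubstep.labels import Instruction

from conftest import fast_sim_config, noiseless_models


class TestStepSequences:
    def test_degenerate_grammar_is_canonical(self):
        cfg = SimulationConfig(p_swap=0.0, p_miss=0.0)
        seq = sample_step_sequence(Mode.HANDRUB, cfg, 0)
        assert [s for s, _ in seq] == HANDRUB_ORDER
        assert len(seq) == 11

    def test_all_missed_gives_empty_sequence(self):
        cfg = SimulationConfig(p_miss=1.0)
        assert sample_step_sequence(Mode.HANDWASH, cfg, 0) == []

    def test_durations_positive_and_sum_to_total(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = sample_step_sequence(Mode.HANDWASH, cfg, rng,
                                       instruction=Instruction.VIDEO)
            durs = np.array([d for _, d in seq])
            assert np.all(durs > 0.5)

    def test_position_match_rate_calibrated_to_compliance_target(self):
        """Default p_swap/p_miss give ~91 % canonical position compliance
        (direct-counting oracle over both grammars)."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(7)
        rates = []
        for i in range(10_000):
            mode = Mode.HANDRUB if i % 2 == 0 else Mode.HANDWASH
            seq = sample_step_sequence(mode, cfg, rng)
            rates.append(position_match_rate([s for s, _ in seq], mode))
        assert 0.89 <= np.mean(rates) <= 0.93

    def test_session_duration_mean_matches_condition_model(self):
        """Handwash/video total durations concentrate on the configured
        53.4 s mean (within 2 standard errors over 300 draws)."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(3)
        totals = [
            sum(d for _, d in sample_step_sequence(
                Mode.HANDWASH, cfg, rng, instruction=Instruction.VIDEO))
            for _ in range(300)
        ]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 53.4) <= 2 * se


class TestChannelSynthesis:
    def test_noiseless_single_step_accel_is_pure_sinusoid(self):
        models = noiseless_models()
        cfg = SimulationConfig()
        profile = ParticipantProfile("P")
        seq = [(StepLabel.S2_PALM, 10.0)]
        cs = synthesize_channels(seq, Placement.RF, profile, models, cfg, 0)
        x = cs.accel.values[:, 0] - cs.accel.values[:, 0].mean()
        freqs = np.fft.rfftfreq(x.size, d=1 / 50.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        expect = models[StepLabel.S2_PALM].oscillation_hz
        assert abs(peak - expect) <= freqs[1]  # within one FFT bin

    def test_same_seed_reproduces_arrays(self):
        models = default_signal_models()
        cfg = SimulationConfig()
        profile = ParticipantProfile("P")
        seq = [(StepLabel.S2_PALM, 3.0), (StepLabel.S4_INTERLOCK, 3.0)]
        a = synthesize_channels(seq, Placement.LF, profile, models, cfg, 42)
        b = synthesize_channels(seq, Placement.LF, profile, models, cfg, 42)
        np.testing.assert_array_equal(a.accel.values, b.accel.values)
        np.testing.assert_array_equal(a.emg.values, b.emg.values)

    def test_output_rates_are_exact(self):
        cs = synthesize_channels(
            [(StepLabel.S2_PALM, 4.0)], Placement.RF, ParticipantProfile("P"),
            default_signal_models(), SimulationConfig(), 0)
        assert cs.accel.t.size == 200 and cs.emg.t.size == 800
        np.testing.assert_allclose(np.diff(cs.accel.t), 1 / 50.0)
        np.testing.assert_allclose(np.diff(cs.emg.t), 1 / 200.0)

    def test_forearm_snr_exceeds_arm_snr(self):
        """ARM placements get attenuated signal and amplified noise, so the
        per-channel SNR (clean variance / residual variance, computed by
        re-synthesizing the same seed noiselessly) must drop."""
        cfg = SimulationConfig()
        models = default_signal_models()
        clean_models = noiseless_models()
        profile = ParticipantProfile("P")
        seq = [(StepLabel.S2_PALM, 5.0), (StepLabel.S4_INTERLOCK, 5.0)]

        def snr(placement):
            full = synthesize_channels(seq, placement, profile, models, cfg, 9)
            clean = synthesize_channels(seq, placement, profile, clean_models, cfg, 9)
            sig = clean.accel.values.var(axis=0)
            noise = (full.accel.values - clean.accel.values).var(axis=0)
            return sig / noise

        assert np.all(snr(Placement.RF) > snr(Placement.RA))


class TestCohort:
    def test_default_condition_counts_give_600_sessions(self):
        """20 participants x (5+10+5+10) sessions; short durations keep the
        check cheap, the session count is what matters."""
        cfg = fast_sim_config(n_participants=20, seed=0, duration_s=7.0)
        cfg.sessions_per_condition = SimulationConfig().sessions_per_condition
        cfg.placements = (Placement.RF,)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 600
        assert len({s.participant_id for s in cohort}) == 20

    def test_one_session_per_condition_gives_four(self):
        cfg = fast_sim_config(n_participants=1, sessions_per_condition=1)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 4
        assert {(s.mode, s.instruction) for s in cohort} == {
            (m, i) for m in Mode for i in Instruction}

    def test_same_seed_gives_identical_label_tracks(self):
        cfg = fast_sim_config(seed=13)
        a = generate_cohort(cfg)
        b = generate_cohort(fast_sim_config(seed=13))
        for sa, sb in zip(a, b):
            assert sa.labels.intervals == sb.labels.intervals

    def test_generated_sessions_are_valid(self, tiny_cohort):
        for s in tiny_cohort[:4]:
            assert validate_session(s) == []

    def test_label_span_equals_duration_sum(self, tiny_cohort):
        for s in tiny_cohort:
            span = s.labels.span
            stream_end = s.devices[Placement.RF].accel.t[-1] + 1 / 50.0
            assert abs(span - stream_end) <= 1 / 25.0


class TestSeparability:
    def test_nearest_centroid_on_noiseless_windows_is_perfect(self):
        """Noiseless classes are linearly separable on per-window mean and
        variance features (steady-state windows; cross-fades excluded)."""
        from scrubstep import (
            combine_placements, resample_to_common_rate, slide_windows,
            zscore_normalize,
        )
        cfg = fast_sim_config(duration_s=14.0)
        models = noiseless_models()
        profile = ParticipantProfile("P")
        seq = sample_step_sequence(Mode.HANDWASH, SimulationConfig(p_swap=0, p_miss=0),
                                   0, instruction=Instruction.POSTER)
        seq = [(lab, 1.5) for lab, _ in seq]

        def feats(seed):
            cs = synthesize_channels(seq, Placement.RF, profile, models, cfg, seed)
            from scrubstep.sessions import LabelTrack
            bounds = np.cumsum([0] + [d for _, d in seq])
            track = LabelTrack([(bounds[i], bounds[i + 1], seq[i][0])
                                for i in range(len(seq))])
            rs = zscore_normalize(resample_to_common_rate(cs, Placement.RF))
            ws = slide_windows(rs, track)
            starts = np.array([s for s, _ in ws.windows])
            idx = starts[:, None] + np.arange(5)[None, :]
            cube = rs.matrix[:, idx]
            X = np.concatenate([cube.mean(-1), cube.var(-1)]).T
            # steady-state windows only: at least 0.5 s past each boundary
            t = ws.centers()
            keep = np.ones(len(ws), bool)
            for b in bounds[1:-1]:
                keep &= ~((t >= b - 0.2) & (t <= b + 0.5))
            return X[keep], ws.labels[keep]

        Xtr, ytr = feats(1)
        Xte, yte = feats(2)
        cents = {c: Xtr[ytr == c].mean(axis=0) for c in np.unique(ytr)}
        keys = sorted(cents)
        C = np.stack([cents[c] for c in keys])
        pred = np.array(keys)[np.argmin(
            ((Xte[:, None, :] - C[None]) ** 2).sum(-1), axis=1)]
        assert np.mean(pred == yte) == 1.0
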