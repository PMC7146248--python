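"""Energy statistic, divisive change-point detection, and smoothing.

The energy statistic is checked against an independent brute-force
pairwise-distance oracle that shares no code with the implementation.
"""

import numpy as np
import pytest

from scrubstep import (
    PredictionStream,
    StepLabel,
    best_split,
    e_divisive,
    energy_divergence,
    smooth_predictions,
)


def brute_force_energy(X, Y, alpha=1.0):
    """Independent oracle: plain double loops over the defining sums."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[0] == 1 and X.size > 1 and X.shape[1] != Y.shape[1]:
        X = X.T
    m, n = len(X), len(Y)
    between = sum(
        np.linalg.norm(X[i] - Y[j]) ** alpha for i in range(m) for j in range(n)
    )
    e = 2.0 * between / (m * n)
    if m > 1:
        within = sum(np.linalg.norm(X[i] - X[k]) ** alpha
                     for i in range(m) for k in range(i + 1, m))
        e -= within / (m * (m - 1) / 2)
    if n > 1:
        within = sum(np.linalg.norm(Y[j] - Y[k]) ** alpha
                     for j in range(n) for k in range(j + 1, n))
        e -= within / (n * (n - 1) / 2)
    return e, (m * n / (m + n)) * e


def brute_force_best_split(x, alpha, min_size):
    """Oracle split scan: evaluate q-hat at every admissible index."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1:
        x = x.T
    n = len(x)
    best = (None, -np.inf)
    for tau in range(min_size, n - min_size + 1):
        _, q = brute_force_energy(x[:tau], x[tau:], alpha)
        if q > best[1]:
            best = (tau, q)
    return best


class TestEnergyDivergence:
    def test_hand_computed_singletons(self):
        e, q = energy_divergence(np.array([0.0]), np.array([1.0]))
        assert (e, q) == (2.0, 1.0)

    def test_hand_computed_pairs(self):
        e, q = energy_divergence(np.array([0.0, 0.0]), np.array([10.0, 10.0]))
        assert (e, q) == (20.0, 20.0)

    def test_identical_singletons_give_zero(self):
        e, q = energy_divergence(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
        assert e == 0.0 and q == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            energy_divergence(np.empty((0, 2)), np.ones((3, 2)))

    def test_alpha_validated(self):
        with pytest.raises(ValueError, match="alpha"):
            energy_divergence(np.ones((2, 1)), np.ones((2, 1)), alpha=3.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            m, n = rng.integers(1, 15, 2)
            d = rng.integers(1, 5)
            alpha = rng.choice([0.5, 1.0, 1.5, 2.0])
            X, Y = rng.normal(size=(m, d)), rng.normal(size=(n, d))
            e, q = energy_divergence(X, Y, alpha)
            eo, qo = brute_force_energy(X, Y, alpha)
            assert abs(e - eo) < 1e-10 and abs(q - qo) < 1e-10


class TestBestSplit:
    def test_obvious_mean_shift(self):
        tau, q = best_split(np.array([0, 0, 0, 10, 10, 10.0]), min_size=2)
        assert tau == 3

    def test_constant_sequence_ties_to_smallest_admissible(self):
        tau, q = best_split(np.zeros(12), min_size=3)
        assert tau == 3 and q == 0.0

    def test_ramp_matches_oracle(self):
        x = np.arange(10.0)
        tau, q = best_split(x, min_size=2)
        tau_o, q_o = brute_force_best_split(x, 1.0, 2)
        assert tau == tau_o and q == pytest.approx(q_o, abs=1e-10)

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            x = rng.normal(size=(n, int(rng.integers(1, 4))))
            tau, q = best_split(x, min_size=2)
            tau_o, q_o = brute_force_best_split(x, 1.0, 2)
            assert tau == tau_o
            assert q == pytest.approx(q_o, abs=1e-10)

    def test_too_short_slice_rejected(self):
        with pytest.raises(ValueError, match="no admissible split"):
            best_split(np.zeros(5), min_size=3)


class TestEDivisive:
    def test_short_stream_returns_no_change_points(self):
        r = e_divisive(np.zeros((10, 2)), min_size=30)
        assert r.change_points == []

    def test_two_segment_recovery(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, (100, 3)), rng.normal(5, 1, (100, 3))])
        r = e_divisive(x, R=199, min_size=10, seed=1)
        assert len(r.change_points) == 1
        assert abs(r.change_points[0] - 100) <= 2
        assert all(p <= 0.05 for p in r.p_values)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, (60, 2)), rng.normal(4, 1, (60, 2))])
        a = e_divisive(x, min_size=10, seed=2)
        b = e_divisive(x + 17.3, min_size=10, seed=2)
        assert a.change_points == b.change_points

    def test_scale_invariance_of_locations(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, (60, 2)), rng.normal(4, 1, (60, 2))])
        a = e_divisive(x, min_size=10, seed=3)
        b = e_divisive(2.5 * x, min_size=10, seed=3)
        assert a.change_points == b.change_points
        np.testing.assert_allclose(np.array(b.statistics),
                                   2.5 * np.array(a.statistics), rtol=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(80, 3))
        a = e_divisive(x, seed=4, min_size=10)
        b = e_divisive(x, seed=4, min_size=10)
        assert a.change_points == b.change_points and a.p_values == b.p_values

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            e_divisive(np.zeros((100, 2)), sig_level=0.0)
        with pytest.raises(ValueError):
            e_divisive(np.zeros((100, 2)), min_size=0)


def _one_hot_stream(labels, n_classes=14):
    labels = np.asarray(labels)
    probs = np.eye(n_classes)[labels]
    return PredictionStream(np.arange(labels.size) / 25.0, probs,
                            np.arange(n_classes))


class TestSmoothing:
    def test_majority_vote_in_single_segment(self):
        stream = _one_hot_stream([2, 2, 3, 2, 2])
        seg = smooth_predictions(stream, min_size=5, R=19, seed=0)
        assert len(seg.segments) == 1
        assert np.all(seg.window_labels(5) == 2)

    def test_blocked_stream_recovers_boundary_and_labels(self):
        labels = np.array([1] * 40 + [6] * 40)
        seg = smooth_predictions(_one_hot_stream(labels), min_size=10, R=99, seed=0)
        assert [int(s.source.change_points[0]) for s in [seg]] == [40]
        assert [lab for _, _, lab in seg.segments] == [StepLabel(1), StepLabel(6)]

    def test_segments_partition_the_stream(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(rng.permutation(6), 25)
        seg = smooth_predictions(_one_hot_stream(labels), min_size=8, R=49, seed=2)
        bounds = [s for s, _, _ in seg.segments] + [seg.segments[-1][1]]
        assert bounds[0] == 0 and bounds[-1] == labels.size
        assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:]))
        cps = seg.source.change_points
        assert [e for _, e, _ in seg.segments][:-1] == cps

    def test_smoothing_beats_raw_on_flipped_blocks(self):
        """Isolated label flips are repaired by segment majority vote."""
        wins = 0
        for i in range(10):
            rng = np.random.default_rng(100 + i)
            truth = np.repeat(rng.permutation(6), 30)
            labels = truth.copy()
            flips = rng.random(truth.size) < 0.05
            labels[flips] = (labels[flips] + rng.integers(1, 14, flips.sum())) % 14
            seg = smooth_predictions(_one_hot_stream(labels), min_size=10,
                                     R=99, seed=i)
            sm = seg.window_labels(truth.size)
            wins += np.mean(sm == truth) > np.mean(labels == truth)
        assert wins >= 9

    def test_empty_stream_rejected(self):
        stream = PredictionStream(np.array([]), np.zeros((0, 3)), np.arange(3))
        with pytest.raises(ValueError, match="non-empty"):
            smooth_predictions(stream)
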