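"""Energy-divisive multiple change-point detection and majority-vote
smoothing.

Raw per-window predictions flicker between classes faster than a hand can
plausibly move, so the prediction stream is segmented into homogeneous
stretches and each segment relabeled by majority vote — a replacement for
HMM smoothing that makes no assumption about step order or duration.

Change points come from the hierarchical divisive energy procedure: for two
multivariate samples X (size m) and Y (size n) the empirical energy
divergence with index ``alpha`` in (0, 2] is

    e(X, Y) = 2/(mn) * sum_ij |x_i - y_j|^a
              - C(m,2)^-1 * sum_{i<k} |x_i - x_k|^a
              - C(n,2)^-1 * sum_{j<k} |y_j - y_k|^a

(within-sample terms are 0 for singleton samples), and its sample-size
scaled form is q(X, Y) = (mn/(m+n)) * e(X, Y).  The best split of a segment
maximizes q over all admissible split points (both sides >= ``min_size``;
ties go to the smallest index).  The divisive procedure repeatedly takes
the globally best split over all current segments and accepts it while a
conditional permutation test — observations permuted within current
segments, with the +1-corrected p-value p = (1 + #{q_perm >= q_obs})/(R+1)
— stays at or below ``sig_level``.

Distances are computed once per stream; every split scan then runs in
linear time from cumulative sums, so the whole procedure is O(n^2) memory
and roughly O(R * n^2) time per accepted split.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .classify import PredictionStream
from .labels import StepLabel


def energy_divergence(
    X: np.ndarray, Y: np.ndarray, alpha: float = 1.0
) -> Tuple[float, float]:
    """Empirical energy divergence ``(e, q)`` between two samples.

    ``X`` and ``Y`` are (m, d) and (n, d) arrays (1-D inputs are treated as
    d=1).  ``alpha`` must lie in (0, 2].
    """
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must lie in (0, 2]")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("samples must be non-empty")
    m, n = X.shape[0], Y.shape[0]

    between = cdist(X, Y) ** alpha
    e = 2.0 * between.sum() / (m * n)
    if m > 1:
        e -= (pdist(X) ** alpha).sum() / (m * (m - 1) / 2.0)
    if n > 1:
        e -= (pdist(Y) ** alpha).sum() / (n * (n - 1) / 2.0)
    q = (m * n / (m + n)) * e
    return float(e), float(q)


# --------------------------------------------------------------------------
# fast split scans over a precomputed distance matrix


def _qhat_profile(D: np.ndarray) -> np.ndarray:
    """q-hat for every split index tau = 1..n-1 of a segment.

    ``D`` is the symmetric matrix of alpha-power distances.  Returns an
    array ``q`` of length n where ``q[tau]`` scores the split into
    ``[0, tau)`` and ``[tau, n)``; entries 0 and beyond n-1 are -inf.
    """
    n = D.shape[0]
    q = np.full(n, -np.inf)
    if n < 2:
        return q
    # r[t] = sum of D[t, :t]; S[tau] = 2 * sum_{t<tau} r[t] = full double sum
    csum = np.cumsum(D, axis=1)
    r = np.zeros(n)
    r[1:] = csum[np.arange(1, n), np.arange(0, n - 1)]
    S = np.zeros(n + 1)
    S[1:] = 2.0 * np.cumsum(r)
    rowtot = D.sum(axis=1)
    cumrow = np.zeros(n + 1)
    cumrow[1:] = np.cumsum(rowtot)
    TS = rowtot.sum() / 2.0

    tau = np.arange(1, n)
    m = tau.astype(float)
    k = (n - tau).astype(float)
    WL = S[tau] / 2.0
    B = cumrow[tau] - S[tau]
    WR = TS - WL - B
    e = 2.0 * B / (m * k)
    with np.errstate(divide="ignore", invalid="ignore"):
        left_term = np.where(m > 1, WL / (m * (m - 1) / 2.0), 0.0)
        right_term = np.where(k > 1, WR / (k * (k - 1) / 2.0), 0.0)
    e = e - left_term - right_term
    q[1:] = (m * k / (m + k)) * e
    return q


def _best_split_from_D(D: np.ndarray, min_size: int) -> Tuple[int, float]:
    n = D.shape[0]
    if n < 2 * min_size:
        raise ValueError("no admissible split: segment shorter than 2 * min_size")
    q = _qhat_profile(D)
    q[:min_size] = -np.inf
    q[n - min_size + 1:] = -np.inf
    tau = int(np.argmax(q))  # argmax returns the smallest index on ties
    return tau, float(q[tau])


def best_split(
    segment: np.ndarray, alpha: float = 1.0, min_size: int = 2
) -> Tuple[int, float]:
    """Exhaustive best split of one segment: the index tau maximizing q-hat
    with both sides >= ``min_size`` (ties to the smallest tau)."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] == 1:
        segment = segment.T
    D = squareform(pdist(segment) ** alpha)
    return _best_split_from_D(D, min_size)


@dataclasses.dataclass
class ChangePointResult:
    """Accepted change points with their test statistics."""

    change_points: List[int]          # strictly increasing segment boundaries
    statistics: List[float]           # q-hat of each accepted split, in order found
    p_values: List[float]             # permutation p-value of each accepted split
    alpha: float
    R: int
    sig_level: float
    min_size: int

    def segments(self, n: int) -> List[Tuple[int, int]]:
        bounds = [0] + sorted(self.change_points) + [n]
        return list(zip(bounds[:-1], bounds[1:]))


def e_divisive(
    stream: np.ndarray,
    sig_level: float = 0.05,
    R: int = 199,
    min_size: int = 30,
    alpha: float = 1.0,
    seed: Union[int, np.random.Generator] = 0,
) -> ChangePointResult:
    """Hierarchical divisive change-point estimation on a (windows, d)
    stream.  Deterministic given the seed."""
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must lie in (0, 2]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if R < 0 or not 0.0 < sig_level < 1.0:
        raise ValueError("invalid permutation-test parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    stream = np.atleast_2d(np.asarray(stream, dtype=float))
    if stream.shape[0] == 1 and stream.shape[1] > 1:
        stream = stream.T
    n = stream.shape[0]
    result = ChangePointResult([], [], [], alpha, R, sig_level, min_size)
    if n < 2 * min_size:
        return result

    Dfull = squareform(pdist(stream) ** alpha)
    segments: List[Tuple[int, int]] = [(0, n)]
    best_cache = {}

    def seg_best(seg: Tuple[int, int]) -> Optional[Tuple[int, float]]:
        if seg not in best_cache:
            s, e = seg
            if e - s < 2 * min_size:
                best_cache[seg] = None
            else:
                tau, q = _best_split_from_D(Dfull[s:e, s:e], min_size)
                best_cache[seg] = (s + tau, q)
        return best_cache[seg]

    while True:
        candidates = [(seg, seg_best(seg)) for seg in segments]
        candidates = [(seg, b) for seg, b in candidates if b is not None]
        if not candidates:
            break
        seg_star, (cp, q_obs) = max(candidates, key=lambda c: c[1][1])

        exceed = 0
        for _ in range(R):
            q_max = -np.inf
            for s, e in segments:
                if e - s < 2 * min_size:
                    continue
                p = rng.permutation(e - s)
                Dp = Dfull[s:e, s:e][np.ix_(p, p)]
                _, qp = _best_split_from_D(Dp, min_size)
                q_max = max(q_max, qp)
            if q_max >= q_obs:
                exceed += 1
        p_value = (1.0 + exceed) / (R + 1.0)
        if p_value > sig_level:
            break

        result.change_points.append(cp)
        result.statistics.append(q_obs)
        result.p_values.append(p_value)
        s, e = seg_star
        segments.remove(seg_star)
        segments.extend([(s, cp), (cp, e)])
        segments.sort()

    result.change_points.sort()
    return result


@dataclasses.dataclass
class Segmentation:
    """A partition of the prediction stream with one majority label per
    segment."""

    segments: List[Tuple[int, int, StepLabel]]
    source: ChangePointResult

    def window_labels(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        for s, e, label in self.segments:
            out[s:e] = int(label)
        return out


def smooth_predictions(
    stream: PredictionStream,
    sig_level: float = 0.05,
    R: int = 199,
    min_size: int = 30,
    alpha: float = 1.0,
    seed: Union[int, np.random.Generator] = 0,
    cp_input: str = "probs",
) -> Segmentation:
    """Segment the prediction stream and relabel each segment by majority
    vote over its argmax labels (ties to the smallest class index).

    ``cp_input='probs'`` (default) feeds the class-probability rows to the
    change-point procedure, preserving classifier uncertainty;
    ``'onehot'`` uses the hardened argmax labels instead.
    """
    if stream.probs.shape[0] == 0:
        raise ValueError("stream must be non-empty")
    if cp_input == "probs":
        points = stream.probs
    elif cp_input == "onehot":
        arg = np.argmax(stream.probs, axis=1)
        points = np.eye(stream.probs.shape[1])[arg]
    else:
        raise ValueError("cp_input must be 'probs' or 'onehot'")

    cps = e_divisive(points, sig_level=sig_level, R=R, min_size=min_size,
                     alpha=alpha, seed=seed)
    argmax = stream.argmax_labels
    segments: List[Tuple[int, int, StepLabel]] = []
    n = stream.probs.shape[0]
    for s, e in cps.segments(n):
        votes = np.bincount(argmax[s:e], minlength=int(StepLabel.NONE) + 1)
        label = StepLabel(int(np.argmax(votes)))  # ties -> smallest index
        segments.append((s, e, label))
    return Segmentation(segments=segments, source=cps)
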