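"""Resampling, normalization, and sliding windows.

All channels are brought to a common 25 Hz grid.  IMU channels (50 Hz) are
zero-phase low-pass filtered at 10 Hz and decimated 2:1.  sEMG channels
(200 Hz) are full-wave rectified and low-pass filtered at 10 Hz first — the
standard envelope — because naive 8:1 decimation of a broadband sEMG signal
aliases to noise; a plain ``decimate`` mode is available for comparison.
Orientation quaternions are renormalized after filtering.

Channels are then z-scored per channel per session (population SD, zero-SD
channels map to zeros) and cut into 0.2 s sliding windows.  At 25 Hz a
0.2 s window is 5 samples; an exact 75 % overlap of 5 samples is
non-integral, so the hop is 1 sample (80 % effective overlap).  Each window
carries the majority step label over its samples, with ties broken by the
label at the window's center sample and then by the smallest label index;
windows whose majority is ``NONE`` are flagged but retained.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal

from .labels import Placement, StepLabel
from .sessions import (
    LabelTrack,
    MODALITY_CHANNELS,
    SensorChannelSet,
)

TARGET_HZ = 25.0
WINDOW_S = 0.2
OVERLAP = 0.75
LOWPASS_HZ = 10.0

_IMU_TAPS = 31
_EMG_TAPS = 51


@dataclasses.dataclass
class ChannelInfo:
    """Identity of one resampled channel: placement code, modality, axis."""

    placement: str
    modality: str
    axis: str

    @property
    def name(self) -> str:
        return f"{self.placement}.{self.modality}.{self.axis}"


@dataclasses.dataclass
class ResampledSession:
    """channels x time matrix on a shared 25 Hz grid."""

    matrix: np.ndarray
    channel_info: List[ChannelInfo]
    t0: float = 0.0
    rate: float = TARGET_HZ

    @property
    def channel_names(self) -> List[str]:
        return [c.name for c in self.channel_info]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate


@dataclasses.dataclass
class WindowSet:
    """Fixed-length, fixed-hop windows into a :class:`ResampledSession`."""

    windows: List[Tuple[int, int]]  # (start_index, end_index) half-open
    labels: np.ndarray              # int StepLabel index per window
    none_flags: np.ndarray          # True where the majority label is NONE
    window_s: float = WINDOW_S
    overlap: float = OVERLAP

    def __len__(self) -> int:
        return len(self.windows)

    def centers(self, rate: float = TARGET_HZ, t0: float = 0.0) -> np.ndarray:
        """Window-center times in seconds."""
        mids = np.array([(s + e - 1) / 2.0 for s, e in self.windows])
        return t0 + mids / rate


def _zero_phase_lowpass(x: np.ndarray, fs: float, cutoff: float, numtaps: int) -> np.ndarray:
    taps = signal.firwin(numtaps, cutoff, fs=fs)
    n = x.shape[0]
    if n <= numtaps:
        raise ValueError(
            f"session too short: {n} samples at {fs} Hz "
            f"(need > {numtaps} for zero-phase filtering)"
        )
    padlen = min(3 * numtaps, n - 1)
    return signal.filtfilt(taps, [1.0], x, axis=0, padlen=padlen)


def resample_to_common_rate(
    channelset: SensorChannelSet,
    placement: Placement,
    target_hz: float = TARGET_HZ,
    emg_mode: str = "envelope",
) -> ResampledSession:
    """Bring all modalities of one armband to the shared ``target_hz`` grid.

    ``emg_mode='envelope'`` (default) rectifies and low-pass filters sEMG
    before decimation; ``'decimate'`` low-pass filters the raw signal only.
    """
    if emg_mode not in ("envelope", "decimate"):
        raise ValueError("emg_mode must be 'envelope' or 'decimate'")
    imu_dec = int(round(50.0 / target_hz))
    emg_dec = int(round(200.0 / target_hz))

    columns: List[np.ndarray] = []
    info: List[ChannelInfo] = []

    for modality in ("accel", "gyro", "orientation"):
        ch = channelset.modality(modality)
        filtered = _zero_phase_lowpass(ch.values, 50.0, LOWPASS_HZ, _IMU_TAPS)
        dec = filtered[::imu_dec]
        if modality == "orientation":
            norms = np.linalg.norm(dec, axis=1, keepdims=True)
            dec = np.divide(dec, norms, out=np.zeros_like(dec), where=norms > 0)
        for k, axis in enumerate(MODALITY_CHANNELS[modality]):
            columns.append(dec[:, k])
            info.append(ChannelInfo(placement.value, modality, axis))

    emg = channelset.emg.values
    if emg_mode == "envelope":
        emg = np.abs(emg)
    emg = _zero_phase_lowpass(emg, 200.0, LOWPASS_HZ, _EMG_TAPS)[::emg_dec]
    for k, axis in enumerate(MODALITY_CHANNELS["emg"]):
        columns.append(emg[:, k])
        info.append(ChannelInfo(placement.value, "emg", axis))

    n = min(c.shape[0] for c in columns)
    matrix = np.stack([c[:n] for c in columns])
    return ResampledSession(matrix=matrix, channel_info=info, rate=target_hz)


def combine_placements(parts: Sequence[ResampledSession]) -> ResampledSession:
    """Stack the channels of several armbands onto one shared grid
    (truncating to the shortest)."""
    n = min(p.n_samples for p in parts)
    matrix = np.concatenate([p.matrix[:, :n] for p in parts], axis=0)
    info = [c for p in parts for c in p.channel_info]
    return ResampledSession(matrix=matrix, channel_info=info, rate=parts[0].rate)


def zscore_normalize(resampled: ResampledSession) -> ResampledSession:
    """Per-channel, per-session z-score (population SD; constant channels
    map to all-zeros).  Idempotent on its own output."""
    m = resampled.matrix
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel to normalize")
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)  # population SD (denominator n)
    out = np.divide(m - mean, sd, out=np.zeros_like(m), where=sd > 0)
    return ResampledSession(
        matrix=out, channel_info=list(resampled.channel_info),
        t0=resampled.t0, rate=resampled.rate,
    )


def window_geometry(n_samples: int, rate: float = TARGET_HZ,
                    window_s: float = WINDOW_S, overlap: float = OVERLAP
                    ) -> Tuple[int, int]:
    """(window length, hop) in samples; hop is at least one sample."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    length = int(round(window_s * rate))
    hop = max(1, int(round(length * (1.0 - overlap))))
    return length, hop


def slide_windows(
    resampled: ResampledSession,
    labels: LabelTrack,
    window_s: float = WINDOW_S,
    overlap: float = OVERLAP,
) -> WindowSet:
    """Cut the session into labeled sliding windows.

    The window label is the majority step label over its samples; ties break
    to the label of the center sample, then to the smallest label index.
    """
    length, hop = window_geometry(resampled.n_samples, resampled.rate, window_s, overlap)
    n = resampled.n_samples
    if n < length:
        raise ValueError(f"session length {n} shorter than window {length}")
    sample_labels = labels.sample_labels(resampled.times())

    n_windows = (n - length) // hop + 1
    starts = np.arange(n_windows) * hop
    idx = starts[:, None] + np.arange(length)[None, :]
    win_labels_all = sample_labels[idx]  # (n_windows, length)

    n_classes = int(StepLabel.NONE) + 1
    counts = np.zeros((n_windows, n_classes), dtype=np.int64)
    for c in range(n_classes):
        counts[:, c] = (win_labels_all == c).sum(axis=1)
    max_count = counts.max(axis=1)
    # majority; break ties via the center sample, then smallest index
    out = np.empty(n_windows, dtype=np.int64)
    is_max = counts == max_count[:, None]
    n_ties = is_max.sum(axis=1)
    out = np.argmax(is_max, axis=1)  # smallest index among maxima
    tied = np.flatnonzero(n_ties > 1)
    if tied.size:
        center = win_labels_all[tied, length // 2]
        use_center = is_max[tied, center]
        out[tied[use_center]] = center[use_center]

    windows = [(int(s), int(s + length)) for s in starts]
    return WindowSet(
        windows=windows,
        labels=out,
        none_flags=out == int(StepLabel.NONE),
        window_s=window_s,
        overlap=overlap,
    )
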