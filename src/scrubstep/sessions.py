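"""Session data model and on-disk format.

A :class:`HygieneSession` is one participant's single hand-hygiene
performance: per-placement raw channel sets (3-axis acceleration in g at
50 Hz, 3-axis angular velocity in deg/s at 50 Hz, a unit orientation
quaternion at 50 Hz, and 8-channel sEMG activation at 200 Hz) plus the
ground-truth label track.  Time is in seconds from session start and all
label intervals are half-open ``[start, end)``.

On disk a session is a directory with ``manifest.json``, one CSV per
placement per modality (``{placement}_{modality}.csv`` with a ``t`` column
followed by channel columns), and ``labels.csv``.  CSVs are UTF-8 with a
``.`` decimal separator and values rendered with 12 significant digits, so a
write/read roundtrip is an identity well within 1e-9.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .labels import Instruction, Mode, Placement, StepLabel, allowed_labels, parse_label

IMU_RATE_HZ = 50.0
EMG_RATE_HZ = 200.0
RATE_TOLERANCE = 0.02  # nominal rates must hold within +/- 2 %

MODALITIES = ("accel", "gyro", "orientation", "emg")
MODALITY_CHANNELS = {
    "accel": ["ax", "ay", "az"],
    "gyro": ["gx", "gy", "gz"],
    "orientation": ["qw", "qx", "qy", "qz"],
    "emg": [f"e{i}" for i in range(1, 9)],
}
MODALITY_RATES = {
    "accel": IMU_RATE_HZ,
    "gyro": IMU_RATE_HZ,
    "orientation": IMU_RATE_HZ,
    "emg": EMG_RATE_HZ,
}

_FLOAT_FMT = "%.12g"


class SessionValidationError(ValueError):
    """A session violates one or more data-model invariants."""

    def __init__(self, violations: List[str]):
        self.violations = list(violations)
        super().__init__("invalid session:\n  " + "\n  ".join(self.violations))


class SessionFormatError(ValueError):
    """An on-disk session directory is malformed."""


@dataclasses.dataclass
class Channel:
    """One modality of one armband: timestamps (s) and a samples x channels
    value array."""

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]


@dataclasses.dataclass
class SensorChannelSet:
    """All four modalities recorded by a single armband."""

    accel: Channel
    gyro: Channel
    orientation: Channel
    emg: Channel

    def modality(self, name: str) -> Channel:
        return getattr(self, name)

    @property
    def max_time(self) -> float:
        return max(
            float(self.modality(m).t[-1]) for m in MODALITIES if self.modality(m).t.size
        )


@dataclasses.dataclass
class LabelTrack:
    """Ordered, non-overlapping half-open intervals, each carrying one step
    label.  Gaps are implicitly ``NONE``."""

    intervals: List[Tuple[float, float, StepLabel]]

    @property
    def span(self) -> float:
        """Total covered span (last end minus first start); 0 when empty."""
        if not self.intervals:
            return 0.0
        return self.intervals[-1][1] - self.intervals[0][0]

    @property
    def end(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def label_at(self, time_s: float) -> StepLabel:
        for start, end, label in self.intervals:
            if start <= time_s < end:
                return label
        return StepLabel.NONE

    def sample_labels(self, times: np.ndarray) -> np.ndarray:
        """Vectorized per-sample labels (integer indices) at ``times``."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, int(StepLabel.NONE), dtype=np.int64)
        for start, end, label in self.intervals:
            out[(times >= start) & (times < end)] = int(label)
        return out

    def step_sequence(self) -> List[StepLabel]:
        """Run-length collapse of the performed (non-NONE) labels."""
        seq: List[StepLabel] = []
        for _, _, label in self.intervals:
            if label is StepLabel.NONE:
                continue
            if not seq or seq[-1] is not label:
                seq.append(label)
        return seq


@dataclasses.dataclass
class HygieneSession:
    """One participant's one hand-hygiene performance."""

    participant_id: str
    mode: Mode
    instruction: Instruction
    devices: Dict[Placement, SensorChannelSet]
    labels: LabelTrack
    meta: Dict[str, object] = dataclasses.field(default_factory=dict)


def _check_channel(
    name: str, channel: Channel, nominal_hz: float, violations: List[str]
) -> None:
    t = channel.t
    if t.size == 0:
        violations.append(f"{name}: empty stream")
        return
    if t.size != channel.values.shape[0]:
        violations.append(f"{name}: timestamps and values differ in length")
        return
    if t[0] < 0:
        violations.append(f"{name}: timestamps must start at >= 0")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            violations.append(f"{name}: timestamps not strictly increasing")
        else:
            rate = 1.0 / float(np.mean(dt))
            if abs(rate - nominal_hz) > RATE_TOLERANCE * nominal_hz:
                violations.append(
                    f"{name}: mean rate {rate:.2f} Hz outside "
                    f"{nominal_hz} Hz +/- {RATE_TOLERANCE:.0%}"
                )


def validate_session(session: HygieneSession) -> List[str]:
    """Return all invariant violations (empty list when the session is valid).

    Total function: never raises on bad content, only reports it.
    """
    violations: List[str] = []
    if not session.devices:
        violations.append("devices: at least one placement required")
    for placement, channels in session.devices.items():
        for modality in MODALITIES:
            ch = channels.modality(modality)
            name = f"devices[{placement.value}].{modality}"
            _check_channel(name, ch, MODALITY_RATES[modality], violations)
            n_expect = len(MODALITY_CHANNELS[modality])
            if ch.values.ndim != 2 or ch.values.shape[1] != n_expect:
                violations.append(f"{name}: expected {n_expect} channel columns")
        ori = channels.orientation
        if ori.values.ndim == 2 and ori.values.shape[1] == 4 and ori.values.size:
            norms = np.linalg.norm(ori.values, axis=1)
            bad = np.abs(norms - 1.0) > 1e-3
            if np.any(bad):
                violations.append(
                    f"devices[{placement.value}].orientation: "
                    f"{int(bad.sum())} quaternion(s) deviate from unit norm by > 1e-3"
                )

    prev_end: Optional[Tuple[float, float, StepLabel]] = None
    legal = allowed_labels(session.mode)
    for i, (start, end, label) in enumerate(session.labels.intervals):
        if not start < end:
            violations.append(f"labels[{i}]: start {start} must be < end {end}")
        if prev_end is not None and start < prev_end[1]:
            violations.append(
                f"labels: interval {i} [{start}, {end}) overlaps interval {i - 1} "
                f"[{prev_end[0]}, {prev_end[1]})"
            )
        if label not in legal:
            violations.append(
                f"labels[{i}]: step {label.name} not allowed in mode {session.mode.value}"
            )
        prev_end = (start, end, label)

    if session.devices and session.labels.intervals:
        max_t = max(cs.max_time for cs in session.devices.values())
        if session.labels.end > max_t + 0.1:
            violations.append(
                f"labels: end {session.labels.end:.3f} s exceeds last stream "
                f"timestamp {max_t:.3f} s by more than 0.1 s"
            )
    return violations


def write_session(session: HygieneSession, directory) -> Path:
    """Write a validated session to ``directory`` (created if needed)."""
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "participant_id": session.participant_id,
        "mode": session.mode.value,
        "instruction": session.instruction.value,
        "placements": sorted(p.value for p in session.devices),
        "rates_hz": {"imu": IMU_RATE_HZ, "emg": EMG_RATE_HZ},
        "meta": session.meta,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    for placement, channels in session.devices.items():
        for modality in MODALITIES:
            ch = channels.modality(modality)
            df = pd.DataFrame(ch.values, columns=MODALITY_CHANNELS[modality])
            df.insert(0, "t", ch.t)
            df.to_csv(
                directory / f"{placement.value}_{modality}.csv",
                index=False,
                float_format=_FLOAT_FMT,
            )

    labels_df = pd.DataFrame(
        [(s, e, lab.name) for s, e, lab in session.labels.intervals],
        columns=["start_s", "end_s", "label"],
    )
    labels_df.to_csv(directory / "labels.csv", index=False, float_format=_FLOAT_FMT)
    return directory


def _read_csv(path: Path, expected_cols: List[str]) -> pd.DataFrame:
    if not path.exists():
        raise SessionFormatError(f"{path}: missing file")
    df = pd.read_csv(path)
    if list(df.columns) != expected_cols:
        raise SessionFormatError(
            f"{path}: malformed header {list(df.columns)!r}, expected {expected_cols!r}"
        )
    return df


def read_session(directory) -> HygieneSession:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SessionFormatError(f"{manifest_path}: missing file")
    manifest = json.loads(manifest_path.read_text())

    devices: Dict[Placement, SensorChannelSet] = {}
    for code in manifest["placements"]:
        placement = Placement(code)
        parts = {}
        for modality in MODALITIES:
            path = directory / f"{code}_{modality}.csv"
            df = _read_csv(path, ["t"] + MODALITY_CHANNELS[modality])
            t = df["t"].to_numpy(dtype=float)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                line = int(np.argmax(np.diff(t) <= 0)) + 3  # 1 header + 1-based + next row
                raise SessionFormatError(f"{path}: non-monotone timestamps at line {line}")
            parts[modality] = Channel(t, df.iloc[:, 1:].to_numpy(dtype=float))
        devices[placement] = SensorChannelSet(**parts)

    labels_path = directory / "labels.csv"
    labels_df = _read_csv(labels_path, ["start_s", "end_s", "label"])
    intervals = []
    for i, row in enumerate(labels_df.itertuples(index=False)):
        try:
            label = parse_label(str(row.label))
        except ValueError as exc:
            raise SessionFormatError(f"{labels_path}: line {i + 2}: {exc}") from None
        intervals.append((float(row.start_s), float(row.end_s), label))

    session = HygieneSession(
        participant_id=str(manifest["participant_id"]),
        mode=Mode(manifest["mode"]),
        instruction=Instruction(manifest["instruction"]),
        devices=devices,
        labels=LabelTrack(intervals),
        meta=dict(manifest.get("meta", {})),
    )
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    return session
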