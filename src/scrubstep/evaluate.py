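"""Evaluation protocols and participant-compliance analytics.

Two cross-validation protocols mirror the two deployment scenarios:
LOSO (leave-one-session-out, within one participant) measures the
user-dependent model; LOPO (leave-one-participant-out, across the cohort)
measures the user-independent model.  Feature selection and the classifier
are refit inside every training fold, so test windows never influence the
selected feature set.  ``NONE``-labeled windows are excluded from training
and from accuracy denominators.

Reported means are the unweighted mean of per-unit accuracies (per session
for LOSO, per participant for LOPO); the pooled window accuracy is also
emitted and labeled as such.

The module also provides the ablation drivers (armband placements and
sensor combinations), the bootstrapping curve (user-dependent accuracy as a
function of the number of training sessions), and the compliance analytics:
an expected-step x performed-step matrix built by global edit-distance
alignment of each performed sequence against the canonical grammar, session
duration summaries per condition, and the per-session-index compliance
curve.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import PredictionStream, predict_stream, train_classifier
from .features import (
    FeatureMatrix,
    apply_selector,
    extract_features,
    select_top_features,
)
from .labels import (
    Mode,
    PLACEMENT_PAIRS,
    Placement,
    StepLabel,
    canonical_order,
)
from .preprocess import (
    combine_placements,
    resample_to_common_rate,
    slide_windows,
    zscore_normalize,
)
from .segment import smooth_predictions
from .sessions import HygieneSession, LabelTrack

SENSOR_COMBOS: Dict[str, Tuple[str, ...]] = {
    "ACC": ("accel",),
    "GYRO": ("gyro",),
    "EMG": ("emg",),
    "ACC+GYRO": ("accel", "gyro"),
    "ACC+GYRO+ORI": ("accel", "gyro", "orientation"),
    "ACC+GYRO+ORI+EMG": ("accel", "gyro", "orientation", "emg"),
}
ALL_SENSORS = "ACC+GYRO+ORI+EMG"


@dataclasses.dataclass
class PipelineConfig:
    """Everything one evaluation run needs, in one place."""

    placements: Tuple[Placement, ...] = (Placement.RF,)
    sensor_combo: str = ALL_SENSORS
    window_s: float = 0.2
    overlap: float = 0.75
    emg_mode: str = "envelope"
    selection_k: int = 100
    selection_params: Optional[dict] = None
    classifier_params: Optional[dict] = None
    smooth: bool = False
    smooth_params: Optional[dict] = None
    train_stride: int = 1   # keep every n-th training window (test windows all kept)
    seed: int = 0

    def __post_init__(self):
        if self.sensor_combo not in SENSOR_COMBOS:
            raise ValueError(
                f"sensor_combo must be one of {sorted(SENSOR_COMBOS)}"
            )

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """Reduced booster sizes and a training-window stride for
        desk-scale cohorts (the synthetic signals are far more separable
        than the full-default ensemble assumes, so small boosters saturate
        accuracy)."""
        base = dict(
            placements=(Placement.RF,),
            selection_params={"num_boost_round": 15, "max_depth": 4, "max_bin": 64},
            classifier_params={
                "num_boost_round": 40, "max_depth": 4,
                "learning_rate": 0.3, "max_bin": 64,
            },
            train_stride=5,
        )
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class EvalReport:
    """Per-unit accuracies plus the pooled view and a confusion matrix."""

    protocol: str
    per_unit: Dict[str, float]      # session key or participant id -> accuracy
    mean_accuracy: float
    sd_accuracy: float
    pooled_accuracy: float
    confusion: np.ndarray           # (15, 15) true x predicted window counts
    config: PipelineConfig


# --------------------------------------------------------------------------
# feature-table preparation (cached per session+placement)


class FeatureCache:
    """Caches the full-sensor feature table per (session, placements).

    Sensor combinations are column subsets of the full table: every
    resampling/normalization/feature step operates per channel or within a
    single modality group, so dropping a modality cannot change the
    remaining columns.
    """

    def __init__(self):
        self._store: Dict[Tuple[int, Tuple[Placement, ...]], FeatureMatrix] = {}

    def features(self, session: HygieneSession, config: PipelineConfig) -> FeatureMatrix:
        key = (id(session), tuple(config.placements))
        if key not in self._store:
            parts = [
                resample_to_common_rate(
                    session.devices[p], p, emg_mode=config.emg_mode
                )
                for p in config.placements
            ]
            resampled = zscore_normalize(combine_placements(parts))
            windows = slide_windows(
                resampled, session.labels, config.window_s, config.overlap
            )
            self._store[key] = extract_features(windows, resampled)
        full = self._store[key]
        modalities = set(SENSOR_COMBOS[config.sensor_combo])
        keep = [
            i for i, name in enumerate(full.feature_names)
            if name.split(".")[1] in modalities
        ]
        if not keep:
            raise ValueError("empty channel subset for sensor combo")
        if len(keep) == len(full.feature_names):
            return full
        return full.select_columns(keep)


def prepare_session(
    session: HygieneSession,
    config: PipelineConfig,
    cache: Optional[FeatureCache] = None,
) -> FeatureMatrix:
    """Resample, normalize, window, and featurize one session under a
    pipeline configuration (restricted to its placements and sensors)."""
    for p in config.placements:
        if p not in session.devices:
            raise ValueError(
                f"session {session.participant_id}/{session.meta.get('session_index')}"
                f" lacks placement {p.value}"
            )
    cache = cache or FeatureCache()
    return cache.features(session, config)


# --------------------------------------------------------------------------
# metrics


def frame_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of non-NONE windows with matching label."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label arrays differ in length")
    mask = true != int(StepLabel.NONE)
    if not np.any(mask):
        return float("nan")
    return float(np.mean(predicted[mask] == true[mask]))


def _accumulate_confusion(conf: np.ndarray, true: np.ndarray, pred: np.ndarray) -> None:
    np.add.at(conf, (true, pred), 1)


# --------------------------------------------------------------------------
# fold machinery


def _train_matrix(parts: List[FeatureMatrix], stride: int) -> FeatureMatrix:
    values, labels, times = [], [], []
    for fm in parts:
        keep = fm.window_labels != int(StepLabel.NONE)
        idx = np.flatnonzero(keep)[::max(1, stride)]
        values.append(fm.values[idx])
        labels.append(fm.window_labels[idx])
        times.append(fm.window_times[idx])
    return FeatureMatrix(
        values=np.concatenate(values),
        feature_names=parts[0].feature_names,
        window_labels=np.concatenate(labels),
        window_times=np.concatenate(times),
    )


def run_fold(
    train_sessions: List[FeatureMatrix],
    test_features: FeatureMatrix,
    config: PipelineConfig,
) -> Tuple[np.ndarray, PredictionStream]:
    """Fit selector + classifier on training windows, predict the test
    session, optionally smooth; returns (predicted labels, stream)."""
    train = _train_matrix(train_sessions, config.train_stride)
    selector = select_top_features(
        train, k=config.selection_k,
        boosting_params=config.selection_params, seed=config.seed,
    )
    model = train_classifier(
        apply_selector(train, selector),
        params=config.classifier_params, seed=config.seed,
    )
    stream = predict_stream(model, apply_selector(test_features, selector))
    if config.smooth:
        params = dict(config.smooth_params or {})
        params.setdefault("seed", config.seed)
        seg = smooth_predictions(stream, **params)
        pred = seg.window_labels(stream.probs.shape[0])
    else:
        pred = stream.argmax_labels
    return pred, stream


# --------------------------------------------------------------------------
# protocols


def loso_cv(
    sessions: Sequence[HygieneSession],
    config: PipelineConfig,
    cache: Optional[FeatureCache] = None,
) -> EvalReport:
    """Leave-one-session-out CV within one participant: one fold per
    session, each held out exactly once."""
    if len(sessions) < 2:
        raise ValueError("LOSO needs at least 2 sessions")
    cache = cache or FeatureCache()
    feats = [prepare_session(s, config, cache) for s in sessions]
    n_lab = int(StepLabel.NONE) + 1
    conf = np.zeros((n_lab, n_lab), dtype=np.int64)
    per_unit: Dict[str, float] = {}
    for i, held_out in enumerate(feats):
        train = [f for j, f in enumerate(feats) if j != i]
        classes = np.unique(
            np.concatenate([f.window_labels[f.window_labels != int(StepLabel.NONE)]
                            for f in train])
        )
        if classes.size < 2:
            raise ValueError(f"fold {i}: training windows contain a single class")
        pred, _ = run_fold(train, held_out, config)
        true = held_out.window_labels
        per_unit[f"session{sessions[i].meta.get('session_index', i)}"] = frame_accuracy(
            pred, true
        )
        _accumulate_confusion(conf, true, pred)
    accs = np.array(list(per_unit.values()))
    mask = conf[: n_lab - 1].sum()
    pooled = float(np.trace(conf[: n_lab - 1, : n_lab - 1]) / mask) if mask else float("nan")
    return EvalReport(
        protocol="loso",
        per_unit=per_unit,
        mean_accuracy=float(np.nanmean(accs)),
        sd_accuracy=float(np.nanstd(accs)),
        pooled_accuracy=pooled,
        confusion=conf,
        config=config,
    )


def group_by_participant(
    cohort: Sequence[HygieneSession],
) -> Dict[str, List[HygieneSession]]:
    groups: Dict[str, List[HygieneSession]] = {}
    for s in cohort:
        groups.setdefault(s.participant_id, []).append(s)
    return groups


def lopo_cv(
    cohort: Sequence[HygieneSession],
    config: PipelineConfig,
    cache: Optional[FeatureCache] = None,
) -> EvalReport:
    """Leave-one-participant-out CV: one fold per participant; each
    participant's accuracy is over all their windows."""
    groups = group_by_participant(cohort)
    if len(groups) < 2:
        raise ValueError("LOPO needs at least 2 participants")
    cache = cache or FeatureCache()
    feats = {
        pid: [prepare_session(s, config, cache) for s in sess]
        for pid, sess in groups.items()
    }
    n_lab = int(StepLabel.NONE) + 1
    conf = np.zeros((n_lab, n_lab), dtype=np.int64)
    per_unit: Dict[str, float] = {}
    for pid in groups:
        train = [f for other, fl in feats.items() if other != pid for f in fl]
        preds, trues = [], []
        # one model per fold, applied per held-out session
        train_mat = _train_matrix(train, config.train_stride)
        selector = select_top_features(
            train_mat, k=config.selection_k,
            boosting_params=config.selection_params, seed=config.seed,
        )
        model = train_classifier(
            apply_selector(train_mat, selector),
            params=config.classifier_params, seed=config.seed,
        )
        for f in feats[pid]:
            stream = predict_stream(model, apply_selector(f, selector))
            if config.smooth:
                params = dict(config.smooth_params or {})
                params.setdefault("seed", config.seed)
                seg = smooth_predictions(stream, **params)
                pred = seg.window_labels(stream.probs.shape[0])
            else:
                pred = stream.argmax_labels
            preds.append(pred)
            trues.append(f.window_labels)
        pred = np.concatenate(preds)
        true = np.concatenate(trues)
        per_unit[pid] = frame_accuracy(pred, true)
        _accumulate_confusion(conf, true, pred)
    accs = np.array(list(per_unit.values()))
    denom = conf[: n_lab - 1].sum()
    pooled = float(np.trace(conf[: n_lab - 1, : n_lab - 1]) / denom) if denom else float("nan")
    return EvalReport(
        protocol="lopo",
        per_unit=per_unit,
        mean_accuracy=float(np.nanmean(accs)),
        sd_accuracy=float(np.nanstd(accs)),
        pooled_accuracy=pooled,
        confusion=conf,
        config=config,
    )


def bootstrap_curve(
    sessions: Sequence[HygieneSession],
    config: PipelineConfig,
    Ns: Optional[Sequence[int]] = None,
    reps: int = 20,
    seed: int = 0,
    cache: Optional[FeatureCache] = None,
) -> Dict[int, float]:
    """User-dependent accuracy as a function of the number N of training
    sessions: per repetition, shuffle the participant's sessions, train on
    the first N, test on the rest; average over repetitions."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    total = len(sessions)
    if Ns is None:
        Ns = range(1, total)
    cache = cache or FeatureCache()
    feats = [prepare_session(s, config, cache) for s in sessions]
    rng = np.random.default_rng(seed)
    sums: Dict[int, List[float]] = {}
    for _ in range(reps):
        perm = rng.permutation(total)
        for N in Ns:
            if N >= total:
                import warnings

                warnings.warn(f"N={N} >= session count {total}; skipped")
                continue
            train = [feats[i] for i in perm[:N]]
            classes = np.unique(
                np.concatenate([f.window_labels[f.window_labels != int(StepLabel.NONE)]
                                for f in train])
            )
            if classes.size < 2:
                continue
            accs = []
            train_mat = _train_matrix(train, config.train_stride)
            selector = select_top_features(
                train_mat, k=config.selection_k,
                boosting_params=config.selection_params, seed=config.seed,
            )
            model = train_classifier(
                apply_selector(train_mat, selector),
                params=config.classifier_params, seed=config.seed,
            )
            for i in perm[N:]:
                stream = predict_stream(model, apply_selector(feats[i], selector))
                accs.append(frame_accuracy(stream.argmax_labels, feats[i].window_labels))
            sums.setdefault(int(N), []).append(float(np.nanmean(accs)))
    return {N: float(np.mean(v)) for N, v in sorted(sums.items())}


# --------------------------------------------------------------------------
# ablations


def placement_sets() -> List[Tuple[Placement, ...]]:
    """The eight placement sets: four single armbands + four pairs."""
    singles = [(p,) for p in Placement]
    return singles + [tuple(pair) for pair in PLACEMENT_PAIRS]


def placement_ablation(
    cohort: Sequence[HygieneSession],
    config: PipelineConfig,
    protocol: str = "lopo",
    cache: Optional[FeatureCache] = None,
) -> pd.DataFrame:
    """Accuracy per placement set, raw (classifier-only) and smoothed."""
    for s in cohort:
        missing = [p for p in Placement if p not in s.devices]
        if missing:
            raise ValueError(
                f"session {s.participant_id} missing placements "
                + ",".join(p.value for p in missing)
            )
    cache = cache or FeatureCache()
    rows = []
    for pset in placement_sets():
        for smooth in (False, True):
            cfg = dataclasses.replace(config, placements=pset, smooth=smooth)
            if protocol == "lopo":
                report = lopo_cv(cohort, cfg, cache)
            elif protocol == "loso":
                accs = [
                    loso_cv(sess, cfg, cache).mean_accuracy
                    for sess in group_by_participant(cohort).values()
                ]
                report = None
            else:
                raise ValueError("protocol must be 'loso' or 'lopo'")
            mean = report.mean_accuracy if report else float(np.mean(accs))
            rows.append(
                {
                    "placements": "+".join(p.value for p in pset),
                    "smoothed": smooth,
                    "mean_accuracy": mean,
                }
            )
    df = pd.DataFrame(rows)
    return df.pivot(index="placements", columns="smoothed", values="mean_accuracy").rename(
        columns={False: "raw", True: "smoothed"}
    )


def sensor_ablation(
    cohort: Sequence[HygieneSession],
    config: PipelineConfig,
    combos: Optional[Sequence[str]] = None,
    cache: Optional[FeatureCache] = None,
) -> pd.DataFrame:
    """User-independent (LOPO) accuracy per sensor combination."""
    combos = list(combos) if combos is not None else list(SENSOR_COMBOS)
    cache = cache or FeatureCache()
    rows = []
    for combo in combos:
        cfg = dataclasses.replace(config, sensor_combo=combo)
        report = lopo_cv(cohort, cfg, cache)
        rows.append({"sensors": combo, "mean_accuracy": report.mean_accuracy,
                     "sd_accuracy": report.sd_accuracy})
    return pd.DataFrame(rows).set_index("sensors")


# --------------------------------------------------------------------------
# compliance analytics

MISSED = "MISSED"


def _align(expected: List[StepLabel], performed: List[StepLabel]
           ) -> List[Tuple[Optional[StepLabel], Optional[StepLabel]]]:
    """Global alignment (match 1, mismatch 0, gap -0.5; ties prefer the
    diagonal) returning (expected, performed) pairs; None marks a gap."""
    n, m = len(expected), len(performed)
    gap = -0.5
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up(gap perf), 2 left
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (1.0 if expected[i - 1] is performed[j - 1] else 0.0)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(diag, up, left)
            score[i, j] = best
            if diag >= up and diag >= left:
                move[i, j] = 0
            elif up >= left:
                move[i, j] = 1
            else:
                move[i, j] = 2
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0 and i > 0 and j > 0:
            pairs.append((expected[i - 1], performed[j - 1]))
            i, j = i - 1, j - 1
        elif mv == 1 and i > 0:
            pairs.append((expected[i - 1], None))
            i -= 1
        else:
            pairs.append((None, performed[j - 1]))
            j -= 1
    return pairs[::-1]


@dataclasses.dataclass
class ComplianceMatrix:
    """Expected-step x (performed-step + MISSED) counts plus the mean
    per-session compliance."""

    counts: pd.DataFrame
    compliance: float
    per_session: List[float]


def compliance_matrix(tracks: Sequence[LabelTrack], mode: Mode) -> ComplianceMatrix:
    """Score performed step sequences against the canonical grammar.

    Each expected step contributes one count per session: to the performed
    step aligned with it, or to MISSED when aligned to a gap.  Overall
    compliance is the mean fraction of expected steps aligned to themselves.
    """
    expected = canonical_order(mode)
    columns = [lab.name for lab in StepLabel if lab is not StepLabel.NONE] + [MISSED]
    counts = pd.DataFrame(
        0, index=[lab.name for lab in expected], columns=columns, dtype=np.int64
    )
    per_session = []
    for track in tracks:
        performed = track.step_sequence()
        matches = 0
        if not performed:
            for lab in expected:
                counts.loc[lab.name, MISSED] += 1
            per_session.append(0.0)
            continue
        for exp, perf in _align(expected, performed):
            if exp is None:
                continue
            if perf is None:
                counts.loc[exp.name, MISSED] += 1
            else:
                counts.loc[exp.name, perf.name] += 1
                if exp is perf:
                    matches += 1
        per_session.append(matches / len(expected))
    return ComplianceMatrix(
        counts=counts,
        compliance=float(np.mean(per_session)) if per_session else float("nan"),
        per_session=per_session,
    )


def duration_summary(cohort: Sequence[HygieneSession]) -> pd.DataFrame:
    """Per-condition session-duration mean/SD (label-track span)."""
    rows = []
    for (mode, instr), group in itertools.groupby(
        sorted(cohort, key=lambda s: (s.mode.value, s.instruction.value)),
        key=lambda s: (s.mode, s.instruction),
    ):
        spans = [s.labels.span for s in group]
        rows.append(
            {
                "mode": mode.value,
                "instruction": instr.value,
                "n": len(spans),
                "mean_s": float(np.mean(spans)),
                "sd_s": float(np.std(spans, ddof=1)) if len(spans) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def step_duration_summary(cohort: Sequence[HygieneSession]) -> pd.DataFrame:
    """Per-step duration mean/SD pooled over the cohort."""
    per_step: Dict[str, List[float]] = {}
    for s in cohort:
        for start, end, lab in s.labels.intervals:
            if lab is not StepLabel.NONE:
                per_step.setdefault(lab.name, []).append(end - start)
    rows = [
        {"step": k, "n": len(v), "mean_s": float(np.mean(v)),
         "sd_s": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for k, v in sorted(per_step.items())
    ]
    return pd.DataFrame(rows)


def learning_curve(cohort: Sequence[HygieneSession]) -> Dict[int, float]:
    """Mean per-session compliance at each chronological session index."""
    by_index: Dict[int, List[float]] = {}
    for s in cohort:
        idx = int(s.meta.get("session_index", 0))
        cm = compliance_matrix([s.labels], s.mode)
        by_index.setdefault(idx, []).append(cm.compliance)
    return {i: float(np.mean(v)) for i, v in sorted(by_index.items())}
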