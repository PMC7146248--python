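"""Per-window feature bank and boosted-tree feature selection.

The bank covers four families drawn from the activity-recognition
literature (see ``docs/feature_reference.md`` for the operational formula of
every feature):

* time-domain basics per channel: cumulative-sum dispersion (CSD), positive
  and negative peaks, RMS;
* AC/DC statistics per channel: the channel is split into a DC component
  (1 Hz zero-phase low-pass over the whole session) and an AC residual,
  then per-window statistics are taken of each part, plus posture-distance
  and total-mean features over each accelerometer/gyroscope axis triplet;
* jerk/level aggregates over axis triplets and the 8-electrode sEMG bank
  (means, ranges, first/second-difference statistics, and cross-axis
  ratios);
* spectral statistics per channel from the window periodogram (power,
  dominant-bin frequency, and spectral-entropy contributions).  At the
  default 5-sample window these are low-resolution (two usable bins);
  diagnostic tests use longer windows.

Degenerate statistics (skew/kurtosis/entropy of a constant window, ratios
with zero denominators) are defined as 0 so feature matrices are NaN-free.

Feature selection follows the classifier itself: a gradient-boosted tree
ensemble is fit on the training windows and features are ranked by the
number of tree splits that use them (ties broken by total gain, then by
column index); the top 100 form the final feature vector.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import signal as _signal

from .preprocess import ResampledSession, WindowSet

# --------------------------------------------------------------------------
# catalog

MCINTOSH = ["CSD", "peak (positive)", "peak (negative)", "RMS"]
TAPIA_CHANNEL = [
    "ACAbsArea", "ACAbsCV", "ACAbsMean", "ACEntropy", "ACIQR", "ACKur",
    "ACQ1", "ACQ3", "ACRange", "ACSkew", "ACVar", "DCArea", "DCMean",
]
TAPIA_TRIPLET = ["DCPostureDist", "DCTotalMean"]
XIE = [
    "|AL|", "|dAL|", "|dAR|", "|dMAV|", "AJ", "AL", "AR",
    "RAJ", "RMAV", "SAJ", "SDAL", "SDAR", "SRAJ",
]
# "medainS" is kept verbatim from the source feature table (sic).
ZHANG = [
    "meanPKT", "meanPSD", "medainS", "medianPKT", "medianPSD",
    "stdPKT", "stdPSD", "stdS",
]


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str
    scope: str  # per-channel | per-axis-triplet | per-emg-bank


def default_catalog() -> List[FeatureSpec]:
    """The full feature catalog, in canonical order."""
    catalog: List[FeatureSpec] = []
    catalog += [FeatureSpec(n, "mcintosh", "per-channel") for n in MCINTOSH]
    catalog += [FeatureSpec(n, "tapia", "per-channel") for n in TAPIA_CHANNEL]
    catalog += [FeatureSpec(n, "tapia", "per-axis-triplet") for n in TAPIA_TRIPLET]
    catalog += [FeatureSpec(n, "xie", "per-axis-triplet") for n in XIE]
    catalog += [FeatureSpec(n, "xie", "per-emg-bank") for n in XIE]
    catalog += [FeatureSpec(n, "zhang", "per-channel") for n in ZHANG]
    return catalog


@dataclasses.dataclass
class FeatureMatrix:
    """windows x named features, with per-window labels and center times."""

    values: np.ndarray
    feature_names: List[str]
    window_labels: np.ndarray
    window_times: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.window_labels)
        df.insert(0, "t", self.window_times)
        return df

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            window_labels=self.window_labels,
            window_times=self.window_times,
        )


# --------------------------------------------------------------------------
# extraction helpers (all vectorized over a (groups, windows, length) cube)


def _moments(x: np.ndarray):
    m = x.mean(axis=-1)
    c = x - m[..., None]
    m2 = (c**2).mean(axis=-1)
    m3 = (c**3).mean(axis=-1)
    m4 = (c**4).mean(axis=-1)
    return m, m2, m3, m4


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den != 0)


def _entropy8(x: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of the 8-bin normalized histogram of |x|."""
    a = np.abs(x)
    lo = a.min(axis=-1, keepdims=True)
    hi = a.max(axis=-1, keepdims=True)
    width = hi - lo
    ok = width[..., 0] > 0
    q = np.zeros_like(a, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(width > 0, (a - lo) / width, 0.0)
    q = np.clip((scaled * 8).astype(np.int64), 0, 7)
    n = a.shape[-1]
    ent = np.zeros(a.shape[:-1])
    for b in range(8):
        p = (q == b).sum(axis=-1) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log(p), 0.0)
        ent += term
    return np.where(ok, ent, 0.0)


def _mcintosh(win: np.ndarray) -> Dict[str, np.ndarray]:
    cs = np.cumsum(win, axis=-1)
    return {
        "CSD": cs.max(axis=-1) - cs.min(axis=-1),
        "peak (positive)": win.max(axis=-1),
        "peak (negative)": win.min(axis=-1),
        "RMS": np.sqrt((win**2).mean(axis=-1)),
    }


def _tapia_channel(ac: np.ndarray, dc: np.ndarray) -> Dict[str, np.ndarray]:
    a = np.abs(ac)
    abs_mean = a.mean(axis=-1)
    q1 = np.percentile(ac, 25, axis=-1)
    q3 = np.percentile(ac, 75, axis=-1)
    _, m2, m3, m4 = _moments(ac)
    return {
        "ACAbsArea": a.sum(axis=-1),
        "ACAbsCV": _safe_div(a.std(axis=-1), abs_mean),
        "ACAbsMean": abs_mean,
        "ACEntropy": _entropy8(ac),
        "ACIQR": q3 - q1,
        "ACKur": np.where(m2 > 0, _safe_div(m4, m2**2) - 3.0, 0.0),
        "ACQ1": q1,
        "ACQ3": q3,
        "ACRange": ac.max(axis=-1) - ac.min(axis=-1),
        "ACSkew": np.where(m2 > 0, _safe_div(m3, m2**1.5), 0.0),
        "ACVar": m2,
        "DCArea": dc.sum(axis=-1),
        "DCMean": dc.mean(axis=-1),
    }


def _xie(group: np.ndarray) -> Dict[str, np.ndarray]:
    """Level/range/jerk aggregates for one axis group.

    ``group`` has shape (axes, windows, length); statistics are taken per
    axis, then aggregated across axes.
    """
    d1 = np.diff(group, axis=-1)
    d2 = np.diff(group, n=2, axis=-1)
    level = group.mean(axis=-1)            # (axes, windows)
    rng = group.max(axis=-1) - group.min(axis=-1)
    jerk = np.abs(d1).mean(axis=-1)
    mav = np.abs(group).mean(axis=-1)
    jerk_sum = jerk.sum(axis=0)
    mav_sum = mav.sum(axis=0)
    return {
        "AL": level.mean(axis=0),
        "|AL|": np.abs(level).mean(axis=0),
        "SDAL": level.std(axis=0),
        "|dAL|": np.abs(d1.mean(axis=-1)).mean(axis=0),
        "AR": rng.mean(axis=0),
        "SDAR": rng.std(axis=0),
        "|dAR|": (d1.max(axis=-1) - d1.min(axis=-1)).mean(axis=0),
        "AJ": jerk.mean(axis=0),
        "SAJ": np.abs(d1).sum(axis=-1).sum(axis=0),
        "RAJ": _safe_div(jerk.max(axis=0), jerk_sum),
        "SRAJ": _safe_div(jerk.min(axis=0), jerk_sum),
        "RMAV": _safe_div(mav.max(axis=0), mav_sum),
        "|dMAV|": np.abs(d2).mean(axis=-1).mean(axis=0) if d2.shape[-1] else
                  np.zeros(group.shape[1]),
    }


def _zhang(win: np.ndarray, rate: float) -> Dict[str, np.ndarray]:
    length = win.shape[-1]
    spec = np.fft.rfft(win, axis=-1)
    power = (np.abs(spec) ** 2) / length
    power = power[..., 1:]  # drop the DC bin
    freqs = np.fft.rfftfreq(length, d=1.0 / rate)[1:]
    pmax = power.max(axis=-1, keepdims=True)
    has_power = pmax[..., 0] > 0
    peak_mask = (power >= 0.5 * pmax) & (pmax > 0)
    n_peaks = peak_mask.sum(axis=-1)
    f = np.broadcast_to(freqs, power.shape)

    def _peak_stat(kind: str) -> np.ndarray:
        vals = np.where(peak_mask, f, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if kind == "mean":
                out = np.nanmean(vals, axis=-1)
            elif kind == "median":
                out = np.nanmedian(vals, axis=-1)
            else:
                out = np.nanstd(vals, axis=-1)
        return np.where(n_peaks > 0, np.nan_to_num(out), 0.0)

    total = power.sum(axis=-1, keepdims=True)
    q = _safe_div(power, np.broadcast_to(total, power.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(q > 0, -q * np.log(q), 0.0)
    zero = ~has_power
    stats = {
        "meanPSD": power.mean(axis=-1),
        "medianPSD": np.median(power, axis=-1),
        "stdPSD": power.std(axis=-1),
        "meanPKT": _peak_stat("mean"),
        "medianPKT": _peak_stat("median"),
        "stdPKT": _peak_stat("std"),
        "medainS": np.where(zero, 0.0, np.median(s, axis=-1)),
        "stdS": np.where(zero, 0.0, s.std(axis=-1)),
    }
    return stats


def _dc_component(x: np.ndarray, rate: float) -> np.ndarray:
    """1 Hz zero-phase low-pass of a full channel (the DC track).

    For signals too short to filter, falls back to the overall mean.
    """
    numtaps = 101
    n = x.shape[-1]
    if n <= 3 * numtaps:
        numtaps = max(3, (n - 1) // 3)
        if numtaps % 2 == 0:
            numtaps -= 1
    if numtaps < 3:
        return np.broadcast_to(x.mean(axis=-1, keepdims=True), x.shape).copy()
    taps = _signal.firwin(numtaps, 1.0, fs=rate)
    return _signal.filtfilt(taps, [1.0], x, axis=-1, padlen=min(3 * numtaps, n - 1))


# --------------------------------------------------------------------------
# extraction


def extract_features(
    windows: WindowSet,
    resampled: ResampledSession,
    catalog: Optional[List[FeatureSpec]] = None,
) -> FeatureMatrix:
    """Compute every catalog feature for every applicable channel or channel
    group, per window.

    Column names are fully qualified as ``placement.modality.axis.feature``
    (``placement.modality.feature`` for triplet/bank features); column order
    is catalog order (outer) x channel order (inner).
    """
    catalog = catalog if catalog is not None else default_catalog()
    length = windows.windows[0][1] - windows.windows[0][0]
    if length < 3:
        raise ValueError("windows shorter than 3 samples are not supported")

    matrix = resampled.matrix  # (channels, time)
    starts = np.array([s for s, _ in windows.windows])
    idx = starts[:, None] + np.arange(length)[None, :]
    cube = matrix[:, idx]  # (channels, windows, length)

    dc_full = _dc_component(matrix, resampled.rate)
    ac_full = matrix - dc_full
    dc_cube = dc_full[:, idx]
    ac_cube = ac_full[:, idx]

    names = resampled.channel_names
    info = resampled.channel_info
    # axis triplets (accel/gyro per placement) and emg banks per placement
    triplets: List[Tuple[str, List[int]]] = []
    banks: List[Tuple[str, List[int]]] = []
    seen = {}
    for i, ci in enumerate(info):
        key = (ci.placement, ci.modality)
        seen.setdefault(key, []).append(i)
    for (pl, mod), idxs in seen.items():
        if mod in ("accel", "gyro") and len(idxs) == 3:
            triplets.append((f"{pl}.{mod}", idxs))
        elif mod == "emg":
            banks.append((f"{pl}.{mod}", idxs))

    # precompute family results
    mc = _mcintosh(cube)
    tp = _tapia_channel(ac_cube, dc_cube)
    zh = _zhang(cube, resampled.rate)
    xie_groups = {gname: _xie(cube[idxs]) for gname, idxs in triplets}
    xie_banks = {gname: _xie(cube[idxs]) for gname, idxs in banks}
    dc_means = dc_cube.mean(axis=-1)  # (channels, windows)

    columns: List[np.ndarray] = []
    col_names: List[str] = []
    for spec in catalog:
        if spec.scope == "per-channel":
            fam = {"mcintosh": mc, "tapia": tp, "zhang": zh}[spec.family]
            vals = fam[spec.name]  # (channels, windows)
            for c in range(len(names)):
                columns.append(vals[c])
                col_names.append(f"{names[c]}.{spec.name}")
        elif spec.scope == "per-axis-triplet":
            for gname, idxs in triplets:
                if spec.name == "DCPostureDist":
                    m = dc_means[idxs]  # (3, windows)
                    for (a, b) in ((0, 1), (0, 2), (1, 2)):
                        columns.append(m[a] - m[b])
                        col_names.append(f"{gname}.DCPostureDist_{a + 1}{b + 1}")
                elif spec.name == "DCTotalMean":
                    columns.append(dc_means[idxs].mean(axis=0))
                    col_names.append(f"{gname}.DCTotalMean")
                else:
                    columns.append(xie_groups[gname][spec.name])
                    col_names.append(f"{gname}.{spec.name}")
        elif spec.scope == "per-emg-bank":
            for gname, idxs in banks:
                columns.append(xie_banks[gname][spec.name])
                col_names.append(f"{gname}.{spec.name}")
        else:
            raise ValueError(f"unknown scope {spec.scope!r}")

    values = np.column_stack(columns) if columns else np.zeros((len(windows), 0))
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureMatrix(
        values=values,
        feature_names=col_names,
        window_labels=np.asarray(windows.labels),
        window_times=windows.centers(resampled.rate, resampled.t0),
    )


# --------------------------------------------------------------------------
# selection


@dataclasses.dataclass
class FeatureSelector:
    """Top-k features ranked by split occurrences in a boosted ensemble."""

    ranked_features: List[Tuple[int, int]]  # (column index, split occurrences)
    feature_names: List[str]
    k: int = 100

    @property
    def indices(self) -> List[int]:
        return [i for i, _ in self.ranked_features]


DEFAULT_SELECTION_PARAMS = {
    "num_boost_round": 50,
    "max_depth": 6,
    "learning_rate": 0.1,
}


def select_top_features(
    train_features: FeatureMatrix,
    k: int = 100,
    boosting_params: Optional[dict] = None,
    seed: int = 0,
) -> FeatureSelector:
    """Rank features by how often a boosted tree ensemble splits on them.

    The ensemble is fit on the *training* windows only.  Ranking is split
    occurrences descending, ties by total gain descending, then by column
    index; features never used in a split fill the tail in index order.
    """
    params = dict(DEFAULT_SELECTION_PARAMS)
    if boosting_params:
        params.update(boosting_params)
    y = np.asarray(train_features.window_labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("selection undefined: training windows contain a single class")
    ymap = np.searchsorted(classes, y)

    n_features = train_features.values.shape[1]
    fnames = [f"f{i}" for i in range(n_features)]
    dtrain = xgb.DMatrix(train_features.values, label=ymap, feature_names=fnames)
    num_round = int(params.pop("num_boost_round"))
    params["eta"] = params.pop("learning_rate", 0.1)
    xgb_params = {
        "objective": "multi:softprob",
        "num_class": int(classes.size),
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed),
        "verbosity": 0,
        **params,
    }
    booster = xgb.train(xgb_params, dtrain, num_boost_round=num_round)
    occ = booster.get_score(importance_type="weight")
    gain = booster.get_score(importance_type="total_gain")
    counts = np.zeros(n_features, dtype=np.int64)
    gains = np.zeros(n_features, dtype=float)
    for name, c in occ.items():
        counts[int(name[1:])] = int(c)
    for name, g in gain.items():
        gains[int(name[1:])] = float(g)

    order = sorted(range(n_features), key=lambda i: (-counts[i], -gains[i], i))
    if k > n_features:
        warnings.warn(
            f"requested top {k} features but only {n_features} available; returning all"
        )
    chosen = order[: min(k, n_features)]
    return FeatureSelector(
        ranked_features=[(i, int(counts[i])) for i in chosen],
        feature_names=[train_features.feature_names[i] for i in chosen],
        k=k,
    )


def apply_selector(features: FeatureMatrix, selector: FeatureSelector) -> FeatureMatrix:
    """Column-subset a feature matrix to the selector's ranked features."""
    if not selector.ranked_features:
        raise ValueError("empty selector")
    idx = selector.indices
    if max(idx) >= features.values.shape[1]:
        raise IndexError(
            f"selector index {max(idx)} out of range for "
            f"{features.values.shape[1]} feature columns"
        )
    return features.select_columns(idx)
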