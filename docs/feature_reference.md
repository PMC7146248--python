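# Feature reference

Operational definition of every feature the bank computes.  The feature
names follow the activity-recognition literature the bank is drawn from
(McIntosh et al. — wearable gesture features; Munguia Tapia — AC/DC
accelerometer statistics; Xie et al. — sEMG level/jerk aggregates; Zhang
et al. — spectral statistics).  The original sources do not publish
machine-readable formulas, so the definitions below are reconstructions
fixed here for reproducibility; this document is the normative reference
for this package.  Names containing `∆` in the literature are rendered
with an ASCII `d` (`|∆AL|` → `|dAL|`).

Notation: a window is `x = (x_1 … x_L)` samples of one channel at 25 Hz
(default `L = 5`); `Δx` are first differences, `Δ²x` second differences.
Degenerate statistics (moments of a constant window, ratios with a zero
denominator, spectra with zero power) are defined as **0**, so feature
matrices are always finite.

## AC/DC split

Each channel of the resampled session is split once, before windowing,
into a **DC** track — a 1 Hz zero-phase FIR low-pass of the whole channel
(101 taps; for signals too short to filter, the channel mean) — and an
**AC** residual, `AC = x − DC`.  Windows index into both tracks.  A 1 Hz
filter inside a 0.2 s window is undefined, which is why the split is
performed at channel level.

## Per-channel time-domain (McIntosh)

| feature | definition |
|---|---|
| `CSD` | range of the cumulative sum: `max(cumsum x) − min(cumsum x)` |
| `peak (positive)` | `max x` |
| `peak (negative)` | `min x` |
| `RMS` | `sqrt(mean x²)` |

## Per-channel AC/DC statistics (Munguia Tapia)

All statistics are population moments over the window.

| feature | definition |
|---|---|
| `ACAbsArea` | `Σ |AC|` |
| `ACAbsMean` | `mean |AC|` |
| `ACAbsCV` | `std |AC| / mean |AC|` |
| `ACEntropy` | Shannon entropy (nats) of the 8-bin normalized histogram of `|AC|` |
| `ACQ1`, `ACQ3`, `ACIQR` | 25th / 75th percentile of AC, and their difference |
| `ACRange` | `max AC − min AC` |
| `ACVar` | population variance of AC |
| `ACSkew`, `ACKur` | standardized third moment; excess kurtosis |
| `DCArea`, `DCMean` | `Σ DC`; `mean DC` |

Per axis triplet (accelerometer and gyroscope of one armband):

| feature | definition |
|---|---|
| `DCPostureDist_12/13/23` | pairwise differences of the per-axis window DC means |
| `DCTotalMean` | mean of the three per-axis DC means |

## Level/jerk aggregates (Xie), per axis triplet and per sEMG bank

Per axis `a`: level `L_a = mean x_a`, range `R_a = max − min`,
jerk `J_a = mean |Δx_a|`, `MAV_a = mean |x_a|`.  Aggregates over the
group's axes (3 for accel/gyro, 8 electrodes for sEMG):

| feature | definition |
|---|---|
| `AL`, `\|AL\|`, `SDAL` | `mean_a L_a`; `mean_a |L_a|`; `std_a L_a` |
| `\|dAL\|` | `mean_a |mean Δx_a|` |
| `AR`, `SDAR` | `mean_a R_a`; `std_a R_a` |
| `\|dAR\|` | `mean_a range(Δx_a)` |
| `AJ` | `mean_a J_a` |
| `SAJ` | `Σ_a Σ |Δx_a|` |
| `RAJ`, `SRAJ` | `max_a J_a / Σ_a J_a`; `min_a J_a / Σ_a J_a` |
| `RMAV` | `max_a MAV_a / Σ_a MAV_a` |
| `\|dMAV\|` | `mean_a mean |Δ²x_a|` |

## Spectral statistics (Zhang), per channel

`p_k = |rfft(x)_k|² / L` over the non-DC bins `k ≥ 1` with frequencies
`f_k`; `q_k = p_k / Σp`; entropy contributions `s_k = −q_k ln q_k`.
The *peak set* is `{k : p_k ≥ ½ max p}`.

| feature | definition |
|---|---|
| `meanPSD`, `medianPSD`, `stdPSD` | moments of `p_k` |
| `meanPKT`, `medianPKT`, `stdPKT` | moments of the peak-set frequencies (Hz) |
| `medainS`, `stdS` | median / SD of `s_k` (`medainS` is kept verbatim from the source table) |

At the default 5-sample window only two non-DC bins exist; the spectral
family is low-resolution there by design and is exercised with longer
diagnostic windows in the tests.

## Column naming

Feature matrices qualify each column as
`placement.modality.axis.feature` (per-channel) or
`placement.modality.feature` (triplet/bank), e.g. `RF.accel.ax.RMS`,
`LF.gyro.DCTotalMean`, `RF.emg.AJ`.  Column order is catalog order
(outer) × channel order (inner).
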