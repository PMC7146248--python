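# Methods

## Problem

The WHO hand-hygiene guidelines prescribe fixed step sequences for
alcohol-based handrub (11 performable steps) and handwash with soap and
water (13 performable steps; wetting hands and applying soap are excluded
because faucet/dispenser geometry varies).  Together the grammars span 14
step classes plus a residual `NONE` that is never trained on.  The package
recognizes these steps from armband recordings — per armband a 3-axis
accelerometer (g), 3-axis gyroscope (deg/s) and fused orientation
quaternion at 50 Hz, plus 8 sEMG electrodes at 200 Hz — worn at up to four
placements: left/right × arm/forearm.

## Pipeline

1. **Resampling.**  All channels are brought to 25 Hz.  IMU channels:
   10 Hz zero-phase FIR low-pass (31 taps), decimation 2:1.  sEMG:
   full-wave rectification, 10 Hz zero-phase low-pass (51 taps) — the
   standard envelope — then decimation 8:1.  Naive 8:1 decimation of a
   broadband sEMG signal aliases to noise, so the envelope is the default;
   `emg_mode="decimate"` skips rectification for comparison.  Orientation
   quaternions are renormalized after filtering.
2. **Normalization.**  Per channel, per session z-score with the
   population SD (denominator *n*; one convention fixed for bit-stable
   tests); zero-variance channels map to zeros.  Session-local
   normalization avoids any train/test coupling through shared statistics.
3. **Windowing.**  0.2 s windows with 75 % overlap.  At 25 Hz a window is
   5 samples and an exact 75 % overlap is non-integral, so the hop is
   1 sample (80 % effective overlap) — the one documented deviation from
   the nominal overlap.  Window label = majority sample label, ties broken
   by the center sample, then by the smallest class index.  `NONE`-majority
   windows are flagged and retained but excluded from training and from
   accuracy denominators.
4. **Features.**  The full bank (≈500 columns per armband) is described in
   `feature_reference.md`.  Selection refits a boosted ensemble **inside
   every cross-validation training fold** and keeps the 100 features most
   often used in tree splits (ties by total gain, then column index);
   refitting per fold avoids optimistic bias from test windows.
5. **Classification.**  Gradient-boosted trees (softmax probability,
   histogram method, single thread).  Library defaults: 200 trees, depth
   6, learning rate 0.1 — frozen so runs are reproducible; all evaluation
   entry points accept overrides.
6. **Smoothing.**  The prediction stream (class-probability rows, not
   hardened labels — the energy statistic wants points in a metric space
   and probabilities preserve classifier uncertainty; `cp_input="onehot"`
   is available) is segmented by the hierarchical divisive energy
   procedure and each segment is relabeled by majority vote.  Defaults
   follow the reference implementation of the cited method: `alpha = 1`,
   `R = 199` permutations, `sig_level = 0.05`, `min_size = 30` windows
   (≈1.2 s at hop 1 — the shortest detectable step).  The permutation test
   permutes within current segments and uses the +1-corrected p-value;
   detection runs per session, the natural recording unit.

## Energy-divisive change points

For samples X (m points) and Y (n points), with α ∈ (0, 2]:

    ê(X,Y) = 2/(mn) Σᵢⱼ ‖xᵢ−yⱼ‖^α − C(m,2)⁻¹ Σ_{i<k} ‖xᵢ−xₖ‖^α
             − C(n,2)⁻¹ Σ_{j<k} ‖yⱼ−yₖ‖^α
    q̂(X,Y) = mn/(m+n) · ê(X,Y)

Within-sample terms vanish for singletons.  The best split of a segment
maximizes q̂ over all splits leaving ≥ `min_size` points on each side (ties
to the smallest index).  Splits are accepted while the permutation p-value
stays ≤ `sig_level`.  Distances are computed once per stream (O(n²)
memory); every split scan is then linear via cumulative sums, and a
permutation replicate costs one O(n²) re-indexing — adequate for streams
up to a few thousand windows.

Numerical notes: the statistic is translation-invariant and, for α = 1,
positively homogeneous, so change-point locations are invariant to
offset and positive scaling of the stream; both properties are tested.
The test is exact: with R = 199 and level 0.05 a split is accepted iff the
observed q̂ ranks in the top 10 of 200 exchangeable values.

## Evaluation protocols

* **LOSO** (user-dependent): within one participant, each session is held
  out once; the participant's accuracy is the unweighted mean over
  sessions.
* **LOPO** (user-independent): one fold per participant; a participant's
  accuracy pools all their windows; the cohort accuracy is the unweighted
  mean over participants.  Pooled window accuracy is also reported and
  labeled.
* **Bootstrapping curve**: per repetition the participant's sessions are
  shuffled; for each N the model trains on the first N and tests on the
  rest; 20 repetitions by default; the raw (non-monotonized) curve is
  reported.
* **Ablations**: eight placement sets (four singles, four pairs) × raw vs
  smoothed; six sensor combinations (ACC, GYRO, EMG, ACC+GYRO,
  ACC+GYRO+ORI, ACC+GYRO+ORI+EMG) under LOPO.  The device's nine-axis IMU
  exposes fused orientation rather than raw magnetometer data, so the
  "nine-axis" configuration maps to ACC+GYRO+ORI.  Sensor subsetting is
  defined before preprocessing; because resampling, z-scoring and all
  features operate per channel or within one modality group, the harness
  equivalently computes the full feature table once per (session,
  placement) and subsets columns, which keeps ablations affordable.
* **Compliance analytics**: the performed sequence (run-length collapse of
  the label track) is aligned to the canonical grammar by global edit
  distance (match 1, mismatch 0, gap −0.5; ties prefer the diagonal), so a
  swapped left/right pair scores as two mismatches rather than two gaps.
  Each expected step counts toward the performed step aligned to it, or
  `MISSED` for a gap; compliance is the mean fraction of expected steps
  aligned to themselves.  Duration summaries and the per-session-index
  compliance curve expose the inputs for any further statistics; formal
  hypothesis testing is out of scope.

## Synthetic cohort

No recordings of this kind are publicly deposited, so the simulator
generates cohorts with the statistical structure the pipeline assumes.
Defaults are the study conditions: 20 participants × 30 sessions (5 video
+ 10 poster per mode); condition duration models Normal(53.4, 1.1) s for
handwash/video, (47.9, 8.3) handwash/poster, (37.1, 1.4) handrub/video,
(32.6, 5.3) handrub/poster, split across steps by a symmetric Dirichlet
(concentration 20) with a 0.5 s per-step floor.

**Grammar deviations.**  Each symmetric left/right pair swaps with
probability `p_swap = 0.057`; each step is omitted with `p_miss = 0.008`.
These were calibrated once against the position-match compliance measure
(fraction of canonical positions performed as expected; a miss shifts all
later positions, costing ≈(k+1)/2k) to land at 0.91 — the compliance level
of trained performers — and then frozen; Monte-Carlo over 10 000 sequences
gives 0.913.

**Signals.**  Steps are rendered as class sinusoids (tempo 1.2–4.2 Hz
spread over the classes, class-specific per-axis amplitudes) for
accelerometer and gyroscope, plus the gravity direction of the
class-specific posture quaternion in the accelerometer; orientation is the
biased posture quaternion with small-angle noise; sEMG is a Gaussian
carrier modulated by a class-specific 8-electrode envelope.  Consecutive
steps cross-fade over 0.3 s; cross-fade samples carry the later step's
label, mirroring frame-exact annotation.  The signal bank is drawn once
from a frozen internal seed.

**Participant idiosyncrasies** create the user-dependent/user-independent
gap: multiplicative tempo/amplitude/sEMG gains (log-normal, clipped to
[0.5, 2]), an orientation bias (rotation-vector SD 0.45 rad) that composes
with every posture and rotates the inertial axes, and a circular sEMG
electrode rotation (armbands are donned at arbitrary rotation, so
electrode indices do not correspond across users — this is what makes sEMG
features user-dependent, consistent with the observation that sEMG adds
little to user-independent models).  **Placement quality**: ARM placements
receive a 0.6 signal gain and 3× noise; since per-channel z-scoring
removes uniform gains, the noise amplification is the operative mechanism.
These magnitudes were tuned once so that the default cohort shows
user-dependent > user-independent accuracy and forearm > arm, then frozen.

What the simulator does **not** model: real biomechanics (signals are
stylized sinusoids), sensor drift/bias, packet loss, inter-step
variability of posture within a class, or annotation noise.  Passing
tests therefore demonstrate that the pipeline recovers the structure the
generator encodes — calibration of the change-point test, the benefit of
smoothing, and the qualitative protocol orderings — not field performance
on real recordings.

## Desk-scale problem sizes

The evaluation protocols are exercised on a reduced cohort of 6
participants × 8 sessions (`SimulationConfig.desk_scale()`), with smaller
boosters (selection: 15 rounds, depth 4; classifier: 40 rounds, depth 4,
learning rate 0.3, 64 histogram bins) and a training-window stride of 5
(LOSO) / 10 (LOPO): at hop 1 adjacent windows share 4 of 5 samples, so
striding training windows discards almost no information while test
windows are always scored in full.  The synthetic classes are far more
separable than real gestures, so these small ensembles saturate accuracy;
the full-size defaults remain available through every config.  The
change-point recovery experiment uses a 1 % stopping level: each extra
split is an independent gamble at the stopping level, so at 5 % an
experiment about localization would instead measure the stopping rule.

## Known limitations

* The exact feature formulas of the cited sources are not published;
  `feature_reference.md` is a reconstruction and the normative definition
  here.
* Spectral features are nearly degenerate at the default 5-sample window
  (two usable bins).
* The compliance alignment is one reasonable choice among several; a
  position-wise comparison (used for calibration) penalizes misses more
  heavily.
* O(n²) distance storage limits change-point detection to streams of a
  few thousand windows per session — ample for hand-hygiene sessions.
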