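# Methods

## The detection problem

An asynchronous (self-paced) motor-imagery BCI watches a continuous EEG
stream and must decide, every few tens of milliseconds, whether the user
is imagining a movement *right now*. The marker is motor-imagery
event-related desynchronization (MI ERD): a transient attenuation of the
mu/low-beta rhythm (8–28 Hz) over the contralateral motor cortex. In a
rehabilitation setting a false positive is worse than a miss — robot
feedback triggered by something other than motor intention reinforces
the wrong sensorimotor loop — so this detector is built
rejection-first: a single ROI channel carries the detection, and a small
set of *non-ROI* channels sited at the scalp sources of known
contaminants (visual and auditory evoked desynchronization) vetoes
anything that desynchronizes those sources more strongly than the ROI.

The working assumption is that scalp ERD spreads radially: a
desynchronization originating at some electrode appears at neighbouring
electrodes in attenuated form. A genuine MI ERD is therefore deepest at
the ROI; a pseudo-MI ERD radiating from an occipital or temporal source
is deepest there, and comparing depths discriminates the two.

## Signal chain

1. **Resample** to 64 Hz (polyphase, anti-aliased) and **band-pass**
   filter to the subject's ERD band with a 4th-order Butterworth applied
   forward–backward. Zero phase matters: the classifier's trough-timing
   and cross-correlation-lag features would otherwise inherit the
   filter's group delay.
2. **Band power**: the filtered signal squared and smoothed with a
   250-ms centered moving average. The estimator is unspecified
   upstream; 250 ms matches the ERD time scale and is configurable
   (`smooth_s`).
3. **Relative potential (RP)**: `RP = (A − R)/R × 100` in percent, where
   `A` is the running band power and `R` a baseline power. For
   cue-locked epochs the baseline is the mean power over −4…−2 s before
   the cue. For the online stream the baseline is the trailing 2-s mean
   band power before the window start, *frozen* while the start lies in
   a task or cool-down period so that feedback-evoked activity cannot
   corrupt the reference (the epoch-style baseline has no online
   analogue; this is the package's own choice).

## ERSP and channel screening

Time–frequency maps use a short-time DFT with 1-s Hann windows, 97 %
overlap and a 4–32 Hz grid at 1 Hz (at 64 Hz the grid is an exact 1-Hz
comb, so no interpolation is involved). Per channel and frequency the
trial-averaged power is referenced to the pre-stimulus −4…−2 s baseline
and expressed in dB. The baseline reference is the *geometric* mean of
baseline power (equivalently, the mean log-power is subtracted): this is
the log-domain baseline convention, and it makes the baseline-interval
mean of every ERSP trace exactly 0 dB — a property the test suite
asserts to 1e−6 dB. An arithmetic-mean reference cannot satisfy it
(Jensen's inequality).

Screening then proceeds:

* **ROI**: mean task-interval (0–2 s) ERSP topographies in five bands
  (8–12 … 24–28 Hz); the channel at the global minimum wins. The
  minimum must reach −1.5 dB (`min_depth_db`): pure noise leaves
  shallow minima near −0.7 dB on 30 trials, and accepting those would
  return an arbitrary channel, so shallower minima raise a "no ERD
  found" error. With 32 discrete electrodes the argmin channel *is* the
  "channel closest to the deepest area"; no spatial interpolation is
  attempted.
* **Band**: at the ROI, the contiguous 1-Hz run of frequencies whose
  task-interval ERSP reaches half the depth of the deepest bin
  (`depth_fraction = 0.5`), widened toward the deeper neighbour until it
  spans at least 3 Hz. The choice is double-checked by recomputing the
  topography over the chosen band; if the ROI is no longer the minimum,
  a warning is raised and flagged in the diagnostics (not fatal — the
  original workflow re-inspects rather than overrides).
* **Non-ROI candidates**: the same band topography on each
  contamination paradigm (auditory cue, action-observation video,
  non-motor imagery), ranked most-negative-first; the top 2 negative
  channels per paradigm enter the pool.
* **Combination search**: every candidate subset of size 1–3 is run
  through the *full* two-phase classifier over the contamination-
  paradigm recordings; the subset removing the largest fraction of the
  baseline (no non-ROI) detections wins. Ties break toward higher
  selectivity on the MI recording, then the smaller subset, then label
  order. Because both phases compare the ROI against *every* non-ROI
  channel, growing the subset can only shrink the detection set, so the
  search objective is monotone in subset size (asserted on synthetic
  sessions).

## Two-phase classifier

The stream is cut into 3-s windows advancing one sample at a time
(the nominal 20-ms step rounds to one sample at 64 Hz, i.e. 15.6 ms —
20 ms is incommensurate with the working rate). Each window is split
into a front area [0, 2) s and a hind area [2, 3) s; a promising ERD
carries its trough in the hind area, which minimizes detection latency.

**Phase 1** computes, per channel, the hind-area trough `Peak_HW` and
its time `t_PH` (earliest sample on ties), the area means `Mean_FW`,
`Mean_HW`, their difference `ΔMean`, and the decline angle

    θ_ERD = atan( (Peak_HW − Mean_FW) / (t_PH − t_FW) ),   t_FW = 2 s

with the numerator in RP percent and the denominator in seconds — no
rescaling, which is valid because θ is only ever *compared across
channels* at identical window geometry (atan is monotone, so the
comparison is a slope comparison). The window passes iff the ROI shows
`Peak_HW < 0`, `Mean_HW < 0` (configurable), `θ < 0`, and against every
non-ROI channel: deeper trough, lower hind mean, larger front-to-hind
drop and steeper decline. An empty non-ROI list degrades to the
ROI-only conditions (the ablation arm).

**Phase 2** compares the window with the subject's training template:
Pearson correlation at zero lag `R`, and the maximum `CC_max` (with its
lag `CC_lat`) of the normalized cross-correlation over ±0.5 s. Inside
the engine each lagged window is fully populated from the surrounding
stream; the standalone function falls back to truncated overlap when
only the bare window exists. Zero lag is part of the search, so
`CC_max ≥ R` always; ties prefer the smallest |lag|. A zero-variance
window or template yields all-zero features, flagged. The window is
accepted iff `|CC_lat| ≤ 0.25 s`, `R ≥ r_threshold` (default 0.7,
runtime-adjustable) and, against every non-ROI channel, both `CC_max`
and `R` are strictly larger on the ROI. Correlation features are
amplitude-scale invariant, so this stage judges *shape*, not magnitude.

Because Pearson correlation is invariant under the affine map from raw
band power to RP, the engine evaluates phase 2 directly on power
series; the suite cross-checks the vectorized arrays against the
per-window reference functions.

**Template**: 3-s windows sliding over the band-filtered −4…+4 s MI
epochs; keep windows that pass phase 1 (against the full non-ROI
candidate pool — the final subset does not exist yet, since the subset
search itself needs the template) with the hind-area trough inside
(0, 2] s post-cue, at most the deepest-trough window per trial, and
average pointwise. A kept window must also reach −20 % RP
(`min_peak_pct`): the ROI-only phase-1 conditions are sign tests, and
without a depth demand an epsilon-deep noise dip would qualify as a
"training exemplar".

**Threshold recalibration**: to absorb day-to-day variation,
`r_threshold` can be re-fit on a practice run by grid search over
[0.30, 0.95] in steps of 0.05, maximizing selectivity subject to
sensitivity ≥ 20 %; ties go to the larger (more conservative) value,
and if nothing meets the floor the prior threshold is kept with a
warning.

## Session engine and scoring

Detections are stamped at the window *end* (newest sample). A counted
detection starts a 3-s refractory during which the detector is offline.
Windows ending inside a scheduled cool-down interval are still
evaluated, but a positive decision there is recorded as
`ignored_cooldown` and excluded from the counts (and starts no
refractory). Scoring follows the block design: a detection in a task
period is a TP (at most one per task period, so TP ≤ trials), in a rest
period an FP.

Block presets (all configurable, none hard-coded into the engine):

| preset          | layout per block                     | blocks | scored rest |
|-----------------|--------------------------------------|--------|-------------|
| calibration     | 10 s rest, 2 s task, 2 s buffer      | 30     | 5 min       |
| online healthy  | 6 s rest, 2 s pre, 2 s task, 2 s post| 30     | 3 min       |
| online stroke   | 8 s rest, 2 s pre, 4 s task, 2 s post| 30     | 4 min       |

These reproduce the FPM denominators of the reference session tables
exactly (FP/5, FP/3, FP/4 per minute).

## Metrics

sensitivity = TP/trials·100; selectivity = TP/(TP+FP)·100; FP rate =
FP/trials·100; FPM = FP per scored rest minute; rejection rate =
rejected/(FP without non-ROI)·100, not applicable when the ablated run
produced no FPs. Group "Average" rows pool selectivity
(ΣTP/Σdetections) and average the per-subject FP rate, FPM and
sensitivity — with equal trial counts the mean FP rate equals the
pooled one, which is why both conventions agree in the reference
tables. Display rounding is half-up to two decimals; full precision is
kept internally. The bundled reference tables mix truncation and
half-up in a few Average cells, so the regeneration tests allow ±0.015
on generic cells while the headline aggregates reproduce exactly at two
decimals. Four printed cells are internally inconsistent with their own
row's counts and are excluded from the checks (they are listed next to
the frozen tables in the test suite).

## Synthetic data model

The generator produces what the detector's assumptions describe, with
ground truth:

* **Background**: per-channel 1/f pink noise (8 µV RMS) mixed with a
  spatially correlated common pink component (weight 0.4).
* **Rhythms**: every channel carries one intrinsic oscillation modelled
  as a constant-envelope sinusoid whose instantaneous frequency drifts
  inside its band (Ornstein–Uhlenbeck drift, τ = 0.4 s, s.d. = width/6).
  Constant envelope is deliberate: the band power of a Gaussian
  band-noise rhythm is χ²-distributed and its ±50 % swings at non-ROI
  channels would veto genuine MI windows for reasons that have nothing
  to do with contamination. With an FM rhythm, the event envelope — not
  amplitude noise — carries the ERD.
* **Events spread as modulation, not superposition.** An event at a
  source attenuates the source's rhythm by `erd_depth` and every other
  channel's rhythm by `erd_depth · exp(−d/spread_scale)` (montage
  distance `d`, scale 0.4 head radii), with raised-cosine 0.25-s ramps;
  the noise floor is untouched. The source channel therefore always
  shows the strongest desynchronization and neighbours a graded,
  shape-identical pseudo-ERD — exactly the premise the rejection stage
  relies on, and the test suite asserts it per event (source trough
  deeper than the ROI trough in ≥ 95 % of contamination events).
  Additive waveform leakage was tried first and cannot work: a leaked
  copy beats coherently against the receiving channel's own rhythm, and
  the resulting power ripple `2·√(P_roi·P_leak)` always dominates the
  leaked power step `0.75·P_leak` unless the leak outweighs the local
  rhythm several-fold, which would destroy MI detectability instead.
* **Defaults** (chosen once to satisfy the stated qualitative orderings
  and the recovery targets; all are exposed parameters): MI mu source
  20 µV at C3, depth 0.5; contamination sources 25 µV at O1/O2 (visual)
  and T7 (auditory), depth 0.8 — sensory alpha blocking is typically
  near-complete, and it is the contamination *depth*, not amplitude,
  that reaches the ROI under the modulation model; idle rhythms 10 µV;
  all rhythm bands 10–12 Hz, so the drifting frequency stays inside
  whatever ≥3-Hz band the screening selects (occupancy outside the
  subject's filter band would read as spurious power collapse);
  generation at 128 Hz; in online sessions each rest period receives a
  contamination event of a random type with probability 0.6.
* **Block designs** follow the presets above; 30-trial calibration
  sessions last exactly 7 minutes.

What the generator does *not* emulate: volume-conducted waveform mixing
(see above), bursty amplitude dynamics of real mu rhythm, eye/muscle
artifacts, electrode drift and impedance changes, or day-to-day
non-stationarity. Passing the synthetic recovery targets therefore
shows that the pipeline implements its own model faithfully and that
the rejection logic does what it claims under the radial-spread
premise — not that these operating points would be attained on real
patients (the bundled clinical tables show what real sessions gave).

## Numerical choices and edge cases

* Sample indexing 0-based; all intervals half-open; cue sample =
  `floor(onset·rate)`.
* Hind-area trough ties: earliest sample wins. A trough exactly at the
  split makes the decline-angle denominator zero; θ then saturates at
  ±π/2.
* ERSP frequencies map to the nearest DFT bin; bins with analytically
  zero power (pure-tone inputs) are clamped away from log(0) but their
  dB values are meaningless, as with any spectrogram.
* The non-ROI search with zero rejected FPs falls back to the
  highest-MI-selectivity subset, with a warning.
* Determinism: the generator is a pure function of its seed, and the
  engine contains no randomness, so synth + simulate reports are
  byte-identical across runs (asserted).

## Problem sizes used in the validation suite

Unit tests run on 6–15-trial sessions; the end-to-end recovery check
runs 20 seeded subjects at the full 30-trial defaults; the reproduction
script (`scripts/acceptance.py`) regenerates every table aggregate from
the bundled counts and runs 10 seeded synthetic subjects.

## Known limitations

* The online RP baseline freeze rule is a design choice without a
  counterpart in cue-locked analysis; other choices (e.g. exponential
  forgetting) would shift the operating point.
* The exact cool-down durations of the online block designs are presets,
  not established constants; all scoring is reported against the
  schedule actually used.
* EDF/BDF support is read-only (via mne); the internal ``.npz``
  container is the round-trip-exact format.
* With shape-identical graded pseudo-ERD, the phase-2 similarity
  comparisons between ROI and non-ROI channels are decided by local
  SNR; motor-adjacent channels admitted into the non-ROI set by the
  combination search measurably cost sensitivity, mirroring the
  original observation that non-ROI selection may reject true MI in
  some cases.
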