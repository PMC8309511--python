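# Methods

`gazebehave` parses screen-based eye-tracking recordings into oculomotor
events and gaze *behaviours*, renders the results at three abstraction
levels, and evaluates detectors against scripted stimuli.  This note
documents the models, the defaults and why they were chosen, and what the
bundled simulator does and does not capture.

## Data model and conventions

A recording is a strictly time-ordered sequence of samples
`(t_ms, x, y, left_valid, right_valid)`.  Positions are either screen
pixels (origin top-left, y downward) or visual-angle degrees about the
screen centre; the conversion uses the per-axis flat-screen tangent
`deg = atan(offset_mm / viewing_distance)`, which is standard for desktop
monitors and invertible on the screen rectangle.  The great-circle angle
is not used; at desktop eccentricities (< 30°) the per-axis error is well
below the noise floor of consumer trackers.

Velocity is the two-point backward difference between consecutive samples
in deg/s, with the first sample's velocity defined as 0.  No velocity
smoothing is applied: the parsing algorithms here are deliberately the
plain single-threshold formulations whose parameter sensitivity the
toolkit is designed to expose.

Blink handling is minimal by design: samples reported invalid in *both*
eyes are treated as outliers and can be removed (`remove_binocular_dropouts`);
one-eye samples are retained.  No pupil-based blink model is attempted.

## Event detectors

* **I-VT** — one parameter `v_T` (deg/s).  Per-sample thresholding, then
  maximal runs.  No minimum-duration filter is applied, so
  threshold-boundary "blips" (one fixation splitting into several at
  particular `v_T` values) are preserved; they are part of what the
  toolkit measures.  `merge_short_segments` and `stare_regions` are
  explicit, off-by-default post-processing utilities.
* **I-DT** — window growth in the Salvucci–Goldberg form: initialize the
  window to cover `dur_T` ms; if dispersion `(max x − min x) + (max y −
  min y) ≤ D_T`, grow until the next sample would exceed it and emit a
  fixation, else slide one sample.  Each grown window is emitted as its
  own fixation even when windows touch, so every reported fixation
  individually satisfies both thresholds.
* **DBSCAN with IQR** — density clustering on `(x, y, w·t̃)` where `t̃` is
  the timestamp min-max scaled to the spatial extent and `w` is a time
  weight (default 1.0).  The automatic radius is the third quartile
  (linear-interpolation quantile) of sample distances from the data
  centroid.  That rule matches data concentrated around one area; on
  multi-target layouts the Q3 distance is on the scale of the layout
  itself (every sample sits roughly one half-diagonal from the global
  centroid), which chains all clusters together.  For such scripts the
  recommended parameters therefore pass a foveal-scale explicit
  `eps ≈ 1°`.  DBSCAN itself is implemented in-package because the border
  rule is pinned down exactly: a non-core point is assigned to the cluster
  of its lowest-index core neighbour; tests cross-check the core-point
  partition against scikit-learn's DBSCAN and a naive quadratic
  implementation.
* **I-VDT** — stage 1 removes saccades with `v_T`; stage 2 splits each
  slow run with the same window-growth rule as I-DT: a sub-window covering
  at least 100 ms (config `min_fix_dur_ms`) with dispersion ≤ `D_T` is
  fixation, samples that cannot open such a window are smooth pursuit.
  The minimum window duration matters: with a 2-sample minimum, steady
  pursuit at 30 deg/s (≈ 0.75°/sample at 40 Hz) would be chopped into
  endless 3-sample "fixations" because any short window passes a 1.5°
  dispersion test; a 100 ms window spans ≈ 3° of pursuit and classifies
  correctly.  A run tail shorter than the window is classified as a block
  by its dispersion.

All detectors emit segments that partition the sample range; each segment
carries its member-sample centroid and duration.

### Recommended parameters

For the bundled 40 Hz tasks (`RECOMMENDED`): box task — I-VT `v_T = 30`,
I-DT `D_T = 3°, dur_T = 100 ms`, DBSCAN `min_points = 4, eps = 1°`, I-VDT
`v_T = 30, D_T = 3°`; pursuit tasks — I-VDT `v_T = 50, D_T = 1.5°` (the
velocity gate must sit above the 30 deg/s pursuit plus noise, and the
dispersion test below the ≈ 3° the pursuit covers per 100 ms window).
The I-DT dispersion threshold is wider than the classical 1° because the
simulated fixational noise (drift plus return-biased microsaccades) can
spread a 3 s stay over ≈ 2–2.5° summed x/y range.

## Stare/move behaviour imaging

The behaviour classifier does not consume velocities; it consumes small
images.  A window of 32 × 32 degrees — large enough that a 10–30 deg/s
pursuit arc over the retained history and the 1–2° foveal region both fit
— is centred on each gaze sample.  The current sample and its `history_n`
predecessors inside the window are drawn oldest-first as 1 px dots on a
black background, with opacity fading linearly with age
(`fade(age) = (n+1−age)/(n+1)`); overlapping dots combine by maximum so
the newest dot stays on top.  Defaults: 64 × 64 px raster, `history_n = 8`
(200 ms at 40 Hz).  Fixation and smooth pursuit map to *stare* (both hold
the target on the fovea); saccades and post-saccadic oscillations map to
*move*; anything else is excluded.

Windows are anti-alias-free integer rasters, which makes translation
equivariance exact and the rendering deterministic.

## Classifiers

Three small convolutional networks, implemented on an in-package numpy
layer stack (im2col convolution, 2×2 max pooling, dense layers, softmax
cross-entropy, Adam):

| name | conv | pool | fc | activation |
|---|---|---|---|---|
| `cnn3` | 3 | 1 | 2 | ReLU |
| `alexnet_like` | 5 | 3 | 3 | ReLU |
| `lenet_like` | 2 | 2 | 3 | sigmoid |

Channel widths are modest (8–24) so the nets train in minutes on one CPU
core at 64² input.  Fixed hyperparameters: Adam 1e-3, batch 64, inputs in
[0, 1], cross-entropy loss; training is bit-reproducible at a fixed seed.
Accuracy is the standard `(TP + TN) / total` with *stare* as the positive
class.  The default training length is 6 epochs: the separable structure
of the windows is learned within a couple of epochs, and the capacity
ordering between the architectures is visible before both ReLU nets
saturate on the synthetic corpus.  Per-window predictions become
behaviour segments by merging runs shorter than `min_run` (default 2)
into the longer neighbouring run, ties toward stare — the window-level
classifier has no notion of events, so some aggregation rule is required
and this one is the simplest that removes single-sample flicker.

## Evaluation metrics

*FQnS* is the percentage of eligible stimulus-fixation samples at which a
detected fixation is active with centroid within `dist_tol` (default
1.5°, mid-foveal) of the stimulus position; samples within a 200 ms
saccadic-latency window after each stimulus fixation onset are excluded
since the eye cannot yet have arrived.  *FQlS* is the mean
centroid-to-stimulus distance over samples where a detected fixation is
active (lower is better).  The pursuit pair scores the percentage of
stimulus-pursuit samples covered by detected pursuit with gaze position
within 2° (position variant) or gaze speed within 10 deg/s of the target
speed (velocity variant).  The literature names these inconsistently
(PQnS vs PQlS_P/PQlS_V); the package exposes `pursuit_position_score` /
`pursuit_velocity_score`.

Range-Coefficient sweeps re-run a detector over the one-parameter family
`threshold(RC) = C + RC · Vi · T` and record one score per integer RC.
The published composition of T, Vi and C is ambiguous (the formula is
stated but the units are not); this linear rule is the simplest reading
that makes `Vi = 0` a constant sweep and is exposed in the sweep result
for transparency.

F1 is computed per class at the *sample* level (no event-matching
tolerance is defined anywhere authoritative); classes absent from the
truth are reported as missing (NaN) rather than 0.

## The simulator

`simulate_gaze` turns a stimulus script (waypoints + stay/transition
timing) into a gaze recording with per-sample truth labels.  The eye
model:

* **Stays** — fixation at the waypoint with three micromovement
  components: ~90 Hz tremor (amplitude 0.05°, aliased at low sampling
  rates exactly as a real tracker would see it); drift as an
  Ornstein–Uhlenbeck position process (τ = 0.7 s, stationary std =
  0.3 s × drift_speed = 0.15° at the 0.5 deg/s default); Poisson
  microsaccades (1.5/s, amplitude 0.3°, 70 % return-biased, clamped so
  the total fixational excursion stays inside ≈ 1.5°).  The 95th
  percentile fixation radius stays under 2°, consistent with foveal
  fixation.
* **Pursuit** — target motion at ≤ 30 deg/s is tracked at
  `pursuit_gain` (default 0.95); the accumulating positional lag triggers
  a catch-up saccade at 2°, amplitude equal to the lag.
* **Saccades** — faster repositionings use a main-sequence-style duration
  `2.2·A + 21 ms` with a symmetric triangular velocity profile, capped at
  `saccade_peak_velocity` (600 deg/s).
* **Dropouts** — both-eye-invalid samples at `dropout_rate` (default 2 %),
  with the position frozen at the last value as consumer trackers do.

A sample's truth label is the event occupying the majority of its
sampling interval `(t_{i-1}, t_i]`, not the event at the instant `t_i`:
per-sample labels describe the motion since the previous sample, which is
also exactly what a sample-to-sample velocity estimate measures.  Labels
at event edges are therefore aligned with what any detector can observe.

Scripted tasks: the 4-target box task (rectangle corners with 15°, 27.5°,
15° consecutive separations, 3 s stays, 0.1–2 s transitions) and two
6-point tasks (30 deg/s target, up–down or Z-shaped, with 3 s stops or
pass-through).  The 6-point geometry spans ±10° on a regular layout and
is config-overridable, since no authoritative point spacing exists for it.

**What the simulator does not capture**: post-saccadic oscillations,
pursuit onset latency and asymmetric gain, saccadic suppression artifacts,
head movement, vergence, calibration drift, and tracker-specific noise
spectra.  Passing tests on simulated data therefore demonstrate algorithm
correctness and qualitative behaviour (parameter sensitivity, pursuit/
fixation separability), not performance on any particular hardware corpus.

## Bundled training corpus

`datasets.bundled_dataset` mixes ~160 short search-like scripts (random
waypoints, 0.35 s stays, fast transitions — dense saccade coverage), 10
six-point pursuit runs and 6 box runs, all at 40 Hz, and draws an exactly
class-balanced set of stare/move windows (default 4000 per class, split
50/50 into train/validation at the window level).  Validation accuracy on
this corpus is optimistic relative to truly held-out recordings because
neighbouring windows share most of their history; the corpus is meant for
sanity checks and architecture comparison, not as a benchmark.

## Visualization

* **Heatmap (high abstraction)** — per-pixel counts of fixation samples
  (saccade samples contribute nothing), Gaussian-smoothed with a 1°
  bandwidth (the foveal scale), mapped through a perceptually ordered
  colormap with zero-count pixels transparent.  The pre-smoothing mass
  equals the fixation-sample count exactly.
* **Scanpath (low abstraction)** — fixation centroids as dots (radius
  scalable by duration) joined by straight links in time order, optionally
  over the raw points.
* **Abstract gaze movement (mid abstraction)** — one heatmap layer per
  stare segment, coloured by time order, composited oldest-first;
  consecutive layers joined by a straight link whose anchors are pulled
  one smoothing bandwidth out of the density cores so overlapping paths
  remain separable, tapered linearly from 6 px at the source to 2 px at
  the destination (thick→thin encodes direction), with the colour
  interpolating from the source layer's colour to the destination's.
  A constant-width legacy link style is available behind a flag for
  comparison figures.

All renderers are deterministic pure functions of their inputs and return
RGBA arrays.

## Problem sizes and numerical choices

The test-suite simulations run at 40 Hz (box task ≈ 500 samples, 6-point
≈ 100–800 samples); detector–oracle equivalence uses 200 random traces of
≤ 50 samples; the classifier checks train the three nets for 6 epochs on
2000 + 2000 windows per class.  Quartiles use linear interpolation;
dispersion comparisons use `<=` with no epsilon; cross-entropy clips
predicted probabilities at 1e-12; degenerate inputs (coincident points,
empty scripts, missing classes) raise informative errors rather than
guessing.

## Known limitations

* The DBSCAN auto-eps rule is global and therefore layout-dependent (see
  above); it is kept as specified-for-single-area use with an explicit
  override.
* Sample-level F1 understates boundary agreement at high sampling rates
  compared to event-level matching schemes.
* The numpy networks target small rasters and CPU batch sizes; they are
  not a general deep-learning framework.
* Simulated windows are cleaner than real tracker output; see the corpus
  note above.
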