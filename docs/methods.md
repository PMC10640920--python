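# Methods

This note records the model implemented by `gave`, the parameter choices
with their rationale, what the synthetic generators do and do not emulate,
and the numerical conventions that tests rely on.

## 1. Gaze model

### 1.1 Iris-center detection

An eye region is cropped from the frame around six eye landmarks (corners
plus two points per lid).  Segmentation proceeds as:

1. **Bilateral filter** (window 11 px, range/spatial sigmas 15): smooths
   sensor noise while preserving the iris/sclera edge.
2. **Grayscale erosion** (3×3 structuring element, 3 iterations): darkens
   and consolidates the iris blob, suppressing specular highlights.
3. **Binary threshold**: foreground = pixels *darker* than the threshold.
   `"auto"` (the default) uses the midpoint of the 5th and 95th intensity
   percentiles of the filtered crop, which is invariant to additive gray
   offsets and sits between the iris and background modes whenever the crop
   contains both.
4. **Centroid** via image moments: `cx = M10/M00`, `cy = M01/M00` — exactly
   the mean of the foreground pixel coordinates.

Degenerate results raise typed exceptions (`SegmentationError` when the
mask is empty or full, `PupilNotFoundError` for an empty centroid).

### 1.2 Ratios and renormalization

Raw ratios are the iris center's fractional position between the corner
x-coordinates (horizontal) and the eyelid midlines (vertical), clamped to
`[0, 1]`.  Because eyelids never open symmetrically around the iris and
corners bound more than the iris travel, raw ratios occupy a sub-interval;
they are renormalized with fixed pilot bounds — horizontal `0.28–0.87`,
vertical `0.48–0.95` — and clamped again.  The two eyes are combined by the
arithmetic mean; if only one eye yields a detection, that eye is used
alone, and `None` is returned if neither does.  Averaging (rather than
differencing) the eyes is the only combination consistent with both eyes
carrying the same signal plus independent noise.

Coordinates follow the mirrored webcam image: `h → 1` is a leftward gaze,
`v → 1` a downward gaze, and "left eye" means image-left (the subject's
right eye).

### 1.3 One-point calibration

A fixation of `duration = 2 s` on the screen center is averaged after two
filters: invalid (blink) samples are dropped, then samples farther than
`mad_factor = 2.5` median absolute deviations from the median in either
coordinate are rejected (if the MAD is exactly zero — a constant stream —
all samples are kept).  At least `min_valid_samples = 10` samples must
survive.  The result stores the neutral point `(h_c, v_c)`, the central
rectangle `w × l` (defaults `0.4 × 0.2` ratio units), the kept sample
count, and the pooled sample standard deviation.

### 1.4 Five-zone classification

A ratio pair is `center` iff `|h − h_c| ≤ w/2` **and** `|v − v_c| ≤ l/2`
(closed boundary, so the rectangle edge belongs to center).  Otherwise the
normalized excesses `e_h = (|Δh| − w/2)·2/w` and `e_v = (|Δv| − l/2)·2/l`
are compared; the larger axis wins (exact ties go to the horizontal axis,
which has the wider travel and is estimated more reliably).  Horizontal
excursions with `h > h_c` are `left` (mirrored image); vertical with
`v > v_c` are `down`.

### 1.5 Selection machine

Selection is two-stage: dwell on a direction to open a cluster of three
items (laid out on `left`/`down`/`right`; `up` always means *back*), then
dwell again to pick the item.  The machine is event-driven and
sample-rate-agnostic: a confirmation fires when the current event's
timestamp satisfies `t − dwell_start ≥ dwell_threshold` with an unbroken
run of the same direction since `dwell_start`.  Any excursion (including
`center`) resets the dwell, except excursions shorter than the optional
`grace_period` (default 0 s — strict resets).  If a stage lasts longer
than `timeout = 10 s` without a confirmation, the attempt is recorded as
missed and the machine resets to the cluster stage.

## 2. Synthetic generators

### 2.1 Eye images

A synthetic eye is two quadratic Bézier lid arcs joined at the corners,
filled sclera (gray 220), and a dark iris disc (gray 40) clipped to the
opening, on a gray-150 background, with optional Gaussian pixel noise.
Ground truth (iris center, landmarks) is returned alongside the image, and
specs that place the iris outside the opening are rejected.  The generator
emulates the *geometry and contrast structure* that the segmentation
pipeline consumes; it does not emulate eyelashes, specular glints, skin
texture, makeup, glasses, off-axis head pose, or illumination gradients —
robustness to those is out of scope for the synthetic test bed.

### 2.2 Gaze streams

Gaze ratio streams are sampled at `sample_rate = 30 Hz` with three
components:

- **Deterministic intent**: piecewise-constant targets (the neutral center
  plus direction offsets of ±0.3 ratio units) with a fixed
  `reaction_latency = 0.4 s` between intent changes — a typical choice for
  reaction plus saccade time.
- **Fixational jitter**: a stationary Gaussian AR(1) process with marginal
  standard deviation `jitter_sd = 0.12` and correlation time
  `jitter_tau = 0.35 s` (`φ = exp(−Δt/τ)`).  Correlated drift, not white
  noise, is what produces sustained wrong-zone dwells and hence realistic
  false selections; white noise of the same amplitude only flickers and
  can never confirm a wrong target.  The pair (0.12, 0.35 s) was fixed
  once as the default operating point of the simulator: it yields slow
  drift excursions on the timescale of the dwell thresholds, producing a
  qualitative regime in which false selections decrease and misses
  increase with the threshold and the total error is minimized at an
  intermediate threshold — the structure the package's trend tests and
  acceptance script then measure.
- **Blinks**: a Poisson process at `blink_rate = 17 /min` with
  `blink_duration = 0.2 s` invalid gaps (non-overlapping; abutting blinks
  may merge).

Substreams are seeded by `numpy.random.SeedSequence` spawning, so jitter
and blinks are independent and every run is reproducible from one seed.

Two simulation routes exist deliberately:

- `generate_gaze_stream` is **open-loop**: a fixed schedule (react, hold
  for `dwell + max(0.15, 3/rate)`, re-center, …) that a noise-free replay
  must convert into exactly the intended selections — the oracle used by
  the tests.
- `experiment.run_trial` is **closed-loop**: a simulated user watches the
  machine's feedback, reacts `0.4 s` after each stage transition, keeps
  holding until a confirmation arrives, and proceeds unaware after a wrong
  cluster opens (which is how false detections complete).  Only the closed
  loop produces noise-dependent completion times and error trade-offs.

## 3. Simulated experiment

The factorial design crosses central-area size
(`small 0.16×0.09`, `medium 0.20×0.12`, `large 0.24×0.16` ratio units) ×
viewing distance (`45, 55, 65 cm`) × dwell threshold
(`0.5, 0.8, 1.0, 1.2 s`): 36 conditions.  The default study size is 22
participants × 4 repetitions = 3168 trials, with distance blocks
alternating near→far / far→near across participants and the 12
size×threshold cells shuffled per participant and block.  Distance scales
the jitter amplitude by `distance / 45 cm` (the same angular noise spans a
larger ratio excursion when the eye image is smaller).  Outcomes are
exhaustive and exclusive — `success`, `false_detection`, `missed` — so the
error rate decomposes exactly as `error = false + missed`.  Completion
times are averaged over successful trials only.

`pixels_per_degree` converts the display geometry (15.6-inch diagonal,
1920×1080, 45 cm) to `2·d·tan(0.5°)/pitch ≈ 43.7 ≈ 44 px/deg`.  Note the
small-angle visual span of the screen at 45 cm and a per-degree linear
approximation are not mutually consistent to better than a percent; the
package reports the exact tangent formula.

## 4. Numerical conventions

- Filter outputs are rounded to 4 decimals before thresholding, so
  pixels sitting exactly at a gray level are not flipped by float residue
  from the bilateral filter.
- The center rectangle boundary is closed; zone ties go to the horizontal
  axis.  Tests verify the partition with the classifier's own
  normalized-excess arithmetic, since `w/2` for study sizes like 0.16 is
  not exactly representable in binary floating point.
- MAD-based outlier rejection degrades gracefully: a zero MAD keeps all
  samples rather than rejecting everything.
- All random draws flow from explicit seeds through `SeedSequence`; any
  integer seeds surfaced externally are kept below 2³¹.

## 5. Limitations

- Pilot renormalization bounds and direction offsets are fixed constants;
  real deployments would re-estimate them per user or camera.
- Vertical range is short (eyelids), so vertical classification is
  intrinsically less robust than horizontal — one reason ties resolve
  horizontally.
- The simulated user model is intentionally simple (constant reaction
  latency, no learning, no fatigue, proceeds unaware after a wrong
  cluster); its outcome rates characterize the *interface dynamics under
  the stated noise model*, not human performance.
- Irises partially occluded by a lid have genuinely biased centroids; the
  recovery guarantees apply to irises inside the visible opening.
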