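# gave — gaze-based selection from webcam eye images

`gave` implements a complete, testable model of a low-cost gaze interface:
iris-center detection in eye images, pupil-position gaze ratios with a
one-point calibration, five-zone screen classification, and a dwell-based
two-stage (cluster → item) selection state machine.  Synthetic generators
for eye images and gaze streams make every stage verifiable against ground
truth, and a simulated factorial experiment quantifies the speed/accuracy
trade-off of the dwell threshold and central-area size.

## The problem

Eye trackers built from ordinary webcams cannot rely on infrared glints or
3-D eye models.  A robust alternative maps the iris center's position
*within the eye opening* to a coarse gaze direction:

- **Horizontal ratio.** With eye-corner landmarks at `x_min` and `x_max`
  and detected iris center `x`, the raw ratio is
  `r_h = (x − x_min) / (x_max − x_min)`.
- **Vertical ratio.** The vertical reference span runs between the upper
  and lower eyelid midlines: `y_min = (y₃₇ + y₃₈)/2`,
  `y_max = (y₄₀ + y₄₁)/2` (68-point landmark indexing), and
  `r_v = (y − y_min) / (y_max − y_min)`.
- Raw ratios occupy only part of `[0, 1]`; they are renormalized with
  pilot bounds (`h: 0.28–0.87`, `v: 0.48–0.95`) and averaged across the
  two eyes.

Webcam images are mirrored, so `h` near 1 means the user looks *left* and
`v` near 1 means the user looks *down*.  ("Left eye" throughout the package
means image-left, i.e. the subject's right eye.)

A 2-second fixation on the screen center calibrates the neutral point
`(h_c, v_c)`.  Gaze is then classified into five zones: a central rectangle
of width `w` and height `l` (ratio units) around `(h_c, v_c)`, and the
four directions beyond it, decided by whichever normalized excess —
`(|Δh| − w/2)·2/w` vs `(|Δv| − l/2)·2/l` — is larger.

Selection is hierarchical: dwell on a direction for `T` seconds to pick a
cluster of three items, then dwell again to pick the item (up always means
*back*).  A 10-second stage timeout marks the attempt as missed.

## Worked example

Detect the iris in a synthetic eye image (`examples/01_iris_detection.py`):

```text
true iris center   : (36.00, 25.00) px
detected center    : (36.00, 25.00) px
localization error : 0.00 px
```

Calibrate and classify (`examples/02_calibration_and_zones.py`):

```text
true neutral gaze   : h=0.560, v=0.510
calibrated center   : h=0.557, v=0.513  (45 samples kept, sd=0.0145)
  (h=0.857, v=0.513) -> left    # large +h excursion (mirrored image: looking left)
  (h=0.747, v=0.513) -> center  # just inside the half-width: still center
```

Run a full selection (`examples/03_selection_replay.py`):

```text
target item : tea (cluster 'right', item position 'down')
  t= 0.40 s  focus            right
  t= 1.23 s  cluster_selected right
  t= 1.77 s  focus            down
  t= 2.60 s  item_selected    tea
```

Simulate a small study (`examples/04_simulated_study.py`):

```text
dwell (s)     n  mean time (s)   false  missed   error
      0.5   100           2.94    0.10    0.00    0.10
      0.8   100           5.30    0.01    0.03    0.04
      1.0   100           6.09    0.01    0.08    0.09
      1.2   100           7.91    0.00    0.29    0.29
```

False selections fall and misses rise with the dwell threshold; total error
is minimized at an intermediate value.

## Library tour

| Module | Contents |
| --- | --- |
| `gave.eye_image` | landmark containers, eye-region extraction, iris segmentation (bilateral filter → erosion → threshold), moment centroid |
| `gave.gaze_ratio` | raw/renormalized ratios, two-eye combination, full image → `RatioPair` pipeline |
| `gave.calibration` | one-point calibration with outlier rejection, five-zone classifier, sample → event conversion |
| `gave.selection` | menu model, dwell/timeout selection state machine, stream replay |
| `gave.synthetic` | ground-truthed eye/face image generators, AR(1)-jittered gaze-stream simulator with blinks |
| `gave.experiment` | factorial condition grid, closed-loop trial simulation, outcome metrics, display geometry |

A thin CLI mirrors the pipeline for file-based use:
`gave detect`, `gave ratios`, `gave calibrate`, `gave classify`,
`gave replay`, `gave simulate`, `gave eval` (see `gave --help`).

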