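"""Synthetic eye images, landmark sets, and gaze-ratio streams.

Everything downstream of a webcam is testable without one: this module
renders grayscale eye images with *known* iris centers and the implied
6-point eye landmarks, composes them into face frames with full 68-point
landmark sets, and simulates timestamped gaze-ratio streams with fixation
jitter, reaction latency, and blink dropouts.

The eye opening is modeled as two quadratic arcs (upper and lower lid)
through the corner points; the iris is a dark filled disc clipped to the
opening.  This is deliberately schematic — no photorealism, head pose, or
color — but it exercises the exact geometry the estimation pipeline relies
on (corner landmarks, eyelid midlines, dark-iris/bright-sclera contrast).

Gaze jitter is a stationary Gaussian AR(1) process: ocular drift and head
micro-movement are temporally correlated, so wrong-zone excursions persist
over several frames rather than flickering sample-by-sample.  ``jitter_tau``
(the correlation time) set to 0 recovers white noise.  Blinks arrive as a
Poisson process at ``blink_rate`` per minute (human resting rate: about 17)
with non-overlapping fixed-length gaps during which samples are present but
flagged invalid.

A single scenario seed is expanded into independent per-component
substreams, so adding a noise source never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, polygon

from .eye_image import FaceLandmarks

Point = Tuple[float, float]

#: ratio-space displacement applied when "looking" at each arrow; 0.3 is
#: safely outside the default central rectangle (w/2 = 0.2, l/2 = 0.1)
DIRECTION_OFFSETS: Dict[str, Tuple[float, float]] = {
    "up": (0.0, -0.3),
    "down": (0.0, 0.3),
    "left": (0.3, 0.0),   # mirrored webcam: higher h-ratio = looking left
    "right": (-0.3, 0.0),
    "center": (0.0, 0.0),
}


@dataclass(frozen=True)
class EyeImageSpec:
    """Geometry and photometry of one synthetic eye.

    All coordinates are frame pixels (x right, y down).  ``eyelid_apex_offsets``
    are the (upper, lower) lid apex distances from the corner line, in pixels.
    """

    image_size: Tuple[int, int] = (64, 48)          # (width, height)
    eye_corners: Tuple[Point, Point] = ((12.0, 24.0), (52.0, 24.0))
    eyelid_apex_offsets: Tuple[float, float] = (9.0, 9.0)
    iris_center: Point = (32.0, 24.0)
    iris_radius: float = 7.0
    sclera_intensity: int = 220
    iris_intensity: int = 40
    background_intensity: int = 150
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iris_radius <= 0:
            raise ValueError("iris_radius must be positive")
        if not self.iris_intensity < self.sclera_intensity:
            raise ValueError("iris must be darker than sclera")


@dataclass(frozen=True)
class EyeGroundTruth:
    iris_center: Point
    landmarks: np.ndarray  # (6, 2): corner, 2 upper-lid, corner, 2 lower-lid


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze-ratio observation; ``valid`` is False during
    blinks or detection dropouts (``h``/``v`` then hold no meaning)."""

    timestamp: float
    h: float
    v: float
    valid: bool = True


@dataclass(frozen=True)
class GazeScenario:
    """Behavioral parameters of a simulated user working through targets."""

    target_sequence: Tuple[str, ...] = ()
    reaction_latency: float = 0.4     # s from stimulus to gaze shift
    jitter_sd: float = 0.12           # marginal sd of fixation jitter (ratio units)
    jitter_tau: float = 0.35          # AR(1) correlation time, s (0 = white noise)
    blink_rate: float = 17.0          # events / minute
    blink_duration: float = 0.2       # s
    sample_rate: float = 30.0         # Hz
    seed: int = 0
    true_center: Tuple[float, float] = (0.56, 0.51)
    direction_offsets: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DIRECTION_OFFSETS)
    )

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.jitter_sd < 0 or self.blink_rate < 0:
            raise ValueError("jitter_sd and blink_rate must be non-negative")


# ---------------------------------------------------------------------------
# eye-image rendering


def _bezier(p0: np.ndarray, apex_offset: float, p1: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Quadratic arc through p0 and p1 whose t=0.5 point sits ``apex_offset``
    pixels (y, signed down) off the corner midpoint."""
    ctrl = (p0 + p1) / 2.0 + np.array([0.0, 2.0 * apex_offset])
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def eye_landmarks_for_spec(spec: EyeImageSpec) -> np.ndarray:
    """The 6 eye landmarks implied by the geometry: the two corners plus two
    points on each lid arc (at t = 1/3 and 2/3), ordered corner, upper x2,
    corner, lower x2 — mirroring the standard 68-point eye ordering."""
    p0 = np.asarray(spec.eye_corners[0], dtype=float)
    p1 = np.asarray(spec.eye_corners[1], dtype=float)
    upper = _bezier(p0, -spec.eyelid_apex_offsets[0], p1, np.array([1 / 3, 2 / 3]))
    lower = _bezier(p0, spec.eyelid_apex_offsets[1], p1, np.array([2 / 3, 1 / 3]))
    return np.vstack([p0, upper, p1, lower])


def _opening_mask(spec: EyeImageSpec) -> np.ndarray:
    w, h = spec.image_size
    p0 = np.asarray(spec.eye_corners[0], dtype=float)
    p1 = np.asarray(spec.eye_corners[1], dtype=float)
    t = np.linspace(0.0, 1.0, 41)
    upper = _bezier(p0, -spec.eyelid_apex_offsets[0], p1, t)
    lower = _bezier(p0, spec.eyelid_apex_offsets[1], p1, t[::-1])
    ring = np.vstack([upper, lower])
    rr, cc = polygon(ring[:, 1], ring[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_eye_image(spec: EyeImageSpec) -> Tuple[np.ndarray, EyeGroundTruth]:
    """Render one eye: light sclera inside the lid arcs, dark iris disc.

    Deterministic for a fixed seed.  Rejects specs whose iris center falls
    outside the eye opening.
    """
    mask = _opening_mask(spec)
    cx, cy = spec.iris_center
    ix, iy = int(round(cx)), int(round(cy))
    if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]):
        raise ValueError("iris_center lies outside the eyelid opening")
    img = np.full(mask.shape, float(spec.background_intensity))
    img[mask] = spec.sclera_intensity
    rr, cc = disk((cy, cx), spec.iris_radius, shape=mask.shape)
    keep = mask[rr, cc]
    img[rr[keep], cc[keep]] = spec.iris_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, EyeGroundTruth(iris_center=(float(cx), float(cy)),
                               landmarks=eye_landmarks_for_spec(spec))


def _filler_landmarks(frame_size: Tuple[int, int]) -> np.ndarray:
    """Plausible placeholder positions for the 56 non-eye landmarks: a face
    oval plus schematic brows/nose/mouth.  Only indices 36-47 carry meaning
    for this package; the rest exist so fixtures are valid 68-point sets."""
    w, h = frame_size
    cx, cy = w / 2.0, h / 2.0
    pts = np.zeros((68, 2))
    jaw_t = np.linspace(math.pi * 0.15, math.pi * 0.85, 17)
    pts[0:17, 0] = cx - 0.45 * w * np.cos(jaw_t)
    pts[0:17, 1] = cy + 0.40 * h * np.sin(jaw_t)
    for i in range(5):  # brows
        pts[17 + i] = (cx - 0.35 * w + i * 0.07 * w, cy - 0.30 * h)
        pts[22 + i] = (cx + 0.07 * w + i * 0.07 * w, cy - 0.30 * h)
    for i in range(9):  # nose bridge + base
        pts[27 + i] = (cx + (i - 4) * 0.02 * w * (i >= 4), cy - 0.10 * h + i * 0.04 * h)
    mouth_t = np.linspace(0, 2 * math.pi, 20, endpoint=False)
    pts[48:68, 0] = cx + 0.18 * w * np.cos(mouth_t)
    pts[48:68, 1] = cy + 0.30 * h + 0.06 * h * np.sin(mouth_t)
    return pts


def default_frame_specs(
    frame_size: Tuple[int, int] = (320, 240),
    gaze: Tuple[float, float] = (0.5, 0.5),
    iris_radius: float = 7.0,
    apex_offset: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[EyeImageSpec, EyeImageSpec]:
    """Specs for the two eyes of a face frame whose irises sit at the given
    raw ratios: ``gaze=(h, v)`` places the iris at fraction ``h`` between the
    corners and ``v`` between the eyelid midlines (both eyes identically)."""
    w, h = frame_size
    eye_w = 0.18 * w
    centers_x = (0.30 * w, 0.70 * w)
    eye_y = 0.42 * h
    specs = []
    for k, ecx in enumerate(centers_x):
        corners = ((ecx - eye_w / 2, eye_y), (ecx + eye_w / 2, eye_y))
        spec = EyeImageSpec(
            image_size=frame_size,
            eye_corners=corners,
            eyelid_apex_offsets=(apex_offset, apex_offset),
            iris_center=(0.0, 0.0),  # placed below from the requested ratios
            iris_radius=iris_radius,
            noise_sd=noise_sd,
            seed=seed + k,
        )
        lm = eye_landmarks_for_spec(spec)
        x_min, x_max = lm[0, 0], lm[3, 0]
        y_min = (lm[1, 1] + lm[2, 1]) / 2.0
        y_max = (lm[4, 1] + lm[5, 1]) / 2.0
        iris = (x_min + gaze[0] * (x_max - x_min), y_min + gaze[1] * (y_max - y_min))
        specs.append(replace(spec, iris_center=iris))
    return specs[0], specs[1]


def generate_face_frame(
    left_spec: EyeImageSpec,
    right_spec: EyeImageSpec,
    background_intensity: int = 150,
) -> Tuple[np.ndarray, FaceLandmarks, Dict[str, Point]]:
    """Compose two eyes into one frame with a full 68-point landmark set.

    ``left_spec`` is the image-left eye (landmarks 36-41), ``right_spec``
    the image-right eye (42-47).  Both specs must share ``image_size``,
    which becomes the frame size.  Returns (frame, landmarks, ground truth
    iris centers keyed ``iris_left``/``iris_right``).
    """
    if left_spec.image_size != right_spec.image_size:
        raise ValueError("both eye specs must share the frame size")
    img_l, gt_l = generate_eye_image(left_spec)
    img_r, gt_r = generate_eye_image(right_spec)
    frame = np.full(img_l.shape, background_intensity, dtype=np.uint8)
    for img, spec in ((img_l, left_spec), (img_r, right_spec)):
        opening = _opening_mask(spec)  # paste only the eye opening
        frame[opening] = img[opening]
    pts = _filler_landmarks(left_spec.image_size)
    pts[36:42] = gt_l.landmarks
    pts[42:48] = gt_r.landmarks
    w, h = left_spec.image_size
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    truth = {"iris_left": gt_l.iris_center, "iris_right": gt_r.iris_center}
    return frame, FaceLandmarks(points=pts), truth


def write_frame(path_png, path_json, frame, landmarks, truth) -> None:
    """Persist a frame as 8-bit grayscale PNG + landmark/ground-truth JSON."""
    iio.imwrite(Path(path_png), frame)
    landmarks.to_json(
        path_json,
        iris_left=list(truth["iris_left"]),
        iris_right=list(truth["iris_right"]),
    )


# ---------------------------------------------------------------------------
# gaze-stream simulation


class _Jitter:
    """Stationary Gaussian AR(1) jitter with marginal sd and correlation time."""

    def __init__(self, sd: float, tau: float, dt: float, rng: np.random.Generator):
        self.sd = sd
        self.phi = math.exp(-dt / tau) if (tau > 0 and sd > 0) else 0.0
        self.rng = rng
        self.state = np.zeros(2)
        if sd > 0:
            self.state = rng.normal(0.0, sd, 2)

    def __call__(self) -> np.ndarray:
        if self.sd == 0:
            return self.state  # zeros
        innov_sd = self.sd * math.sqrt(1.0 - self.phi**2)
        self.state = self.phi * self.state + self.rng.normal(0.0, innov_sd, 2)
        return self.state


def _blink_intervals(
    rate_per_min: float, duration: float, blink_len: float, rng: np.random.Generator
) -> List[Tuple[float, float]]:
    """Non-overlapping blink windows from a Poisson process of the given rate."""
    if rate_per_min <= 0:
        return []
    out: List[Tuple[float, float]] = []
    t = 0.0
    rate = rate_per_min / 60.0
    while True:
        t += rng.exponential(1.0 / rate)
        if out and t < out[-1][1]:  # enforce non-overlap
            t = out[-1][1]
        if t >= duration:
            return out
        out.append((t, t + blink_len))


def _phase_schedule(
    scenario: GazeScenario, menu, dwell_threshold: float
) -> List[Tuple[float, str]]:
    """Open-loop intent script: (duration, direction-or-center) phases."""
    hold = dwell_threshold + max(0.15, 3.0 / scenario.sample_rate)
    phases: List[Tuple[float, str]] = []
    for target in scenario.target_sequence:
        cluster_dir, item_dir = menu.locate(target)
        phases += [
            (scenario.reaction_latency, "center"),
            (hold, cluster_dir),
            (scenario.reaction_latency, "center"),
            (hold, item_dir),
        ]
    return phases


def generate_gaze_stream(
    scenario: GazeScenario, menu, dwell_threshold: float
) -> List[GazeSample]:
    """Simulate the ratio stream of a user selecting each scenario target.

    Open loop: for each target the user fixates the center for the reaction
    latency, then holds the cluster direction just past the dwell threshold,
    re-centers, and holds the item direction likewise.  AR(1) jitter and
    blink gaps are superimposed.  Deterministic for a fixed seed; an empty
    target sequence yields an empty stream.
    """
    phases = _phase_schedule(scenario, menu, dwell_threshold)
    total = sum(d for d, _ in phases)
    if total == 0:
        return []
    ss = np.random.SeedSequence(scenario.seed)
    rng_jitter, rng_blink = (np.random.default_rng(s) for s in ss.spawn(2))
    dt = 1.0 / scenario.sample_rate
    jitter = _Jitter(scenario.jitter_sd, scenario.jitter_tau, dt, rng_jitter)
    blinks = _blink_intervals(
        scenario.blink_rate, total, scenario.blink_duration, rng_blink
    )
    n = int(round(total * scenario.sample_rate))
    samples: List[GazeSample] = []
    boundaries = np.cumsum([d for d, _ in phases])
    for i in range(n):
        t = i * dt
        k = int(np.searchsorted(boundaries, t, side="right"))
        k = min(k, len(phases) - 1)
        off = scenario.direction_offsets[phases[k][1]]
        j = jitter()
        h = min(1.0, max(0.0, scenario.true_center[0] + off[0] + j[0]))
        v = min(1.0, max(0.0, scenario.true_center[1] + off[1] + j[1]))
        valid = not any(a <= t < b for a, b in blinks)
        samples.append(GazeSample(timestamp=t, h=h, v=v, valid=valid))
    return samples


def generate_calibration_stream(
    scenario: GazeScenario, duration: float = 2.0
) -> List[GazeSample]:
    """Center-fixation stream for one-point calibration (same noise model)."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_jitter, rng_blink = (np.random.default_rng(s) for s in ss.spawn(2))
    dt = 1.0 / scenario.sample_rate
    jitter = _Jitter(scenario.jitter_sd, scenario.jitter_tau, dt, rng_jitter)
    blinks = _blink_intervals(
        scenario.blink_rate, duration, scenario.blink_duration, rng_blink
    )
    n = int(round(duration * scenario.sample_rate)) + 1
    out = []
    for i in range(n):
        t = i * dt
        j = jitter()
        h = min(1.0, max(0.0, scenario.true_center[0] + j[0]))
        v = min(1.0, max(0.0, scenario.true_center[1] + j[1]))
        valid = not any(a <= t < b for a, b in blinks)
        out.append(GazeSample(timestamp=t, h=h, v=v, valid=valid))
    return out


def stream_to_csv(samples: Sequence[GazeSample], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [s.timestamp for s in samples],
            "h_ratio": [s.h for s in samples],
            "v_ratio": [s.v for s in samples],
            "valid": [int(s.valid) for s in samples],
        }
    )
    df.to_csv(path, index=False)


def stream_from_csv(path: Union[str, Path]) -> List[GazeSample]:
    df = pd.read_csv(path)
    return [
        GazeSample(
            timestamp=float(r.timestamp),
            h=float(r.h_ratio),
            v=float(r.v_ratio),
            valid=bool(r.valid),
        )
        for r in df.itertuples()
    ]
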