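"""Eye-region extraction, iris segmentation, and pupil-center estimation.

Works from a grayscale face frame plus a standard 68-point facial-landmark
annotation.  Indices 36-41 delimit one eye opening and 42-47 the other
(following the usual annotation scheme these are the image-left and
image-right eyes; because a webcam mirrors the subject, the image-left eye
is the subject's right).  Within each eye crop the iris is the dark region
against the light sclera, so a bilateral filter + grayscale erosion +
threshold yields a binary iris mask whose intensity centroid (first image
moments over the zeroth) is the pupil-center estimate.

Landmark detection itself is not performed here: any detector that produces
the 68-point scheme can feed this module.  Tests and fixtures use landmark
sets generated with known ground truth (:mod:`gave.synthetic`), or loaded
from JSON via :meth:`FaceLandmarks.from_json`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
from skimage.morphology import erosion, footprint_rectangle
from skimage.restoration import denoise_bilateral

LEFT_EYE_IDX = np.arange(36, 42)
RIGHT_EYE_IDX = np.arange(42, 48)


class InvalidLandmarksError(ValueError):
    """Landmarks missing, outside the frame, or degenerate."""


class SegmentationError(RuntimeError):
    """Iris segmentation produced an all-foreground or all-background mask."""


class PupilNotFoundError(RuntimeError):
    """No foreground pixels to take a centroid of."""


@dataclass(frozen=True)
class FaceLandmarks:
    """A 68-point facial-landmark set in pixel coordinates (x right, y down)."""

    points: np.ndarray  # (68, 2) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise InvalidLandmarksError(f"expected 68 points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)
        for idx in (LEFT_EYE_IDX, RIGHT_EYE_IDX):
            if _polygon_area(pts[idx]) <= 0.0:
                raise InvalidLandmarksError("degenerate (zero-area) eye landmark hull")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FaceLandmarks":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(points=np.asarray(payload["points"], dtype=float))

    def to_json(self, path: Union[str, Path], **extra) -> None:
        payload = {"points": np.asarray(self.points).tolist(), **extra}
        Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class EyeRegion:
    """A per-eye crop plus the reference coordinates used for ratio geometry.

    All reference coordinates are in full-frame pixels; ``origin`` translates
    crop-local coordinates back to the frame.
    """

    crop: np.ndarray
    origin: Tuple[int, int]  # (x, y) of crop's top-left corner in the frame
    corner_x_min: float
    corner_x_max: float
    eyelid_y_min: float
    eyelid_y_max: float

    def __post_init__(self) -> None:
        if not self.corner_x_min < self.corner_x_max:
            raise InvalidLandmarksError("corner_x_min must be < corner_x_max")
        if not self.eyelid_y_min < self.eyelid_y_max:
            raise InvalidLandmarksError("eyelid_y_min must be < eyelid_y_max")


@dataclass(frozen=True)
class IrisSegParams:
    """Filter-chain parameters for iris segmentation.

    ``binary_threshold`` is an 8-bit gray level, or ``"auto"`` for the
    midpoint of the 5th and 95th intensity percentiles of the filtered crop
    (robust for the bimodal sclera/iris histogram and invariant to adding a
    constant to all gray levels).
    """

    bilateral_diameter: int = 11
    bilateral_sigma_color: float = 15.0
    bilateral_sigma_space: float = 15.0
    erosion_kernel: int = 3
    erosion_iterations: int = 3
    binary_threshold: Union[int, str] = "auto"

    def __post_init__(self) -> None:
        if min(self.bilateral_diameter, self.bilateral_sigma_color,
               self.bilateral_sigma_space, self.erosion_kernel,
               self.erosion_iterations) <= 0:
            raise ValueError("all segmentation parameters must be positive")
        if self.binary_threshold != "auto" and not 0 <= self.binary_threshold <= 255:
            raise ValueError("fixed threshold must lie in [0, 255]")


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:  # luma conversion for color input
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return img.astype(float)


def _extract_one(image: np.ndarray, pts: np.ndarray, margin: int) -> EyeRegion:
    h, w = image.shape[:2]
    corner_x_min = float(pts[0, 0])   # inner landmark of the corner pair
    corner_x_max = float(pts[3, 0])
    eyelid_y_min = float((pts[1, 1] + pts[2, 1]) / 2.0)  # upper-lid midpoint
    eyelid_y_max = float((pts[4, 1] + pts[5, 1]) / 2.0)  # lower-lid midpoint
    x0 = max(0, int(np.floor(pts[:, 0].min())) - margin)
    x1 = min(w, int(np.ceil(pts[:, 0].max())) + margin + 1)
    y0 = max(0, int(np.floor(pts[:, 1].min())) - margin)
    y1 = min(h, int(np.ceil(pts[:, 1].max())) + margin + 1)
    crop = np.asarray(image)[y0:y1, x0:x1]
    return EyeRegion(
        crop=crop,
        origin=(x0, y0),
        corner_x_min=corner_x_min,
        corner_x_max=corner_x_max,
        eyelid_y_min=eyelid_y_min,
        eyelid_y_max=eyelid_y_max,
    )


def extract_eye_regions(
    image: np.ndarray, landmarks: FaceLandmarks, margin: int = 5
) -> Tuple[EyeRegion, EyeRegion]:
    """Crop the two eye openings and record their ratio-reference coordinates.

    The horizontal references are the corner landmarks (36/39 and 42/45);
    the vertical references are the mean y of the two upper-lid points and
    of the two lower-lid points.  Crops are clamped to the frame.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    pts = landmarks.points
    if (pts < 0).any() or (pts[:, 0] > w - 1).any() or (pts[:, 1] > h - 1).any():
        raise InvalidLandmarksError("landmarks fall outside the image bounds")
    return (
        _extract_one(img, pts[LEFT_EYE_IDX], margin),
        _extract_one(img, pts[RIGHT_EYE_IDX], margin),
    )


def segment_iris(region: EyeRegion, params: IrisSegParams = IrisSegParams()) -> np.ndarray:
    """Binary iris mask of the crop: bilateral filter -> erosion -> threshold.

    Foreground (True) is the iris — the dark region — regardless of any
    display polarity; grayscale erosion grows dark structures, compensating
    for partial eyelid occlusion of the limbus.
    """
    crop = _as_gray(region.crop)
    if crop.size == 0:
        raise SegmentationError("empty crop")
    win = params.bilateral_diameter | 1  # bilateral window must be odd
    span = float(crop.max() - crop.min())
    if span > 0:
        scaled = (crop - crop.min()) / span
        filtered = denoise_bilateral(
            scaled,
            win_size=win,
            sigma_color=params.bilateral_sigma_color / 255.0,
            sigma_spatial=params.bilateral_sigma_space,
        )
        filtered = filtered * span + crop.min()
    else:
        filtered = crop
    footprint = footprint_rectangle((params.erosion_kernel, params.erosion_kernel))
    for _ in range(params.erosion_iterations):
        filtered = erosion(filtered, footprint)
    # round away float residue from the filter chain so pixels sitting
    # exactly at the threshold never flip on numerical noise
    filtered = np.round(filtered, 4)
    if params.binary_threshold == "auto":
        p5, p95 = np.percentile(filtered, [5, 95])
        thr = 0.5 * (p5 + p95)
    else:
        thr = float(params.binary_threshold)
    mask = filtered < thr
    if mask.all() or not mask.any():
        raise SegmentationError("degenerate mask (no sclera/iris contrast)")
    return mask


def pupil_center(mask: np.ndarray, origin: Tuple[float, float] = (0.0, 0.0)) -> Tuple[float, float]:
    """Centroid of the mask foreground via image moments, in frame coordinates.

    Returns real-valued ``(x, y)`` = (M10/M00, M01/M00) + origin.
    """
    m = np.asarray(mask, dtype=bool)
    m00 = m.sum()
    if m00 == 0:
        raise PupilNotFoundError("empty mask")
    ys, xs = np.nonzero(m)
    return (xs.sum() / m00 + origin[0], ys.sum() / m00 + origin[1])
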