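"""Pupil-center ratios and their renormalization.

The gaze direction is read out from where the pupil center sits inside the
eye opening, expressed per axis as a dimensionless ratio in [0, 1]:

* horizontal: ``(x - x_min) / (x_max - x_min)`` where ``x_min``/``x_max`` are
  the eye-corner x coordinates.  A ratio near 1 means the user looks to their
  leftmost, near 0 to their rightmost (the webcam mirrors the scene).
* vertical: the same construction between the upper- and lower-eyelid
  midlines; near 1 means gazing at the bottom of the screen.

Because the pupil never physically reaches the landmark positions, raw ratios
occupy only part of [0, 1].  A small pilot study established the reachable
bounds (horizontal 0.28–0.87, vertical 0.48–0.95); :func:`renormalize`
stretches the raw ratio over those bounds so the usable range maps back onto
the full unit interval.  The two eyes are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .eye_image import (
    EyeRegion,
    FaceLandmarks,
    IrisSegParams,
    PupilNotFoundError,
    SegmentationError,
    extract_eye_regions,
    pupil_center,
    segment_iris,
)


class InvalidGeometryError(ValueError):
    """Raised when a normalization span is empty or inverted."""


class RatioPair(NamedTuple):
    """Normalized (horizontal, vertical) gaze ratios, each in [0, 1]."""

    h: float
    v: float


@dataclass(frozen=True)
class NormalizationConstants:
    """Reachable raw-ratio bounds used to stretch raw ratios onto [0, 1].

    Defaults are the pilot-study means: the horizontal raw ratio averages
    0.28 at the rightmost gaze and 0.87 at the leftmost; the vertical ratio
    averages 0.48 at the top and 0.95 at the bottom (the upper lid occludes
    the pupil's upward travel, hence the asymmetry).
    """

    h_min: float = 0.28
    h_max: float = 0.87
    v_min: float = 0.48
    v_max: float = 0.95

    def __post_init__(self) -> None:
        for lo, hi, axis in ((self.h_min, self.h_max, "h"), (self.v_min, self.v_max, "v")):
            if not (0.0 <= lo < hi <= 1.0):
                raise InvalidGeometryError(
                    f"{axis}-bounds must satisfy 0 <= min < max <= 1, got ({lo}, {hi})"
                )


DEFAULT_CONSTANTS = NormalizationConstants()


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


def raw_horizontal_ratio(pupil_x: float, corner_x_min: float, corner_x_max: float) -> float:
    """Position of the pupil between the eye corners, clamped to [0, 1]."""
    if not corner_x_min < corner_x_max:
        raise InvalidGeometryError(
            f"corner span must be positive, got [{corner_x_min}, {corner_x_max}]"
        )
    return _clamp01((pupil_x - corner_x_min) / (corner_x_max - corner_x_min))


def raw_vertical_ratio(pupil_y: float, eyelid_y_min: float, eyelid_y_max: float) -> float:
    """Position of the pupil between the eyelid midlines, clamped to [0, 1]."""
    if not eyelid_y_min < eyelid_y_max:
        raise InvalidGeometryError(
            f"eyelid span must be positive, got [{eyelid_y_min}, {eyelid_y_max}]"
        )
    return _clamp01((pupil_y - eyelid_y_min) / (eyelid_y_max - eyelid_y_min))


def renormalize(raw: float, lo: float, hi: float) -> float:
    """Stretch ``raw`` over the reachable bounds ``[lo, hi]`` onto [0, 1].

    Strictly increasing on [lo, hi]; values outside the bounds clamp to the
    nearest endpoint, which keeps the downstream zone geometry well defined
    for users whose range exceeds the pilot bounds.
    """
    if not lo < hi:
        raise InvalidGeometryError(f"bounds must satisfy lo < hi, got ({lo}, {hi})")
    return _clamp01((raw - lo) / (hi - lo))


def combine_eyes(left: Optional[float], right: Optional[float]) -> Optional[float]:
    """Average the per-eye ratios; fall back to the single visible eye.

    Either eye can be missing (blink, failed segmentation).  With one eye
    missing its partner is returned unchanged so occlusion degrades
    gracefully; with both missing the result is missing too.
    """
    if left is None:
        return right
    if right is None:
        return left
    return 0.5 * (left + right)


def _eye_ratios(
    region: EyeRegion,
    params: IrisSegParams,
    constants: NormalizationConstants,
) -> Optional[tuple[float, float]]:
    try:
        mask = segment_iris(region, params)
        cx, cy = pupil_center(mask, region.origin)
    except (SegmentationError, PupilNotFoundError):
        return None
    h = renormalize(
        raw_horizontal_ratio(cx, region.corner_x_min, region.corner_x_max),
        constants.h_min,
        constants.h_max,
    )
    v = renormalize(
        raw_vertical_ratio(cy, region.eyelid_y_min, region.eyelid_y_max),
        constants.v_min,
        constants.v_max,
    )
    return h, v


def ratios_from_frame(
    image,
    landmarks: FaceLandmarks,
    params: Optional[IrisSegParams] = None,
    constants: NormalizationConstants = DEFAULT_CONSTANTS,
    margin: int = 5,
) -> Optional[RatioPair]:
    """Full per-frame pipeline: eye crops -> iris masks -> centroids -> ratios.

    Returns ``None`` when neither eye yields a pupil (e.g. during a blink).
    """
    if params is None:
        params = IrisSegParams()
    left_region, right_region = extract_eye_regions(image, landmarks, margin=margin)
    left = _eye_ratios(left_region, params, constants)
    right = _eye_ratios(right_region, params, constants)
    h = combine_eyes(left[0] if left else None, right[0] if right else None)
    v = combine_eyes(left[1] if left else None, right[1] if right else None)
    if h is None or v is None:
        return None
    return RatioPair(h=h, v=v)
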