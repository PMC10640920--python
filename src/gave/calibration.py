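"""One-point calibration and five-zone gaze classification.

A brief (default 2 s) fixation on a single central point yields the user's
personal center ratio ``(h_c, v_c)``; individual centers vary (a typical
value is (0.56, 0.51)).  Around that center a closed rectangle of width
``w`` and height ``l`` (in ratio units; default 0.4 x 0.2 from the pilot
data) is the *center* dead zone — gaze inside it triggers nothing.  Outside
the rectangle the plane is split into left/right/up/down by the dominant
normalized excess beyond the rectangle edge.

Axis conventions follow the mirrored webcam geometry: a horizontal ratio
above the center means the user looks to their left; a vertical ratio above
the center means they look down.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .gaze_ratio import RatioPair

DIRECTIONS = ("up", "down", "left", "right")
LABELS = ("center",) + DIRECTIONS


class CalibrationFailedError(RuntimeError):
    """Too few valid samples in the calibration window; caller should restart."""


@dataclass(frozen=True)
class GazeEvent:
    """A classified gaze direction at an instant."""

    label: str  # one of LABELS
    timestamp: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class CalibrationState:
    """Per-user center ratio plus the central-rectangle geometry."""

    h_c: float
    v_c: float
    w: float = 0.4
    l: float = 0.2
    n_samples: int = 1
    sample_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h_c <= 1.0 and 0.0 <= self.v_c <= 1.0):
            raise ValueError("center ratios must lie in [0, 1]")
        if not (0.0 < self.w < 1.0 and 0.0 < self.l < 1.0):
            raise ValueError("rectangle sides must lie in (0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationState":
        return cls(**json.loads(Path(path).read_text()))


def _robust_keep(values: np.ndarray, mad_factor: float) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:  # constant (or half-constant) stream: nothing to reject
        return np.ones(len(values), dtype=bool)
    return np.abs(values - med) <= mad_factor * mad


def run_one_point_calibration(
    stream: Sequence,
    duration: float = 2.0,
    w: float = 0.4,
    l: float = 0.2,
    min_valid_samples: int = 10,
    mad_factor: float = 2.5,
) -> CalibrationState:
    """Estimate the user's center ratio from a central-fixation stream.

    Uses the first ``duration`` seconds of the stream.  Missing samples
    (blinks, failed detection) are dropped, then samples farther than
    ``mad_factor`` median-absolute-deviations from the per-axis median are
    rejected as outliers before averaging.  Raises
    :class:`CalibrationFailedError` when too few valid samples remain.

    ``stream`` elements need ``timestamp``, ``h``, ``v`` and ``valid``
    attributes (see :class:`gave.synthetic.GazeSample`).
    """
    if not stream:
        raise CalibrationFailedError("empty stream")
    t0 = stream[0].timestamp
    if stream[-1].timestamp - t0 < duration - 1e-9:
        raise CalibrationFailedError(
            f"stream spans {stream[-1].timestamp - t0:.2f}s < window {duration}s"
        )
    window = [s for s in stream if s.timestamp - t0 <= duration and s.valid]
    if len(window) < min_valid_samples:
        raise CalibrationFailedError(
            f"only {len(window)} valid samples in window (need {min_valid_samples})"
        )
    hs = np.array([s.h for s in window])
    vs = np.array([s.v for s in window])
    keep = _robust_keep(hs, mad_factor) & _robust_keep(vs, mad_factor)
    hs, vs = hs[keep], vs[keep]
    if len(hs) < min_valid_samples:
        raise CalibrationFailedError("outlier rejection left too few samples")
    sd = math.sqrt(0.5 * (hs.var() + vs.var()))
    return CalibrationState(
        h_c=float(hs.mean()),
        v_c=float(vs.mean()),
        w=w,
        l=l,
        n_samples=int(len(hs)),
        sample_sd=float(sd),
    )


def classify_zone(
    ratio: RatioPair, calib: CalibrationState, timestamp: float = 0.0
) -> GazeEvent:
    """Map a ratio pair to one of the five gaze zones.

    The center zone is the *closed* rectangle ``|h-h_c| <= w/2 and
    |v-v_c| <= l/2`` (boundary points are center: conservative against
    accidental triggers).  Outside it, the per-axis excess beyond the
    rectangle edge is normalized by the corresponding half-side and the
    larger one wins; an exact tie goes to the horizontal axis.  The
    mirrored conventions give: h above center -> left, below -> right;
    v above center -> down, below -> up.
    """
    dh = ratio.h - calib.h_c
    dv = ratio.v - calib.v_c
    eh = (abs(dh) - calib.w / 2.0) * 2.0 / calib.w
    ev = (abs(dv) - calib.l / 2.0) * 2.0 / calib.l
    if eh <= 0.0 and ev <= 0.0:
        return GazeEvent("center", timestamp)
    if eh >= ev:
        return GazeEvent("left" if dh > 0 else "right", timestamp)
    return GazeEvent("down" if dv > 0 else "up", timestamp)


def events_from_samples(
    samples: Sequence,
    calib: CalibrationState,
    grace_period: float = 0.0,
) -> List[GazeEvent]:
    """Classify a gaze-sample stream into a gaze-event stream.

    Gaps of missing samples (blinks, detection dropouts) longer than
    ``grace_period`` emit a single ``center`` event at the gap start — the
    gaze is lost, so any running dwell is cleared; shorter gaps are ignored
    so that a sub-grace blink neither advances nor resets a dwell.
    """
    events: List[GazeEvent] = []
    gap_start: Optional[float] = None
    gap_end: Optional[float] = None
    for s in samples:
        if not s.valid:
            if gap_start is None:
                gap_start = s.timestamp
            gap_end = s.timestamp
            continue
        if gap_start is not None:
            if gap_end - gap_start > grace_period:
                events.append(GazeEvent("center", gap_start))
            gap_start = gap_end = None
        events.append(classify_zone(RatioPair(s.h, s.v), calib, s.timestamp))
    return events


def events_to_csv(events: Sequence[GazeEvent], path: Union[str, Path]) -> None:
    lines = ["timestamp,label"] + [f"{e.timestamp},{e.label}" for e in events]
    Path(path).write_text("\n".join(lines) + "\n")


def events_from_csv(path: Union[str, Path]) -> List[GazeEvent]:
    rows = Path(path).read_text().strip().splitlines()[1:]
    out = []
    for row in rows:
        t, label = row.split(",")
        out.append(GazeEvent(label=label, timestamp=float(t)))
    return out


def center_area_fraction(calib: CalibrationState) -> float:
    """Fraction of the unit ratio square occupied by the center rectangle
    (exact when the rectangle lies fully inside [0,1]^2)."""
    return calib.w * calib.l
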