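"""Factorial-study simulation harness and objective metrics.

Replicates the *structure* of a three-factor within-subjects usability
design — central-area size (small/medium/large), viewing distance
(45/55/65 cm), and dwell threshold (0.5/0.8/1.0/1.2 s) — with a simulated
user in place of the human participants.  Human performance numbers are not
reproduction targets (they depend on behavior no simulator is calibrated
to); the harness reproduces the design arithmetic, the outcome definitions,
and the qualitative trends:

* a trial is a *success* when the selected item equals the target,
* a *false detection* when some other item is confirmed,
* a *missed detection* when a 10-s stage timeout fires first;
* error rate = false rate + missed rate, each a fraction of all trials.

The simulated user is closed loop: it fixates the center for a reaction
latency, then holds the intended direction until the interface confirms,
re-centering between stages; gaze noise (AR(1) jitter, blinks) comes from
:mod:`gave.synthetic`.  If noise confirms a wrong cluster the simulated
user carries on unaware and confirms that cluster's item at the target's
position — a false detection, mirroring an inattentive participant.

Viewing distance acts through a noise multiplier (jitter scaled by
distance/45): the pixel extent of the eye shrinks with distance, so the
ratio estimate gets noisier.  This is an explicit modeling assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationState, GazeEvent, classify_zone
from .gaze_ratio import RatioPair
from .selection import MenuModel, SelectionMachine
from .synthetic import GazeScenario, GazeSample, _blink_intervals, _Jitter

CENTRAL_AREA_SIZES: Dict[str, Tuple[float, float]] = {
    "small": (0.16, 0.09),
    "medium": (0.2, 0.12),
    "large": (0.24, 0.16),
}
DISTANCES_CM = (45, 55, 65)
DWELL_THRESHOLDS = (0.5, 0.8, 1.0, 1.2)
REFERENCE_DISTANCE_CM = 45.0


@dataclass(frozen=True)
class Condition:
    """One cell of the size x distance x dwell factorial."""

    central_area: str       # small | medium | large
    distance_cm: float
    dwell_threshold: float

    def __post_init__(self) -> None:
        if self.central_area not in CENTRAL_AREA_SIZES:
            raise ValueError(f"unknown central-area size {self.central_area!r}")
        if self.distance_cm <= 0 or self.dwell_threshold <= 0:
            raise ValueError("distance and dwell threshold must be positive")

    @property
    def rect(self) -> Tuple[float, float]:
        return CENTRAL_AREA_SIZES[self.central_area]


@dataclass(frozen=True)
class TrialRecord:
    participant: Optional[int]
    condition: Condition
    target: str
    outcome: str                      # success | false_detection | missed
    completion_time: Optional[float]  # None iff missed
    selected: Optional[str]


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical display description for visual-angle bookkeeping."""

    diagonal_in: float = 15.6
    resolution: Tuple[int, int] = (1920, 1080)
    viewing_distance_cm: float = 45.0

    def __post_init__(self) -> None:
        if min(self.diagonal_in, self.viewing_distance_cm, *self.resolution) <= 0:
            raise ValueError("display geometry values must be positive")


def pixels_per_degree(geom: DisplayGeometry) -> float:
    """Pixels subtending one degree of visual angle at the screen center.

    Physical width follows from the diagonal and the resolution aspect;
    the result is ``2 d tan(0.5 deg) / pixel_pitch``.
    """
    rw, rh = geom.resolution
    width_in = geom.diagonal_in * rw / math.hypot(rw, rh)
    pitch_cm = width_in * 2.54 / rw
    return 2.0 * geom.viewing_distance_cm * math.tan(math.radians(0.5)) / pitch_cm


def build_condition_grid(
    participants: int, reps: int, seed: int = 0
) -> List[Tuple[int, Condition, int]]:
    """Full cross of 3 sizes x 3 distances x 4 dwell thresholds.

    Distance blocks alternate far-to-near / near-to-far across participants
    (balanced seating changes); the 12 size x dwell cells are shuffled per
    participant within each distance block; each cell is repeated ``reps``
    times.  Deterministic for a fixed seed.
    """
    if participants < 1 or reps < 1:
        raise ValueError("participants and reps must be >= 1")
    rng = np.random.default_rng(seed)
    cells = [(s, d) for s in CENTRAL_AREA_SIZES for d in DWELL_THRESHOLDS]
    rows: List[Tuple[int, Condition, int]] = []
    for p in range(participants):
        distances = DISTANCES_CM[::-1] if p % 2 == 0 else DISTANCES_CM
        for dist in distances:
            order = rng.permutation(len(cells))
            for k in order:
                size, dwell = cells[k]
                cond = Condition(size, float(dist), dwell)
                for rep in range(reps):
                    rows.append((p, cond, rep))
    return rows


def run_trial(
    scenario: GazeScenario,
    condition: Condition,
    menu: MenuModel,
    seed: int,
    participant: Optional[int] = None,
    max_duration: float = 30.0,
    grace_period: float = 0.0,
) -> Tuple[TrialRecord, List[GazeSample], List[GazeEvent]]:
    """Simulate one trial closed loop and label its outcome.

    The trial's first target in ``scenario.target_sequence`` is pursued.
    Returns the record plus the raw sample and event streams for replay.
    The clock starts when the cluster stage is displayed (t = 0).
    """
    target = scenario.target_sequence[0]
    cluster_dir, item_dir = menu.locate(target)
    w, l = condition.rect
    calib = CalibrationState(
        h_c=scenario.true_center[0], v_c=scenario.true_center[1], w=w, l=l
    )
    sd = scenario.jitter_sd * condition.distance_cm / REFERENCE_DISTANCE_CM
    ss = np.random.SeedSequence((seed, scenario.seed))
    rng_jitter, rng_blink = (np.random.default_rng(s) for s in ss.spawn(2))
    dt = 1.0 / scenario.sample_rate
    jitter = _Jitter(sd, scenario.jitter_tau, dt, rng_jitter)
    blinks = _blink_intervals(
        scenario.blink_rate, max_duration, scenario.blink_duration, rng_blink
    )
    machine = SelectionMachine(
        menu, condition.dwell_threshold, grace_period=grace_period
    )

    intent = "center"            # current gaze intent of the simulated user
    intent_until = scenario.reaction_latency
    goal = cluster_dir           # direction to hold once reacted
    samples: List[GazeSample] = []
    events: List[GazeEvent] = []
    outcome: Optional[str] = None
    completion: Optional[float] = None
    selected: Optional[str] = None
    in_gap = False

    n = int(round(max_duration / dt))
    for i in range(n):
        t = i * dt
        if intent == "center" and t >= intent_until:
            intent = goal
        off = scenario.direction_offsets[intent]
        j = jitter()
        h = min(1.0, max(0.0, scenario.true_center[0] + off[0] + j[0]))
        v = min(1.0, max(0.0, scenario.true_center[1] + off[1] + j[1]))
        valid = not any(a <= t < b for a, b in blinks)
        samples.append(GazeSample(t, h, v, valid))
        if not valid:
            if not in_gap:       # gaze lost: clear any running dwell
                in_gap = True
                event = GazeEvent("center", t)
            else:
                continue
        else:
            in_gap = False
            event = classify_zone(RatioPair(h, v), calib, t)
        events.append(event)
        res = machine.step(event)
        kind = res.action.kind
        if kind == "reset_missed":
            outcome = "missed"
            break
        if kind == "cluster_selected":
            # user (right or wrong cluster alike) now pursues the item slot
            intent, intent_until, goal = "center", t + scenario.reaction_latency, item_dir
        elif kind == "back":
            intent, intent_until, goal = "center", t + scenario.reaction_latency, cluster_dir
        elif kind == "item_selected":
            selected = res.action.payload
            outcome = "success" if selected == target else "false_detection"
            completion = t
            break
    if outcome is None:
        outcome = "missed"
    record = TrialRecord(
        participant=participant,
        condition=condition,
        target=target,
        outcome=outcome,
        completion_time=completion,
        selected=selected,
    )
    return record, samples, events


def simulate_study(
    menu: MenuModel,
    base_scenario: GazeScenario,
    participants: int = 22,
    reps: int = 4,
    seed: int = 0,
    conditions: Optional[Sequence[Condition]] = None,
) -> List[TrialRecord]:
    """Run the full factorial (or a restricted condition list) once.

    Targets are drawn uniformly from the menu per trial; every trial gets an
    independent seed derived from the study seed, so results are
    reproducible yet trials are independent.
    """
    rng = np.random.default_rng(seed)
    if conditions is None:
        rows = build_condition_grid(participants, reps, seed=seed)
    else:
        rows = [
            (p, c, r)
            for p in range(participants)
            for c in conditions
            for r in range(reps)
        ]
    items = menu.items
    records = []
    for i, (p, cond, rep) in enumerate(rows):
        target = items[rng.integers(len(items))]
        scen = replace(base_scenario, target_sequence=(target,))
        rec, _, _ = run_trial(scen, cond, menu, seed=int(rng.integers(2**31)),
                              participant=p)
        records.append(rec)
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [r.participant for r in records],
            "size": [r.condition.central_area for r in records],
            "distance_cm": [r.condition.distance_cm for r in records],
            "dwell_s": [r.condition.dwell_threshold for r in records],
            "target": [r.target for r in records],
            "outcome": [r.outcome for r in records],
            "selected": [r.selected for r in records],
            "completion_time_s": [r.completion_time for r in records],
        }
    )


def compute_metrics(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-condition descriptive table of the study's objective measures.

    Columns: trial count, mean and SD of completion time over successes
    (SD is 0 by convention when a single success exists), error rate, and
    its decomposition into false-detection and missed-detection rates —
    all three rates are fractions of *all* trials in the cell, so
    ``error_rate == false_rate + missed_rate`` exactly.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)
    rows = []
    for (size, dist, dwell), g in df.groupby(["size", "distance_cm", "dwell_s"]):
        n = len(g)
        succ = g[g.outcome == "success"]["completion_time_s"]
        false_rate = (g.outcome == "false_detection").mean()
        missed_rate = (g.outcome == "missed").mean()
        rows.append(
            {
                "size": size,
                "distance_cm": dist,
                "dwell_s": dwell,
                "n_trials": n,
                "mean_time_s": succ.mean() if len(succ) else float("nan"),
                "sd_time_s": (succ.std(ddof=1) if len(succ) > 1 else 0.0)
                if len(succ) else float("nan"),
                "error_rate": false_rate + missed_rate,
                "false_rate": false_rate,
                "missed_rate": missed_rate,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["distance_cm", "dwell_s", "size"], ignore_index=True
    )
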