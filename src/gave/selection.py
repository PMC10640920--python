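"""Dwell-based two-stage hierarchical selection.

A menu of 12 items is organized as four clusters of three, one cluster per
gaze direction (up/down/left/right).  Selection happens in two stages:

1. *Cluster stage* — dwelling on a direction arrow for longer than the dwell
   threshold selects that cluster.
2. *Item stage* — the cluster's three items are laid out left / bottom /
   right (preserving their left/middle/right order within the cluster) and
   the top position becomes a *back* control returning to the cluster stage.

Feedback mirrors the on-screen behavior: entering a direction zone focuses
it (gray circle); completing the dwell confirms it (red circle).  Looking at
the center clears the focus, which is what makes dwell selection robust to
the Midas-touch problem: inspection at the center triggers nothing.

If no confirmation happens within a 10-second stage window the machine
resets to the cluster stage and reports a missed selection.

The machine is event driven — it consumes timestamped gaze events and is
therefore agnostic to the camera's sample rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from .calibration import DIRECTIONS, GazeEvent

BACK = "back"
CLUSTER_STAGE = "cluster"
ITEM_STAGE = "item"

#: item-stage layout: position within the cluster triple -> direction to gaze
ITEM_POSITION_TO_DIRECTION = {0: "left", 1: "down", 2: "right"}


class RejectedEventError(ValueError):
    """An event arrived with a timestamp earlier than one already seen."""


@dataclass(frozen=True)
class MenuModel:
    """Four clusters of three items each, keyed by gaze direction."""

    clusters: Dict[str, Tuple[str, str, str]]

    def __post_init__(self) -> None:
        if set(self.clusters) != set(DIRECTIONS):
            raise ValueError(f"clusters must be keyed by {sorted(DIRECTIONS)}")
        object.__setattr__(
            self, "clusters", {d: tuple(v) for d, v in self.clusters.items()}
        )
        items = [it for triple in self.clusters.values() for it in triple]
        if any(len(t) != 3 for t in self.clusters.values()):
            raise ValueError("each cluster must hold exactly 3 items")
        if len(set(items)) != 12:
            raise ValueError("the 12 item identifiers must be unique")

    @property
    def items(self) -> List[str]:
        return [it for d in ("up", "down", "left", "right") for it in self.clusters[d]]

    def locate(self, item: str) -> Tuple[str, str]:
        """Return (cluster direction, item-stage direction) for an item."""
        for direction, triple in self.clusters.items():
            if item in triple:
                return direction, ITEM_POSITION_TO_DIRECTION[triple.index(item)]
        raise KeyError(item)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "MenuModel":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(clusters={d: tuple(v) for d, v in data.items()})

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({d: list(v) for d, v in self.clusters.items()}))


def default_menu() -> MenuModel:
    """A vending-machine style demo menu (12 snack/drink items)."""
    return MenuModel(
        clusters={
            "up": ("pizza", "burger", "hotdog"),
            "down": ("drumstick", "chips", "popcorn"),
            "left": ("cola", "juice", "water"),
            "right": ("coffee", "tea", "cocoa"),
        }
    )


def expand_cluster(menu: MenuModel, direction: str) -> Dict[str, str]:
    """Item-stage layout for a cluster: left/middle/right items keep their
    side, the middle item moves to the bottom, and *up* is always back."""
    left, middle, right = menu.clusters[direction]
    return {"left": left, "down": middle, "right": right, "up": BACK}


@dataclass(frozen=True)
class Feedback:
    kind: str                       # none | focus | confirm
    direction: Optional[str] = None


@dataclass(frozen=True)
class Action:
    kind: str                       # none | cluster_selected | item_selected | back | reset_missed
    payload: Optional[str] = None


@dataclass
class SelectionState:
    stage: str = CLUSTER_STAGE
    active_cluster: Optional[str] = None
    focused: Optional[str] = None
    dwell_start: Optional[float] = None
    stage_start: float = 0.0
    dwell_threshold: float = 1.0
    timeout: float = 10.0
    grace_period: float = 0.0
    last_timestamp: Optional[float] = None
    last_focus_seen: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dwell_threshold <= 0:
            raise ValueError("dwell_threshold must be positive")


@dataclass(frozen=True)
class StepResult:
    state: SelectionState
    feedback: Feedback
    action: Action


class SelectionMachine:
    """Stateful wrapper folding :func:`step` over an event stream.

    ``grace_period`` (seconds, default 0) tolerates brief excursions out of
    the focused zone — zone flicker from a noisy estimator — without
    resetting the dwell clock.  The default is the strictest reading of
    "continuously focuses": any excursion resets.
    """

    def __init__(
        self,
        menu: MenuModel,
        dwell_threshold: float,
        timeout: float = 10.0,
        grace_period: float = 0.0,
        start_time: float = 0.0,
    ) -> None:
        self.menu = menu
        self.state = SelectionState(
            stage_start=start_time,
            dwell_threshold=dwell_threshold,
            timeout=timeout,
            grace_period=grace_period,
        )

    def step(self, event: GazeEvent) -> StepResult:
        return step(self.state, self.menu, event)


def _confirm(s: SelectionState, menu: MenuModel, t: float) -> Action:
    direction = s.focused
    if s.stage == CLUSTER_STAGE:
        action = Action("cluster_selected", direction)
        s.stage = ITEM_STAGE
        s.active_cluster = direction
    else:
        layout = expand_cluster(menu, s.active_cluster)
        target = layout[direction]
        action = Action("back") if target == BACK else Action("item_selected", target)
        s.stage = CLUSTER_STAGE
        s.active_cluster = None
    # every confirmation opens a fresh interface stage: restart its clock
    s.stage_start = t
    s.focused = None
    s.dwell_start = None
    s.last_focus_seen = None
    return action


def step(state: SelectionState, menu: MenuModel, event: GazeEvent) -> StepResult:
    """Advance the machine by one gaze event.

    Semantics: *center* clears the focus; a direction event starts or
    continues a dwell; once the contiguous dwell reaches the threshold the
    focused control is confirmed (cluster selection, item selection, or
    back).  If a stage lasts longer than ``timeout`` with no confirmation
    the machine resets to the cluster stage and emits ``reset_missed``.
    """
    t = event.timestamp
    if state.last_timestamp is not None and t < state.last_timestamp:
        raise RejectedEventError(
            f"event at t={t} precedes last seen t={state.last_timestamp}"
        )
    state.last_timestamp = t

    if t - state.stage_start > state.timeout:
        state.stage = CLUSTER_STAGE
        state.active_cluster = None
        state.focused = None
        state.dwell_start = None
        state.last_focus_seen = None
        state.stage_start = t
        return StepResult(state, Feedback("none"), Action("reset_missed"))

    label = event.label
    in_grace = (
        state.focused is not None
        and state.grace_period > 0
        and state.last_focus_seen is not None
        and t - state.last_focus_seen <= state.grace_period
    )

    if label == "center":
        if in_grace:
            return StepResult(state, Feedback("focus", state.focused), Action("none"))
        state.focused = None
        state.dwell_start = None
        state.last_focus_seen = None
        return StepResult(state, Feedback("none"), Action("none"))

    if label == state.focused:
        state.last_focus_seen = t
        if t - state.dwell_start >= state.dwell_threshold:
            direction = state.focused
            action = _confirm(state, menu, t)
            return StepResult(state, Feedback("confirm", direction), action)
        return StepResult(state, Feedback("focus", label), Action("none"))

    # a different direction
    if in_grace:
        return StepResult(state, Feedback("focus", state.focused), Action("none"))
    state.focused = label
    state.dwell_start = t
    state.last_focus_seen = t
    return StepResult(state, Feedback("focus", label), Action("none"))


def run_stream(
    menu: MenuModel,
    dwell_threshold: float,
    events: Sequence[GazeEvent],
    timeout: float = 10.0,
    grace_period: float = 0.0,
    start_time: Optional[float] = None,
) -> Tuple[List[Tuple[float, str, Optional[str]]], SelectionState]:
    """Replay an event stream; log every feedback transition and action.

    Log rows are ``(timestamp, kind, payload)`` where kind is an action kind
    or ``focus``/``unfocus`` feedback transitions.  Deterministic: identical
    streams produce identical logs.
    """
    if start_time is None:
        start_time = events[0].timestamp if events else 0.0
    machine = SelectionMachine(
        menu, dwell_threshold, timeout=timeout,
        grace_period=grace_period, start_time=start_time,
    )
    log: List[Tuple[float, str, Optional[str]]] = []
    prev_focus: Optional[str] = None
    for event in events:
        res = machine.step(event)
        focus_now = machine.state.focused
        if res.action.kind != "none":
            log.append((event.timestamp, res.action.kind, res.action.payload))
        if focus_now != prev_focus:
            if focus_now is None:
                if res.action.kind == "none":
                    log.append((event.timestamp, "unfocus", prev_focus))
            else:
                log.append((event.timestamp, "focus", focus_now))
            prev_focus = focus_now
    return log, machine.state
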