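"""Dwell state machine: focus/confirm semantics, timeout, back navigation."""

import numpy as np
import pytest

from gave.calibration import GazeEvent
from gave.selection import (
    BACK,
    MenuModel,
    RejectedEventError,
    SelectionMachine,
    default_menu,
    expand_cluster,
    run_stream,
)


def ev(label, t):
    return GazeEvent(label, t)


class TestMenuModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            MenuModel(clusters={"up": ("a", "b", "c")})
        dup = {
            "up": ("a", "b", "c"), "down": ("a", "e", "f"),
            "left": ("g", "h", "i"), "right": ("j", "k", "l"),
        }
        with pytest.raises(ValueError):
            MenuModel(clusters=dup)

    def test_expand_cluster_layout(self, menu):
        layout = expand_cluster(menu, "down")
        assert layout == {
            "left": "drumstick", "down": "chips", "right": "popcorn", "up": BACK
        }

    def test_up_is_always_back(self, menu):
        assert all(expand_cluster(menu, d)["up"] == BACK for d in menu.clusters)

    def test_locate(self, menu):
        assert menu.locate("drumstick") == ("down", "left")
        assert menu.locate("chips") == ("down", "down")
        assert menu.locate("popcorn") == ("down", "right")


class TestStep:
    def test_dwell_walkthrough_selects_cluster(self, menu):
        m = SelectionMachine(menu, dwell_threshold=1.0)
        assert m.step(ev("down", 0.0)).feedback.kind == "focus"
        assert m.step(ev("down", 0.5)).feedback.kind == "focus"
        res = m.step(ev("down", 1.0))
        assert res.feedback.kind == "confirm"
        assert (res.action.kind, res.action.payload) == ("cluster_selected", "down")
        assert m.state.stage == "item" and m.state.active_cluster == "down"

    def test_leaving_zone_resets_dwell(self, menu):
        m = SelectionMachine(menu, dwell_threshold=1.0)
        m.step(ev("down", 0.0))
        m.step(ev("center", 0.6))
        m.step(ev("down", 0.8))  # dwell restarts here
        assert m.step(ev("down", 1.7)).action.kind == "none"
        assert m.step(ev("down", 1.8)).action.kind == "cluster_selected"

    def test_switching_direction_restarts_dwell(self, menu):
        m = SelectionMachine(menu, dwell_threshold=0.5)
        m.step(ev("down", 0.0))
        m.step(ev("left", 0.3))
        res = m.step(ev("left", 0.7))
        assert res.action.kind == "none"  # only 0.4 s on 'left'
        assert m.step(ev("left", 0.8)).action.kind == "cluster_selected"

    def test_timeout_emits_single_reset_missed(self, menu):
        m = SelectionMachine(menu, dwell_threshold=1.0)
        resets = 0
        t = 0.0
        while t <= 10.5:
            resets += m.step(ev("center", t)).action.kind == "reset_missed"
            t += 1 / 30
        assert resets == 1
        assert m.state.stage == "cluster"

    def test_back_returns_to_cluster_stage(self, menu):
        m = SelectionMachine(menu, dwell_threshold=0.5)
        m.step(ev("down", 0.0))
        assert m.step(ev("down", 0.5)).action.kind == "cluster_selected"
        m.step(ev("up", 1.0))
        res = m.step(ev("up", 1.5))
        assert res.action.kind == "back"
        assert m.state.stage == "cluster" and m.state.active_cluster is None

    def test_item_selection_after_cluster(self, menu):
        m = SelectionMachine(menu, dwell_threshold=0.5)
        m.step(ev("down", 0.0))
        m.step(ev("down", 0.5))          # cluster 'down' confirmed
        m.step(ev("left", 1.0))
        res = m.step(ev("left", 1.5))
        assert (res.action.kind, res.action.payload) == ("item_selected", "drumstick")
        assert m.state.stage == "cluster"  # ready for the next trial

    def test_out_of_order_event_rejected(self, menu):
        m = SelectionMachine(menu, dwell_threshold=1.0)
        m.step(ev("down", 1.0))
        with pytest.raises(RejectedEventError):
            m.step(ev("down", 0.5))

    def test_grace_period_tolerates_single_flicker(self, menu):
        m = SelectionMachine(menu, dwell_threshold=1.0, grace_period=0.05)
        m.step(ev("down", 0.0))
        m.step(ev("down", 0.50))
        m.step(ev("left", 0.53))  # one-sample flicker within grace
        res = m.step(ev("down", 1.0))
        assert res.action.kind == "cluster_selected"  # dwell was not reset


class TestRunStream:
    def test_empty_stream_noop(self, menu):
        log, state = run_stream(menu, 1.0, [])
        assert log == [] and state.stage == "cluster"

    def test_center_only_stream_times_out_once(self, menu):
        events = [ev("center", i / 30) for i in range(int(10.2 * 30))]
        log, _ = run_stream(menu, 1.0, events)
        assert [k for _, k, _ in log] == ["reset_missed"]

    def test_replay_deterministic(self, menu):
        rng = np.random.default_rng(5)
        labels = rng.choice(["center", "up", "down", "left", "right"], size=400)
        events = [ev(lab, i / 30) for i, lab in enumerate(labels)]
        a, _ = run_stream(menu, 0.5, events)
        b, _ = run_stream(menu, 0.5, events)
        assert a == b and len(a) > 0

    def test_two_stage_discipline_and_dwell_bounds(self, menu):
        """On random streams: every item selection is preceded by exactly one
        cluster selection, and every confirm fires no earlier than the dwell
        threshold and no later than one sample interval past it."""
        rng = np.random.default_rng(17)
        dt, thr = 1 / 30, 0.8
        for rep in range(10):
            # sticky random walk over zones so dwells actually complete
            labels, cur = [], "center"
            for _ in range(900):
                if rng.random() < 0.04:
                    cur = rng.choice(["center", "up", "down", "left", "right"])
                labels.append(cur)
            events = [ev(lab, i * dt) for i, lab in enumerate(labels)]
            m = SelectionMachine(menu, thr)
            for e in events:
                pre_stage = m.state.stage
                pre_dwell_start = m.state.dwell_start
                res = m.step(e)
                if res.feedback.kind == "confirm":
                    dwell = e.timestamp - pre_dwell_start
                    assert dwell >= thr - 1e-9          # never early-fires
                    assert dwell <= thr + dt + 1e-9     # never late past one dt
                if res.action.kind == "item_selected":
                    assert pre_stage == "item"
                if res.action.kind == "cluster_selected":
                    assert pre_stage == "cluster"
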