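"""Replay a synthetic gaze stream through the two-stage selection machine.

Generates a noise-free gaze stream for a user who wants "tea" (cluster
right, item position down), converts the samples to zone events with a fixed
calibration, and feeds them to the dwell-based selection machine.  The log
shows the cluster confirmation followed by the item confirmation.
"""

from gave import (
    CalibrationState,
    GazeScenario,
    default_menu,
    events_from_samples,
    generate_gaze_stream,
    run_stream,
)

menu = default_menu()
cal = CalibrationState(h_c=0.56, v_c=0.51, w=0.4, l=0.2)
dwell = 0.8  # seconds of steady gaze required to confirm

scen = GazeScenario(target_sequence=("tea",), jitter_sd=0, blink_rate=0, seed=0)
stream = generate_gaze_stream(scen, menu, dwell_threshold=dwell)
events = events_from_samples(stream, cal)
log, state = run_stream(menu, dwell, events)

cluster_dir, item_dir = menu.locate("tea")
print(f"target item : tea (cluster '{cluster_dir}', item position '{item_dir}')")
print(f"stream      : {len(stream)} samples at {scen.sample_rate} Hz, dwell {dwell} s")
print()
print("selection-machine log:")
for t, kind, payload in log:
    print(f"  t={t:5.2f} s  {kind:16s} {payload or ''}")
print()
selected = [p for _, k, p in log if k == "item_selected"]
print(f"selected: {selected}  (machine back at stage '{state.stage}')")
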