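"""Detect fixations and blinks in a synthetic 30 Hz gaze recording.

Builds a one-minute stream over the packaged traffic scenario, runs the
dispersion-threshold fixation detector (1 degree / 100 ms) and the blink-gap
detector (simultaneous two-eye data loss of 100-600 ms), and prints the
session summary an analyst would start from.
"""

import numpy as np

from atcgaze import (CohortParams, Condition, DetectionParams, blink_stats,
                     detect_blinks, detect_fixations, generate_scenario,
                     pupil_mean, simulate_gaze)

scenario = generate_scenario(Condition(12, "high"), seed=1)
stream = simulate_gaze(scenario, CohortParams(), np.random.default_rng(1),
                       participant_id="P01")

params = DetectionParams()
blinks = detect_blinks(stream, params)
fixations = detect_fixations(stream, params)
count, mean_ms = blink_stats(blinks)

print(f"session: {stream.participant_id}, condition {stream.condition_id}, "
      f"{stream.duration_ms / 1000:.0f} s at 30 Hz")
print(f"fixations: {len(fixations)} "
      f"(median duration {np.median([f.duration_ms for f in fixations]):.0f} ms)")
print(f"blinks: {count} (mean duration {mean_ms:.0f} ms)")
print(f"mean pupil diameter: {pupil_mean(stream):.2f} mm")
print()
print("The fixation count and blink rate index visual intake; mean pupil")
print("diameter and blink suppression rise and fall with mental workload.")
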