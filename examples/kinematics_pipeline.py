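"""Marker trajectories to step asymmetry: the full kinematics pipeline.

Builds a synthetic marker session walking at 10% step asymmetry (left steps
0.55 m, right 0.45 m) with 1 mm marker noise and a few occlusion gaps, then
runs gap filling, 10 Hz zero-phase low-pass filtering, gait event detection,
step lengths, and the stride-level step asymmetry index (SAI).
"""

import numpy as np

from stridelearn.kinematics import (
    MarkerTrajectory,
    detect_events,
    fill_gaps,
    lowpass,
    step_lengths,
    stride_sai,
)
from stridelearn.synthetic import generate_marker_session

targets = np.tile([0.55, 0.45], (40, 1))
session = generate_marker_session(targets, stride_duration=1.1, fs=100.0,
                                  seed=0, noise_sd=0.001)

# plant an occlusion gap in the left heel marker
heel_l = session.markers["heel_L"]
gaps = np.zeros(len(heel_l), bool)
gaps[500:508] = True
session.markers["heel_L"] = MarkerTrajectory(heel_l.position, heel_l.fs, gaps=gaps)

markers = {k: lowpass(fill_gaps(v)) for k, v in session.markers.items()}
ev_l = detect_events(markers["heel_L"], markers["met5_L"])
ev_r = detect_events(markers["heel_R"], markers["met5_R"])
print(f"detected {ev_l.heel_strikes.size} left heel strikes, "
      f"{ev_l.toe_offs.size} left toe offs")

steps = step_lengths(markers["heel_L"], markers["heel_R"], ev_l, ev_r)
series = stride_sai(steps)[2:-2]  # drop edge strides
print(f"mean step length L: {steps[steps.side == 'L']['length'].mean():.3f} m "
      f"(built: 0.550)")
print(f"mean SAI: {series.mean():.2f} %SAI (built: 10.00), "
      f"stride-to-stride SD {series.std(ddof=1):.2f}")
print(
    "SAI = (long - short) / (long + short) * 100; recovering the built-in\n"
    "asymmetry within a few hundredths validates event detection and the\n"
    "step-length computation end to end."
)
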