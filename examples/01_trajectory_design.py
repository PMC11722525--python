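"""Blip-gradient multi-echo radial trajectory design.

Builds the 30-shot, 35-echo sampling scheme used for a 2-second slice
acquisition and prints its key invariants: spokes of one frame tile the
circle uniformly, consecutive frames rotate by the small golden angle.
"""
import numpy as np

from radstar import build_trajectory, frame_angle_offset, spoke_angle, EchoTrain, echo_times

traj = build_trajectory(n_shots=30, n_echoes=35, samples_per_spoke=192, n_frames=2)
print(f"spokes per frame      : {traj.spokes_per_frame}")
print(f"first three angles    : {[round(spoke_angle(1, m, 30, 35), 5) for m in (1, 2, 3)]} rad")
print(f"frame-to-frame offset : {frame_angle_offset(1):.2f} deg (small golden angle)")

angles = np.sort(traj.angles[0].ravel())
print(f"uniform coverage      : max angle-gap deviation "
      f"{np.max(np.abs(np.diff(angles) - 2 * np.pi / 1050)):.2e} rad")

train = EchoTrain(te_first=2.37, delta_te=1.88, n_echoes=35)
te = echo_times(train)
print(f"echo times            : TE1={te[0]} ms ... TE35={te[-1]:.2f} ms (spacing {train.delta_te} ms)")
# The 1050 spokes cover k-space uniformly in a single 2-s acquisition;
# the golden-angle frame rotation makes repeated frames complementary.
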