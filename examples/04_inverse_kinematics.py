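"""Recover joint angles from markers by least-squares inverse kinematics.

A noise-free round trip (forward kinematics -> IK) recovers the driven
angle to numerical precision; with 1 mm isotropic marker noise on a
~29 cm forearm the elbow angle error stays well under a degree. The
per-frame residual RMS doubles as a data-quality report.
"""

import numpy as np

import spastigen as sg
from spastigen.pipeline import inverse_kinematics

patient = sg.load_reference_cohort()[0]
skeleton = sg.build_skeleton(patient.anthropometry)
mv = sg.get_movement("elbow_flexion_extension")
traj = sg.synthesize_trajectory(mv, rate_hz=10.0)  # 61 frames for speed
markers = sg.reduce_markers(sg.forward_kinematics(skeleton, traj),
                            sg.default_marker_map())

ik = inverse_kinematics(markers, skeleton, free_joints=("elbow_flexion",),
                        wrist_preset_deg=mv.wrist_preset_deg,
                        marker_map=sg.default_marker_map())
err = ik.trajectory.angle("elbow_flexion") - traj.angle("elbow_flexion")
print(f"noise-free round trip: max |error| = {np.abs(err).max():.2e} deg, "
      f"max residual RMS = {ik.residual_rms.max():.2e} cm")

rng = np.random.default_rng(0)
noisy = sg.MarkerTrajectorySet(
    markers.marker_names, markers.times,
    np.asarray(markers.positions) + rng.normal(0, 0.1, np.asarray(markers.positions).shape),
    units="cm",  # 0.1 cm = 1 mm noise
)
ik = inverse_kinematics(noisy, skeleton, free_joints=("elbow_flexion",),
                        wrist_preset_deg=mv.wrist_preset_deg,
                        marker_map=sg.default_marker_map())
err = ik.trajectory.angle("elbow_flexion") - traj.angle("elbow_flexion")
print(f"1 mm marker noise: elbow RMSE = "
      f"{np.sqrt(np.mean(err**2)):.3f} deg over {err.size} frames")
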