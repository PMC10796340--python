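"""Synthesize the four upper-limb movements and export one as TRC.

Each movement is a 6 s round trip sampled at 100 Hz (601 frames): start
pose, full range of motion at 3 s via a minimum-jerk profile, return by
6 s. Marker trajectories come from forward kinematics of the patient's
skeleton, reduced to the 14 markers a musculoskeletal model needs and
rotated -90 deg about the vertical axis into model coordinates.
"""

import numpy as np

import spastigen as sg

for mv in sg.movement_catalog():
    traj = sg.synthesize_trajectory(mv)
    ang = traj.angle(mv.driven_joint)
    print(f"{mv.name}: {ang.size} frames, excursion "
          f"{np.max(ang) - mv.start_angle_deg:.0f} deg "
          f"(peak at t = {traj.times[int(np.argmax(ang))]:.1f} s)")

patient = sg.load_reference_cohort()[0]
skeleton = sg.build_skeleton(patient.anthropometry)
traj = sg.synthesize_trajectory(sg.get_movement("elbow_flexion_extension"))
markers = sg.forward_kinematics(skeleton, traj)       # all 71 joints, cm
reduced = sg.reduce_markers(markers, sg.default_marker_map())
framed = sg.to_opensim_frame(reduced, rotate_y_deg=-90.0).in_units("mm")
sg.write_trc(framed, "elbow_patient1.trc", data_rate=traj.rate_hz)
print(f"wrote elbow_patient1.trc: {len(framed.marker_names)} markers, "
      f"{framed.times.size} frames, units {framed.units}")
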