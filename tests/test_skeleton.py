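"""Skeleton construction, forward kinematics, marker reduction, framing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spastigen as sg
from spastigen.kinematics import JointTrajectory, synthesize_trajectory
from spastigen.skeleton import (
    CORE_JOINTS,
    MarkerMap,
    MarkerTrajectorySet,
    lower_limb_joints,
    pelvis_vertical_offset,
    upper_limb_joints,
)


def _single_angle_traj(joint, deg, wrist=0.0):
    return JointTrajectory(
        joint_names=(joint,),
        times=np.array([0.0]),
        angles=np.array([[deg]]),
        rate_hz=100.0,
        wrist_preset_deg=wrist,
    )


class TestBuild:
    def test_71_joints_partitioned(self, skeleton1):
        assert len(skeleton1.joint_names) == 71
        assert len(CORE_JOINTS) == 11
        assert len(lower_limb_joints("L")) == len(lower_limb_joints("R")) == 6
        assert len(upper_limb_joints("L")) == len(upper_limb_joints("R")) == 24
        assert 6 * 2 + 24 * 2 + 11 == 71

    def test_right_chain_matches_anthropometry(self, skeleton1, patient1):
        p = skeleton1.rest_positions
        assert np.linalg.norm(p["R_shoulder"] - p["R_elbow"]) == pytest.approx(
            patient1.upperarm
        )
        assert np.linalg.norm(p["R_elbow"] - p["R_wrist"]) == pytest.approx(
            patient1.forearm
        )
        assert np.linalg.norm(p["R_wrist"] - p["R_hand_end"]) == pytest.approx(
            patient1.hand
        )

    def test_deterministic(self, patient1):
        a = sg.build_skeleton(patient1.anthropometry)
        b = sg.build_skeleton(patient1.anthropometry)
        for name in a.joint_names:
            assert np.array_equal(a.rest_positions[name], b.rest_positions[name])

    def test_rejects_nonpositive_segment(self, patient1):
        import dataclasses
        with pytest.raises(ValueError):
            bad = dataclasses.replace(patient1.anthropometry, forearm=-1.0)
            sg.build_skeleton(bad)


class TestForwardKinematics:
    def test_zero_angles_is_rest_pose(self, skeleton1):
        traj = _single_angle_traj("elbow_flexion", 0.0)
        mk = sg.forward_kinematics(skeleton1, traj)
        for name in skeleton1.joint_names:
            assert np.allclose(mk.marker(name)[0], skeleton1.rest_positions[name])

    def test_segment_length_conservation(self, elbow_markers, patient1):
        for a, b, length in [
            ("R_shoulder", "R_elbow", patient1.upperarm),
            ("R_elbow", "R_wrist", patient1.forearm),
            ("R_wrist", "R_hand_end", patient1.hand),
        ]:
            d = np.linalg.norm(elbow_markers.marker(a) - elbow_markers.marker(b), axis=1)
            assert np.allclose(d, length, rtol=1e-9)

    def test_elbow_90_wrist_chord(self, skeleton1, patient1):
        # rotating the forearm 90 deg about the elbow displaces the wrist
        # by the chord 2 L sin(45 deg) = L sqrt(2)
        mk = sg.forward_kinematics(skeleton1, _single_angle_traj("elbow_flexion", 90.0))
        disp = np.linalg.norm(
            mk.marker("R_wrist")[0] - skeleton1.rest_positions["R_wrist"]
        )
        assert disp == pytest.approx(patient1.forearm * np.sqrt(2), rel=1e-12)

    def test_non_driven_markers_static(self, elbow_markers, skeleton1):
        for name in ("pelvis", "head", "L_wrist", "R_shoulder", "L_foot"):
            assert np.allclose(
                elbow_markers.marker(name), skeleton1.rest_positions[name]
            )

    def test_pronation_moves_radius_not_wrist(self, skeleton1):
        mk0 = sg.forward_kinematics(skeleton1, _single_angle_traj("forearm_pronation", 0.0))
        mk1 = sg.forward_kinematics(skeleton1, _single_angle_traj("forearm_pronation", 60.0))
        assert np.allclose(mk0.marker("R_wrist"), mk1.marker("R_wrist"), atol=1e-9)
        assert np.linalg.norm(mk1.marker("R_radius") - mk0.marker("R_radius")) > 1.0

    def test_unknown_joint_rejected(self, skeleton1):
        with pytest.raises(KeyError, match="unknown joint"):
            sg.forward_kinematics(skeleton1, _single_angle_traj("knee_flexion", 10.0))


class TestReduceMarkers:
    def test_default_map_yields_14(self, elbow_markers, marker_map):
        red = sg.reduce_markers(elbow_markers, marker_map)
        assert len(red.marker_names) == 14
        assert "WristRight" in red.marker_names

    def test_positions_untouched(self, elbow_markers, marker_map):
        red = sg.reduce_markers(elbow_markers, marker_map)
        assert np.array_equal(red.marker("WristRight"), elbow_markers.marker("R_wrist"))

    def test_identity_map(self, elbow_markers):
        m = MarkerMap((("pelvis", "pelvis"), ("head", "head"), ("R_wrist", "R_wrist")))
        red = sg.reduce_markers(elbow_markers, m)
        assert red.marker_names == ("pelvis", "head", "R_wrist")

    def test_missing_source_named(self, elbow_markers):
        m = MarkerMap((("no_such_marker", "X"),))
        with pytest.raises(KeyError, match="no_such_marker"):
            sg.reduce_markers(elbow_markers, m)

    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            MarkerMap((("a", "X"), ("b", "X")))


class TestOpenSimFrame:
    def test_identity(self, elbow_markers):
        out = sg.to_opensim_frame(elbow_markers, rotate_y_deg=0.0, vertical_offset=0.0)
        assert np.allclose(out.positions, elbow_markers.positions)

    def test_minus_90_maps_x_to_z(self):
        mk = MarkerTrajectorySet(("p",), np.array([0.0]), np.array([[[1.0, 0, 0]]]), "cm")
        out = sg.to_opensim_frame(mk, rotate_y_deg=-90.0, vertical_offset=0.0)
        assert np.allclose(out.positions[0, 0], [0.0, 0.0, 1.0], atol=1e-15)

    def test_vertical_axis_invariant_then_offset(self):
        mk = MarkerTrajectorySet(("p",), np.array([0.0]), np.array([[[0.0, 5.0, 0]]]), "cm")
        out = sg.to_opensim_frame(mk, rotate_y_deg=-90.0, vertical_offset=-5.0)
        assert np.allclose(out.positions[0, 0], [0.0, 0.0, 0.0], atol=1e-15)

    def test_isometry_pairwise_distances(self, elbow_markers):
        out = sg.to_opensim_frame(elbow_markers, vertical_offset=-3.0)
        p0 = np.asarray(elbow_markers.positions)[100]
        p1 = np.asarray(out.positions)[100]
        d0 = np.linalg.norm(p0[:, None] - p0[None, :], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=-1)
        assert np.allclose(d0, d1, rtol=1e-9)

    @given(st.floats(-180.0, 180.0), st.floats(-50.0, 50.0))
    def test_isometry_property(self, angle, offset):
        pts = np.array([[[1.0, 2.0, 3.0], [-4.0, 0.5, 2.0], [0.0, -1.0, 7.0]]])
        mk = MarkerTrajectorySet(("a", "b", "c"), np.array([0.0]), pts, "cm")
        out = sg.to_opensim_frame(mk, angle, offset)
        d0 = np.linalg.norm(pts[0, 0] - pts[0, 1])
        d1 = np.linalg.norm(out.positions[0, 0] - out.positions[0, 1])
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_reduce_then_transform_commutes(self, elbow_markers, marker_map):
        a = sg.to_opensim_frame(sg.reduce_markers(elbow_markers, marker_map), -90.0, 2.0)
        b = sg.reduce_markers(sg.to_opensim_frame(elbow_markers, -90.0, 2.0), marker_map)
        assert a.marker_names == b.marker_names
        assert np.allclose(a.positions, b.positions, atol=1e-12)

    def test_pelvis_offset_grounds_pelvis(self, elbow_markers, marker_map):
        red = sg.reduce_markers(elbow_markers, marker_map)
        out = sg.to_opensim_frame(red, -90.0, pelvis_vertical_offset(red))
        assert out.marker("Pelvis")[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_unit_conversion_round_trip(elbow_markers):
    mm = elbow_markers.in_units("mm")
    assert np.allclose(
        np.asarray(mm.positions), np.asarray(elbow_markers.positions) * 10.0
    )
    back = mm.in_units("cm")
    assert np.allclose(back.positions, elbow_markers.positions)
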