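"""71-joint skeleton, right upper-limb forward kinematics, marker handling.

The skeleton mirrors a character-generator rig: 71 named joints split as 6
per lower limb, 24 per upper limb and 11 for body core, head and neck.
Only the right upper-limb chain (shoulder -> elbow -> wrist -> hand tip) is
articulated — the four catalogue movements drive exclusively that chain —
and its segment lengths are taken verbatim from patient anthropometry.
Everything else is static scenery scaled to stature.

Conventions: right-handed frame, Y up, subject facing -Z, +X the subject's
right; internal marker positions in cm (TRC export converts to mm).
Shoulder flexion rotates the arm about +X toward -Z (forward), abduction
about +Z toward +X (away from the body), elbow flexion about +X, and
pronation axially about the forearm direction. The wrist preset is held as
a constant extra axial rotation of the hand markers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cohort import Anthropometry
from .kinematics import JointTrajectory

__all__ = [
    "SkeletonModel",
    "MarkerTrajectorySet",
    "MarkerMap",
    "build_skeleton",
    "forward_kinematics",
    "reduce_markers",
    "to_opensim_frame",
    "pelvis_vertical_offset",
    "default_marker_map",
    "DRIVEN_JOINTS",
    "CORE_JOINTS",
    "lower_limb_joints",
    "upper_limb_joints",
]

#: Angle names the forward-kinematics chain understands.
DRIVEN_JOINTS = (
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "forearm_pronation",
)

#: 11 core / head / neck joints.
CORE_JOINTS = (
    "root", "pelvis", "spine_01", "spine_02", "spine_03",
    "sternum", "neck_base", "neck", "head", "head_end", "jaw",
)

_FINGERS = ("thumb", "index", "middle", "ring", "pinky")


def lower_limb_joints(side: str) -> tuple[str, ...]:
    """6 joints of one lower limb (side 'L' or 'R')."""
    return tuple(f"{side}_{j}" for j in ("thigh", "shin", "foot", "heel", "ball", "toe_end"))


def upper_limb_joints(side: str) -> tuple[str, ...]:
    """24 joints of one upper limb: chain + surface + 15 finger joints."""
    base = ("clavicle", "shoulder", "upperarm_mid", "elbow", "radius",
            "ulna", "wrist", "palm", "hand_end")
    fingers = tuple(f"{f}_{i:02d}" for f in _FINGERS for i in (1, 2, 3))
    return tuple(f"{side}_{j}" for j in base + fingers)


def all_joint_names() -> tuple[str, ...]:
    names = CORE_JOINTS + lower_limb_joints("L") + lower_limb_joints("R") \
        + upper_limb_joints("L") + upper_limb_joints("R")
    assert len(names) == 71 and len(set(names)) == 71
    return names


# Core and lower-limb rest positions as fractions of stature (x, y, z).
_CORE_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "root": (0.0, 0.53, 0.02),
    "pelvis": (0.0, 0.53, 0.0),
    "spine_01": (0.0, 0.58, 0.0),
    "spine_02": (0.0, 0.64, 0.0),
    "spine_03": (0.0, 0.70, 0.0),
    "sternum": (0.0, 0.74, -0.03),
    "neck_base": (0.0, 0.80, -0.01),
    "neck": (0.0, 0.83, 0.0),
    "head": (0.0, 0.87, 0.0),
    "head_end": (0.0, 0.93, 0.0),
    "jaw": (0.0, 0.85, -0.03),
}

_LOWER_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "thigh": (0.055, 0.50, 0.0),
    "shin": (0.055, 0.27, 0.0),
    "foot": (0.055, 0.04, 0.0),
    "heel": (0.055, 0.02, 0.03),
    "ball": (0.055, 0.01, -0.06),
    "toe_end": (0.055, 0.01, -0.10),
}

_SHOULDER_FRAC = (0.115, 0.82, 0.0)
_CLAVICLE_FRAC = (0.040, 0.80, -0.01)

# Finger lateral offsets in cm (thumb most lateral on the right hand) and
# forward offset for the thumb.
_FINGER_DX = {"thumb": 2.5, "index": 1.5, "middle": 0.5, "ring": -0.5, "pinky": -1.5}
_FINGER_DZ = {"thumb": -1.5, "index": 0.0, "middle": 0.0, "ring": 0.0, "pinky": 0.0}


@dataclass(frozen=True)
class SkeletonModel:
    """Rest-pose skeleton: 71 named joints and right-arm segment lengths (cm)."""

    anthropometry: Anthropometry
    joint_names: tuple[str, ...]
    rest_positions: Mapping[str, np.ndarray]  # name -> (3,) cm, Y up

    @property
    def upperarm(self) -> float:
        return self.anthropometry.upperarm

    @property
    def forearm(self) -> float:
        return self.anthropometry.forearm

    @property
    def hand(self) -> float:
        return self.anthropometry.hand


@dataclass(frozen=True)
class MarkerTrajectorySet:
    """Named 3D marker positions per frame."""

    marker_names: tuple[str, ...]
    times: np.ndarray          # (n,) s
    positions: np.ndarray      # (n, n_markers, 3)
    units: str = "cm"          # one of mm / cm / m

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        n = np.asarray(self.times).size
        if pos.shape != (n, len(self.marker_names), 3):
            raise ValueError(
                f"positions shape {pos.shape} != ({n}, {len(self.marker_names)}, 3)"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite marker coordinate")
        if self.units not in ("mm", "cm", "m"):
            raise ValueError(f"units must be mm/cm/m, got {self.units!r}")

    def marker(self, name: str) -> np.ndarray:
        try:
            i = self.marker_names.index(name)
        except ValueError as exc:
            raise KeyError(f"marker {name!r} not present") from exc
        return np.asarray(self.positions)[:, i, :]

    def in_units(self, units: str) -> "MarkerTrajectorySet":
        factor = {"mm": 0.001, "cm": 0.01, "m": 1.0}
        scale = factor[self.units] / factor[units]
        if scale == 1.0:
            return self
        return replace(self, positions=np.asarray(self.positions) * scale, units=units)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered (source -> target) marker renaming; unmapped sources drop."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        targets = [t for _, t in self.pairs]
        if len(set(targets)) != len(targets):
            raise ValueError("target marker names must be unique")

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.pairs)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.pairs)

    def inverted(self) -> "MarkerMap":
        return MarkerMap(tuple((t, s) for s, t in self.pairs))

    @classmethod
    def from_file(cls, path) -> "MarkerMap":
        """Two-line text file: sources on line 1, targets on line 2."""
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if len(lines) < 2:
            raise ValueError(f"marker map {path} needs two non-empty lines")
        sources = lines[0].split()
        targets = lines[1].split()
        if len(sources) != len(targets):
            raise ValueError(
                f"marker map {path}: {len(sources)} sources vs {len(targets)} targets"
            )
        return cls(tuple(zip(sources, targets)))

    def to_file(self, path) -> None:
        Path(path).write_text(
            "\t".join(self.sources) + "\n" + "\t".join(self.targets) + "\n"
        )


def default_marker_map() -> MarkerMap:
    """The packaged 71 -> 14 marker reduction map."""
    path = resources.files("spastigen").joinpath("data", "marker_map.txt")
    return MarkerMap.from_file(str(path))


def build_skeleton(anthropometry: Anthropometry) -> SkeletonModel:
    """Rest-pose skeleton from patient anthropometry.

    The right upper-limb chain uses the patient's segment lengths exactly;
    the left arm mirrors them; all other joints sit at template positions
    scaled to stature.
    """
    h = anthropometry.height
    if min(anthropometry.upperarm, anthropometry.forearm, anthropometry.hand) <= 0:
        raise ValueError("segment lengths must be positive")
    pos: dict[str, np.ndarray] = {}
    for name, frac in _CORE_FRACTIONS.items():
        pos[name] = h * np.asarray(frac)
    for side, sign in (("L", -1.0), ("R", 1.0)):
        for short, frac in _LOWER_FRACTIONS.items():
            f = np.asarray(frac) * [sign, 1.0, 1.0]
            pos[f"{side}_{short}"] = h * f
    lu, lf, lh = anthropometry.upperarm, anthropometry.forearm, anthropometry.hand
    for side, sign in (("L", -1.0), ("R", 1.0)):
        sh = h * np.asarray(_SHOULDER_FRAC) * [sign, 1.0, 1.0]
        pos[f"{side}_clavicle"] = h * np.asarray(_CLAVICLE_FRAC) * [sign, 1.0, 1.0]
        pos[f"{side}_shoulder"] = sh
        pos[f"{side}_upperarm_mid"] = sh + [sign * 2.5, -lu / 2, 0.0]
        elbow = sh + [0.0, -lu, 0.0]
        pos[f"{side}_elbow"] = elbow
        pos[f"{side}_radius"] = elbow + [sign * 2.0, -lf / 2, 0.0]
        pos[f"{side}_ulna"] = elbow + [-sign * 2.0, -lf / 2, 0.0]
        wrist = elbow + [0.0, -lf, 0.0]
        pos[f"{side}_wrist"] = wrist
        pos[f"{side}_palm"] = wrist + [sign * 1.5, -0.4 * lh, 0.0]
        pos[f"{side}_hand_end"] = wrist + [0.0, -lh, 0.0]
        for fing in _FINGERS:
            for i in (1, 2, 3):
                pos[f"{side}_{fing}_{i:02d}"] = wrist + [
                    sign * _FINGER_DX[fing],
                    -lh * (0.45 + 0.15 * i),
                    _FINGER_DZ[fing],
                ]
    names = all_joint_names()
    return SkeletonModel(
        anthropometry=anthropometry,
        joint_names=names,
        rest_positions={k: np.asarray(pos[k], dtype=float) for k in names},
    )


def _group(names: Sequence[str], skeleton: SkeletonModel) -> np.ndarray:
    return np.stack([skeleton.rest_positions[n] for n in names])


def forward_kinematics(
    skeleton: SkeletonModel, trajectory: JointTrajectory
) -> MarkerTrajectorySet:
    """Marker positions (all 71 joints, cm) for a joint-angle trajectory.

    Rigid-body rotations of the right upper-limb chain; segment lengths are
    preserved exactly at every frame. Joints not driven by the trajectory
    stay at rest.
    """
    unknown = [j for j in trajectory.joint_names if j not in DRIVEN_JOINTS]
    if unknown:
        raise KeyError(
            f"trajectory drives unknown joint(s) {unknown}; FK understands {DRIVEN_JOINTS}"
        )
    n = np.asarray(trajectory.times).size

    def angle_or_zero(j: str) -> np.ndarray:
        return (
            np.deg2rad(trajectory.angle(j))
            if j in trajectory.joint_names
            else np.zeros(n)
        )

    sf = angle_or_zero("shoulder_flexion")
    sa = angle_or_zero("shoulder_abduction")
    ef = angle_or_zero("elbow_flexion")
    pr = angle_or_zero("forearm_pronation")
    wrist_preset = np.deg2rad(trajectory.wrist_preset_deg)

    # Frame-stacked rotations. Shoulder: abduction about Z then flexion about X.
    r_sh = Rotation.from_euler("zx", np.column_stack([sa, sf]))
    r_el = r_sh * Rotation.from_euler("x", ef[:, None])
    m_sh = r_sh.as_matrix()
    m_el = r_el.as_matrix()

    p_sh0 = skeleton.rest_positions["R_shoulder"]
    p_el0 = skeleton.rest_positions["R_elbow"]
    p_wr0 = skeleton.rest_positions["R_wrist"]

    # Moving joint centres.
    p_el = p_sh0 + np.einsum("nij,j->ni", m_sh, p_el0 - p_sh0)
    p_wr = p_el + np.einsum("nij,j->ni", m_el, p_wr0 - p_el0)

    # Axial (pronation) rotation about the instantaneous forearm direction.
    fore_dir = p_wr - p_el
    fore_dir = fore_dir / np.linalg.norm(fore_dir, axis=1, keepdims=True)
    m_fore = Rotation.from_rotvec(fore_dir * pr[:, None]).as_matrix() @ m_el
    m_hand = Rotation.from_rotvec(fore_dir * (pr + wrist_preset)[:, None]).as_matrix() @ m_el

    upperarm_names = ("R_upperarm_mid", "R_elbow")
    forearm_names = ("R_radius", "R_ulna", "R_wrist")
    hand_names = tuple(
        n_ for n_ in upper_limb_joints("R")
        if n_.split("R_", 1)[1] in
        tuple(f"{f}_{i:02d}" for f in _FINGERS for i in (1, 2, 3)) + ("palm", "hand_end")
    )
    static_names = tuple(
        n_ for n_ in skeleton.joint_names
        if n_ not in upperarm_names + forearm_names + hand_names
    )

    out: dict[str, np.ndarray] = {}
    for name in static_names:
        out[name] = np.broadcast_to(skeleton.rest_positions[name], (n, 3))
    off_ua = _group(upperarm_names, skeleton) - p_sh0
    pos_ua = p_sh0 + np.einsum("nij,mj->nmi", m_sh, off_ua)
    for k, name in enumerate(upperarm_names):
        out[name] = pos_ua[:, k, :]
    off_fa = _group(forearm_names, skeleton) - p_el0
    pos_fa = p_el[:, None, :] + np.einsum("nij,mj->nmi", m_fore, off_fa)
    for k, name in enumerate(forearm_names):
        out[name] = pos_fa[:, k, :]
    off_h = _group(hand_names, skeleton) - p_wr0
    pos_h = p_wr[:, None, :] + np.einsum("nij,mj->nmi", m_hand, off_h)
    for k, name in enumerate(hand_names):
        out[name] = pos_h[:, k, :]

    positions = np.stack([out[name] for name in skeleton.joint_names], axis=1)
    return MarkerTrajectorySet(
        marker_names=skeleton.joint_names,
        times=np.asarray(trajectory.times, dtype=float),
        positions=positions,
        units="cm",
    )


def reduce_markers(markers: MarkerTrajectorySet, marker_map: MarkerMap) -> MarkerTrajectorySet:
    """Select and rename markers per the map; positions are untouched."""
    missing = [s for s in marker_map.sources if s not in markers.marker_names]
    if missing:
        raise KeyError(f"marker map source(s) absent from input: {missing}")
    idx = [markers.marker_names.index(s) for s in marker_map.sources]
    return MarkerTrajectorySet(
        marker_names=marker_map.targets,
        times=markers.times,
        positions=np.asarray(markers.positions)[:, idx, :],
        units=markers.units,
    )


def to_opensim_frame(
    markers: MarkerTrajectorySet,
    rotate_y_deg: float = -90.0,
    vertical_offset: float = 0.0,
) -> MarkerTrajectorySet:
    """Rotate every position about the vertical (Y) axis and shift vertically.

    p -> R_y(rotate_y_deg) @ p + (0, vertical_offset, 0), the rigid
    transform aligning the animation-side global axes with the
    musculoskeletal model's. ``vertical_offset`` is in the set's own units.
    """
    th = np.deg2rad(rotate_y_deg)
    c, s = np.cos(th), np.sin(th)
    r_y = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    pos = np.einsum("ij,nmj->nmi", r_y, np.asarray(markers.positions))
    pos = pos + np.array([0.0, vertical_offset, 0.0])
    return replace(markers, positions=pos)


def pelvis_vertical_offset(markers: MarkerTrajectorySet, pelvis_name: str = "Pelvis") -> float:
    """Offset that puts the pelvis marker at height 0 in the first frame."""
    names = markers.marker_names
    if pelvis_name not in names and "pelvis" in names:
        pelvis_name = "pelvis"
    return -float(markers.marker(pelvis_name)[0, 1])
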