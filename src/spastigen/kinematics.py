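"""Parameterised upper-limb movement synthesis.

Four right upper-limb movements are provided, each a 6 s round trip: a
static start pose, full range of motion at 3 s, and return to the start
pose at 6 s. Keyframes are joined by a minimum-jerk quintic — the standard
analytic model for point-to-point human reaching, with vanishing velocity
and acceleration at every keyframe. Angles are kept in degrees throughout
trajectories; radians appear only inside dynamics and the model file.

Movement conventions
--------------------
* elbow flexion-extension: arm extended adjacent to the thorax, wrist
  rotated +90 deg (palm facing the shoulder), 140 deg elbow excursion.
* shoulder flexion-extension: arm extended adjacent to the thorax, wrist
  rotated -90 deg (back of the hand to the shoulder), 90 deg excursion.
* shoulder abduction-adduction: arm extended adjacent to the thorax,
  90 deg excursion.
* forearm pronation-supination: shoulder abducted 90 deg, wrist -90 deg,
  150 deg forearm sweep. The sweep is centred on neutral (-75 deg -> +75
  deg, full supination to full pronation) so it respects physiological
  forearm limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "MovementDefinition",
    "JointTrajectory",
    "MOVEMENT_NAMES",
    "movement_catalog",
    "get_movement",
    "synthesize_trajectory",
    "min_jerk_profile",
    "INTERPOLATION_KERNELS",
]

#: Canonical movement names, in catalogue order.
MOVEMENT_NAMES = (
    "elbow_flexion_extension",
    "shoulder_flexion_extension",
    "shoulder_abduction_adduction",
    "forearm_pronation_supination",
)

DEFAULT_RATE_HZ = 100.0
DEFAULT_DURATION_S = 6.0
DEFAULT_PEAK_TIME_S = 3.0


@dataclass(frozen=True)
class MovementDefinition:
    """One parameterised movement: which joint is driven, how far, when."""

    name: str
    driven_joint: str
    rom_deg: float
    rom_tolerance_deg: float
    start_pose: Mapping[str, float] = field(default_factory=dict)
    wrist_preset_deg: float = 0.0
    duration_s: float = DEFAULT_DURATION_S
    peak_time_s: float = DEFAULT_PEAK_TIME_S

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_time_s < self.duration_s):
            raise ValueError(
                f"peak_time_s must be in (0, duration_s): {self.peak_time_s}"
            )
        if self.rom_deg < 0:
            raise ValueError(f"rom_deg must be >= 0, got {self.rom_deg}")

    @property
    def start_angle_deg(self) -> float:
        """Start angle of the driven joint (from the start pose; 0 if absent)."""
        return float(self.start_pose.get(self.driven_joint, 0.0))

    def with_rom(self, rom_deg: float) -> "MovementDefinition":
        """Copy with an overridden excursion; must lie within the tolerance band."""
        lo = self.rom_deg - self.rom_tolerance_deg
        hi = self.rom_deg + self.rom_tolerance_deg
        if not (lo <= rom_deg <= hi):
            raise ValueError(
                f"rom override {rom_deg} outside [{lo}, {hi}] for {self.name}"
            )
        return MovementDefinition(
            name=self.name,
            driven_joint=self.driven_joint,
            rom_deg=rom_deg,
            rom_tolerance_deg=self.rom_tolerance_deg,
            start_pose=dict(self.start_pose),
            wrist_preset_deg=self.wrist_preset_deg,
            duration_s=self.duration_s,
            peak_time_s=self.peak_time_s,
        )


@dataclass(frozen=True)
class JointTrajectory:
    """Uniformly sampled joint-angle time series, angles in degrees."""

    joint_names: tuple[str, ...]
    times: np.ndarray          # (n,) seconds, uniform
    angles: np.ndarray         # (n, n_joints) degrees
    rate_hz: float
    wrist_preset_deg: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if a.shape != (t.size, len(self.joint_names)):
            raise ValueError(
                f"angles shape {a.shape} inconsistent with "
                f"{t.size} frames x {len(self.joint_names)} joints"
            )
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate_hz, rtol=0, atol=1e-9):
                raise ValueError("times must be uniform at 1/rate_hz")
        if not np.all(np.isfinite(a)):
            raise ValueError("angle values must be finite")

    def angle(self, joint: str) -> np.ndarray:
        try:
            j = self.joint_names.index(joint)
        except ValueError as exc:
            raise KeyError(f"joint {joint!r} not in trajectory") from exc
        return np.asarray(self.angles)[:, j]


def min_jerk_profile(t, t0: float, t1: float, x0: float, x1: float):
    """Minimum-jerk quintic between keyframes (t0, x0) and (t1, x1).

    x(t) = x0 + (x1-x0) * (10 s^3 - 15 s^4 + 6 s^5), s = (t-t0)/(t1-t0).
    First and second derivatives vanish at both endpoints. Scalar or array
    ``t``; every value must lie in [t0, t1].
    """
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got {t0} >= {t1}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < t0) or np.any(t_arr > t1):
        raise ValueError(f"t outside [{t0}, {t1}]")
    s = (t_arr - t0) / (t1 - t0)
    out = x0 + (x1 - x0) * (10 * s**3 - 15 * s**4 + 6 * s**5)
    return out if isinstance(t, np.ndarray) else float(out)


def _cosine_profile(t, t0, t1, x0, x1):
    s = (np.asarray(t, dtype=float) - t0) / (t1 - t0)
    return x0 + (x1 - x0) * 0.5 * (1 - np.cos(np.pi * s))


def _linear_profile(t, t0, t1, x0, x1):
    s = (np.asarray(t, dtype=float) - t0) / (t1 - t0)
    return x0 + (x1 - x0) * s


#: Pluggable interpolation kernels (config key ``kinematics.kernel``).
INTERPOLATION_KERNELS: dict[str, Callable] = {
    "min_jerk": min_jerk_profile,
    "cosine": _cosine_profile,
    "linear": _linear_profile,
}


def movement_catalog(
    duration_s: float = DEFAULT_DURATION_S,
    peak_time_s: float = DEFAULT_PEAK_TIME_S,
) -> list[MovementDefinition]:
    """The four catalogue movements with their central ranges of motion."""
    return [
        MovementDefinition(
            name="elbow_flexion_extension",
            driven_joint="elbow_flexion",
            rom_deg=140.0,
            rom_tolerance_deg=20.0,
            start_pose={},
            wrist_preset_deg=90.0,
            duration_s=duration_s,
            peak_time_s=peak_time_s,
        ),
        MovementDefinition(
            name="shoulder_flexion_extension",
            driven_joint="shoulder_flexion",
            rom_deg=90.0,
            rom_tolerance_deg=10.0,
            start_pose={},
            wrist_preset_deg=-90.0,
            duration_s=duration_s,
            peak_time_s=peak_time_s,
        ),
        MovementDefinition(
            name="shoulder_abduction_adduction",
            driven_joint="shoulder_abduction",
            rom_deg=90.0,
            rom_tolerance_deg=10.0,
            start_pose={},
            wrist_preset_deg=0.0,
            duration_s=duration_s,
            peak_time_s=peak_time_s,
        ),
        MovementDefinition(
            name="forearm_pronation_supination",
            driven_joint="forearm_pronation",
            rom_deg=150.0,
            rom_tolerance_deg=10.0,
            start_pose={"shoulder_abduction": 90.0, "forearm_pronation": -75.0},
            wrist_preset_deg=-90.0,
            duration_s=duration_s,
            peak_time_s=peak_time_s,
        ),
    ]


def get_movement(name: str, **kwargs) -> MovementDefinition:
    """Look up a catalogue movement by name."""
    for m in movement_catalog(**kwargs):
        if m.name == name:
            return m
    raise KeyError(f"unknown movement {name!r}; valid: {MOVEMENT_NAMES}")


def synthesize_trajectory(
    movement: MovementDefinition,
    rate_hz: float = DEFAULT_RATE_HZ,
    kernel: str | Callable = "min_jerk",
) -> JointTrajectory:
    """Sample a movement's joint-angle time series at ``rate_hz``.

    The driven joint follows the interpolation kernel out to
    start + rom at ``peak_time_s`` and mirrors back to the start by
    ``duration_s``; all other start-pose joints are held constant. The
    peak time must fall exactly on the sampling grid so the recorded peak
    equals the range of motion with no discretisation loss.
    """
    if rate_hz <= 0:
        raise ValueError(f"rate_hz must be positive, got {rate_hz}")
    if isinstance(kernel, str):
        try:
            kernel_fn = INTERPOLATION_KERNELS[kernel]
        except KeyError as exc:
            raise KeyError(
                f"unknown kernel {kernel!r}; valid: {sorted(INTERPOLATION_KERNELS)}"
            ) from exc
    else:
        kernel_fn = kernel

    dt = 1.0 / rate_hz
    n_frames_f = movement.duration_s * rate_hz
    n_frames = int(round(n_frames_f))
    if abs(n_frames_f - n_frames) > 1e-9:
        raise ValueError(
            f"duration {movement.duration_s}s not a whole number of frames at {rate_hz} Hz"
        )
    peak_idx_f = movement.peak_time_s * rate_hz
    if abs(peak_idx_f - round(peak_idx_f)) > 1e-9:
        raise ValueError(
            f"peak_time {movement.peak_time_s}s does not fall on the {rate_hz} Hz "
            "sampling grid; the recorded peak would undershoot the range of motion"
        )
    peak_idx = int(round(peak_idx_f))
    times = np.arange(n_frames + 1) * dt

    start = movement.start_angle_deg
    peak = start + movement.rom_deg
    driven = np.empty(n_frames + 1)
    if movement.rom_deg == 0:
        driven[:] = start
    else:
        out_t = times[: peak_idx + 1]
        back_t = times[peak_idx:]
        driven[: peak_idx + 1] = kernel_fn(out_t, 0.0, movement.peak_time_s, start, peak)
        driven[peak_idx:] = kernel_fn(
            back_t, movement.peak_time_s, movement.duration_s, peak, start
        )

    joints = [movement.driven_joint]
    columns = [driven]
    for jname, jangle in movement.start_pose.items():
        if jname == movement.driven_joint:
            continue
        joints.append(jname)
        columns.append(np.full(n_frames + 1, float(jangle)))

    return JointTrajectory(
        joint_names=tuple(joints),
        times=times,
        angles=np.column_stack(columns),
        rate_hz=rate_hz,
        wrist_preset_deg=movement.wrist_preset_deg,
    )
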