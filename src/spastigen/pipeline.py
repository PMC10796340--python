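"""Desk-scale musculoskeletal analysis pipeline.

Five simplified stages mirror a standard musculoskeletal workflow for a
marker-driven simulation: (1) scale a generic model to the patient,
(2) marker-based inverse kinematics (least-squares per frame, with residual
reporting standing in for a residual-reduction pass), (3) joint-constraint
checking against limits expressed in radians, (4) musculotendon-length
analysis with constant moment arms, and (5) excitation-driven forward
muscle simulation with the spastic reflex. Motion is prescribed and muscles
respond — the passive-mobilisation scenario of a clinical spasticity exam —
so no rigid-body forward dynamics is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .cohort import Anthropometry, PatientRecord, generic_anthropometry
from .config import SimConfig, provenance_hash
from .kinematics import (
    JointTrajectory,
    MovementDefinition,
    get_movement,
    synthesize_trajectory,
)
from .skeleton import (
    DRIVEN_JOINTS,
    MarkerMap,
    MarkerTrajectorySet,
    SkeletonModel,
    build_skeleton,
    default_marker_map,
    forward_kinematics,
)
from .spastic_muscle import (
    FiberGeometryError,
    MuscleParams,
    MuscleSimResult,
    SpasticityParams,
    grade_parameters,
    simulate_muscle,
)

__all__ = [
    "MuscleGeometry",
    "JointLimits",
    "ScaleResult",
    "IKResult",
    "ConstraintViolation",
    "SimulationResult",
    "load_muscle_params",
    "load_muscle_geometry",
    "muscles_for_motion",
    "movement_driven_joint",
    "scale_model",
    "inverse_kinematics",
    "musculotendon_length",
    "check_joint_constraints",
    "default_joint_limits",
    "run_spastic_simulation",
    "write_model_file",
    "read_model_file",
]


@dataclass(frozen=True)
class MuscleGeometry:
    """Constant-moment-arm path of one muscle over one joint.

    ``lmt_0`` is the musculotendon length at zero joint angle (cm);
    ``moment_arm`` r (cm) is positive for muscles that shorten as the
    joint angle grows (agonists of the positive direction), so
    l_mt(theta) = lmt_0 - r * theta with theta in radians.
    """

    muscle: str
    joint: str
    lmt_0: float
    moment_arm: float
    segment: str = "upperarm"

    def __post_init__(self) -> None:
        if self.lmt_0 <= 0:
            raise ValueError(f"{self.muscle}: lmt_0 must be > 0")
        if self.moment_arm == 0:
            raise ValueError(f"{self.muscle}: moment_arm must be nonzero")


@dataclass(frozen=True)
class JointLimits:
    """Allowed joint excursion, radians."""

    joint: str
    min_angle: float
    max_angle: float

    def __post_init__(self) -> None:
        if not self.min_angle < self.max_angle:
            raise ValueError(f"{self.joint}: min must be < max")


@dataclass(frozen=True)
class ConstraintViolation:
    frame: int
    joint: str
    angle_rad: float
    limit: JointLimits


@dataclass(frozen=True)
class ScaleResult:
    factors: Mapping[str, float]
    skeleton: SkeletonModel


@dataclass(frozen=True)
class IKResult:
    trajectory: JointTrajectory
    residual_rms: np.ndarray          # per-frame, in the marker units
    non_converged_frames: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimulationResult:
    """Everything produced for one (patient, movement, grade) tuple."""

    patient_id: int
    movement: str
    grade: str
    trajectory: JointTrajectory
    muscles: Mapping[str, MuscleSimResult]
    spasticity: SpasticityParams
    constraint_violations: tuple[ConstraintViolation, ...]
    provenance: Mapping[str, object]


# Table of muscles recruited per movement direction. Flexion-extension
# style movements use the union of both direction rows.
_MOTION_MUSCLES: dict[str, list[str]] = {
    "elbow_flexion_extension": ["BICLong", "BICShort", "BRA"],
    "forearm_pronation_supination": [
        "PT", "PQ", "BICLong", "BICShort", "brachioradialis", "SUP",
    ],
    "shoulder_flexion_extension": [
        "DELT1", "BICLong", "BICShort", "PECM1", "PECM2", "PECM3",
        "DELT3", "TRILong",
    ],
    "shoulder_abduction_adduction": [
        "DELT2", "SUPSP", "TMAJ", "PECM1", "PECM2", "PECM3", "TRILong",
    ],
}


def muscles_for_motion(movement: str) -> list[str]:
    """Muscles recruited by a catalogue movement (both directions)."""
    try:
        return list(_MOTION_MUSCLES[movement])
    except KeyError as exc:
        raise KeyError(
            f"unknown movement {movement!r}; valid: {sorted(_MOTION_MUSCLES)}"
        ) from exc


def movement_driven_joint(movement: str) -> str:
    return get_movement(movement).driven_joint


def _data_file(name: str) -> str:
    return str(resources.files("spastigen").joinpath("data", name))


def load_muscle_params(path=None) -> dict[str, MuscleParams]:
    """Per-muscle Hill constants from the packaged (or a user) CSV."""
    df = pd.read_csv(path or _data_file("muscles.csv"))
    out: dict[str, MuscleParams] = {}
    for _, row in df.iterrows():
        out[row["name"]] = MuscleParams(
            name=row["name"],
            f_max=float(row["f_max_n"]),
            l_opt=float(row["l_opt_cm"]),
            l_slack=float(row["l_slack_cm"]),
            v_max=float(row["v_max"]),
            pennation=float(row["pennation_rad"]),
            tau_act=float(row["tau_act_s"]),
            tau_deact=float(row["tau_deact_s"]),
        )
    return out


def load_muscle_geometry(
    path=None, params: Mapping[str, MuscleParams] | None = None,
    segments: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], MuscleGeometry]:
    """(muscle, joint) -> geometry. ``lmt_0`` is derived from the muscle's
    tendon slack length plus the tabulated rest fiber length (in optima)
    so the fiber starts at a plausible point on the force-length curve."""
    params = params or load_muscle_params()
    pdf = pd.read_csv(_data_file("muscles.csv"))
    seg = segments or dict(zip(pdf["name"], pdf["segment"]))
    df = pd.read_csv(path or _data_file("muscle_geometry.csv"))
    out: dict[tuple[str, str], MuscleGeometry] = {}
    for _, row in df.iterrows():
        m = params[row["muscle"]]
        lmt_0 = m.l_slack + float(row["rest_fiber_norm"]) * m.l_opt * math.cos(m.pennation)
        out[(row["muscle"], row["joint"])] = MuscleGeometry(
            muscle=row["muscle"],
            joint=row["joint"],
            lmt_0=lmt_0,
            moment_arm=float(row["moment_arm_cm"]),
            segment=seg.get(row["muscle"], "upperarm"),
        )
    return out


def scale_model(
    generic: Anthropometry,
    patient: Anthropometry,
    geometry: Mapping[tuple[str, str], MuscleGeometry] | None = None,
) -> tuple[ScaleResult, dict[tuple[str, str], MuscleGeometry]]:
    """Scale the generic model to a patient.

    Per-segment factor = patient length / generic length; the skeleton is
    rebuilt with the patient's lengths and each muscle's ``lmt_0`` is
    scaled by its segment's factor.
    """
    factors = {}
    for name in ("height", "upperarm", "forearm", "hand"):
        g = getattr(generic, name)
        if g == 0:
            raise ValueError(f"generic {name} length is zero")
        factors[name] = getattr(patient, name) / g
    skeleton = build_skeleton(patient)
    geometry = geometry if geometry is not None else load_muscle_geometry()
    scaled = {
        key: MuscleGeometry(
            muscle=geo.muscle,
            joint=geo.joint,
            lmt_0=geo.lmt_0 * factors.get(geo.segment, 1.0),
            moment_arm=geo.moment_arm,
            segment=geo.segment,
        )
        for key, geo in geometry.items()
    }
    return ScaleResult(factors=factors, skeleton=skeleton), scaled


def musculotendon_length(
    trajectory: JointTrajectory,
    geometry: MuscleGeometry,
    l_slack: float | None = None,
) -> np.ndarray:
    """l_mt(t) = lmt_0 - r * theta(t), theta in radians (cm).

    If the muscle's tendon slack length is supplied, a path shorter than
    the tendon anywhere raises before any simulation is attempted.
    """
    if geometry.joint not in trajectory.joint_names:
        raise KeyError(
            f"{geometry.muscle}: joint {geometry.joint!r} not in trajectory "
            f"{trajectory.joint_names}"
        )
    theta = np.deg2rad(trajectory.angle(geometry.joint))
    lmt = geometry.lmt_0 - geometry.moment_arm * theta
    if l_slack is not None and np.any(lmt <= l_slack):
        bad = int(np.argmax(lmt <= l_slack))
        raise FiberGeometryError(
            f"{geometry.muscle}: l_mt {lmt[bad]:.3f} cm <= tendon slack "
            f"{l_slack:.3f} cm at frame {bad}"
        )
    return lmt


def default_joint_limits() -> dict[str, JointLimits]:
    """Physiological joint limits, radians."""
    deg = math.radians
    return {
        "elbow_flexion": JointLimits("elbow_flexion", deg(0.0), deg(150.0)),
        "shoulder_flexion": JointLimits("shoulder_flexion", deg(-60.0), deg(180.0)),
        "shoulder_abduction": JointLimits("shoulder_abduction", deg(0.0), deg(180.0)),
        "forearm_pronation": JointLimits("forearm_pronation", deg(-90.0), deg(90.0)),
    }


def check_joint_constraints(
    trajectory: JointTrajectory,
    limits: Mapping[str, JointLimits] | None = None,
) -> list[ConstraintViolation]:
    """Every (frame, joint) sample outside its limits; empty when clean."""
    limits = limits if limits is not None else default_joint_limits()
    out: list[ConstraintViolation] = []
    for joint in trajectory.joint_names:
        if joint not in limits:
            continue
        lim = limits[joint]
        theta = np.deg2rad(trajectory.angle(joint))
        bad = np.nonzero((theta < lim.min_angle - 1e-12) | (theta > lim.max_angle + 1e-12))[0]
        out.extend(
            ConstraintViolation(int(f), joint, float(theta[f]), lim) for f in bad
        )
    out.sort(key=lambda v: (v.frame, v.joint))
    return out


def inverse_kinematics(
    markers: MarkerTrajectorySet,
    skeleton: SkeletonModel,
    free_joints: Sequence[str] = DRIVEN_JOINTS,
    wrist_preset_deg: float = 0.0,
    marker_map: MarkerMap | None = None,
    rate_hz: float | None = None,
    x0_deg: Mapping[str, float] | None = None,
) -> IKResult:
    """Per-frame least-squares joint-angle estimation from markers.

    Minimises the sum of squared distances between observed markers and the
    model-predicted positions of the same markers, warm-starting each frame
    at the previous solution. Markers may be in skeleton (source) names or
    in reduced (target) names — pass the map used for reduction. The
    per-frame residual RMS is reported; a frame whose solve fails falls
    back to the previous frame's angles and is flagged.
    """
    if marker_map is not None:
        inv = {t: s for s, t in marker_map.pairs}
        names = tuple(inv.get(n, n) for n in markers.marker_names)
    else:
        names = markers.marker_names
    usable = [n for n in names if n in skeleton.joint_names]
    if not usable:
        raise KeyError(
            f"no marker resolves to a skeleton joint; got {names[:5]}..."
        )
    obs_idx = [names.index(n) for n in usable]
    sk_idx = [n for n in usable]
    obs = markers.in_units("cm")
    obs_pos = np.asarray(obs.positions)[:, obs_idx, :]
    n_frames = obs_pos.shape[0]
    times = np.asarray(markers.times, dtype=float)
    rate = rate_hz or (1.0 / (times[1] - times[0]) if n_frames > 1 else 100.0)

    free = list(free_joints)
    unknown = [j for j in free if j not in DRIVEN_JOINTS]
    if unknown:
        raise KeyError(f"cannot solve for unknown joint(s) {unknown}")
    limits = default_joint_limits()
    lb = [math.degrees(limits[j].min_angle) for j in free]
    ub = [math.degrees(limits[j].max_angle) for j in free]

    def model_positions(angles_deg: np.ndarray) -> np.ndarray:
        traj = JointTrajectory(
            joint_names=tuple(free),
            times=np.array([0.0]),
            angles=angles_deg.reshape(1, -1),
            rate_hz=rate,
            wrist_preset_deg=wrist_preset_deg,
        )
        fk = forward_kinematics(skeleton, traj)
        idx = [fk.marker_names.index(n) for n in sk_idx]
        return np.asarray(fk.positions)[0, idx, :]

    x = np.array(
        [float((x0_deg or {}).get(j, 0.0)) for j in free]
    )
    angles = np.empty((n_frames, len(free)))
    rms = np.empty(n_frames)
    failed: list[int] = []
    for f in range(n_frames):
        target = obs_pos[f]

        def resid(a):
            return (model_positions(a) - target).ravel()

        try:
            sol = least_squares(
                resid, np.clip(x, lb, ub), bounds=(lb, ub),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            x = sol.x
            r = sol.fun
        except Exception:
            failed.append(f)
            r = resid(x)
        angles[f] = x
        rms[f] = float(np.sqrt(np.mean(r**2)))
    traj = JointTrajectory(
        joint_names=tuple(free),
        times=times,
        angles=angles,
        rate_hz=rate,
        wrist_preset_deg=wrist_preset_deg,
    )
    return IKResult(trajectory=traj, residual_rms=rms,
                    non_converged_frames=tuple(failed))


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_spastic_simulation(
    patient: PatientRecord,
    movement: MovementDefinition | str,
    grade: str,
    config: SimConfig | None = None,
    seed: int | None = None,
    generic: Anthropometry | None = None,
    muscle_params: Mapping[str, MuscleParams] | None = None,
    geometry: Mapping[tuple[str, str], MuscleGeometry] | None = None,
) -> SimulationResult:
    """Full per-sample pipeline for one (patient, movement, MAS grade).

    Deterministic given config and seed. Raises PipelineStageError with the
    failing stage named.
    """
    config = config or SimConfig()
    if isinstance(movement, str):
        movement = get_movement(
            movement, duration_s=config.duration_s, peak_time_s=config.peak_time_s
        )
    if movement.name in config.rom_overrides:
        movement = movement.with_rom(float(config.rom_overrides[movement.name]))

    try:
        scale, scaled_geometry = scale_model(
            generic or generic_anthropometry(), patient.anthropometry, geometry
        )
    except Exception as exc:
        raise PipelineStageError(f"scale: {exc}") from exc

    try:
        trajectory = synthesize_trajectory(
            movement, rate_hz=config.rate_hz, kernel=config.kernel
        )
    except Exception as exc:
        raise PipelineStageError(f"kinematics: {exc}") from exc

    violations = tuple(check_joint_constraints(trajectory))

    params = dict(muscle_params or load_muscle_params())
    if config.scale_force_by_tone:
        from dataclasses import replace as _replace
        params = {
            k: _replace(v, f_max=v.f_max * patient.tone_pct / 50.0)
            for k, v in params.items()
        }
    spastic = grade_parameters(grade)
    driven = movement.driven_joint
    results: dict[str, MuscleSimResult] = {}
    for mname in muscles_for_motion(movement.name):
        key = (mname, driven)
        if key not in scaled_geometry:
            raise PipelineStageError(
                f"musculotendon-length: no geometry for muscle {mname!r} "
                f"over joint {driven!r}"
            )
        geo = scaled_geometry[key]
        m = params[mname]
        try:
            lmt = musculotendon_length(trajectory, geo, l_slack=m.l_slack)
            results[mname] = simulate_muscle(
                lmt, trajectory.times, m, spastic,
                baseline_excitation=config.baseline_excitation,
            )
        except Exception as exc:
            raise PipelineStageError(f"muscle-simulation[{mname}]: {exc}") from exc

    return SimulationResult(
        patient_id=patient.id,
        movement=movement.name,
        grade=grade,
        trajectory=trajectory,
        muscles=results,
        spasticity=spastic,
        constraint_violations=violations,
        provenance={
            "config_hash": provenance_hash(config, seed),
            "seed": seed,
            "scale_factors": dict(scale.factors),
        },
    )


def write_model_file(
    path,
    skeleton: SkeletonModel,
    limits: Mapping[str, JointLimits] | None = None,
    geometry: Mapping[tuple[str, str], MuscleGeometry] | None = None,
) -> None:
    """Miniature structured-text model description (limits in radians)."""
    limits = limits if limits is not None else default_joint_limits()
    geometry = geometry if geometry is not None else load_muscle_geometry()
    doc = {
        "segments_cm": {
            "upperarm": skeleton.upperarm,
            "forearm": skeleton.forearm,
            "hand": skeleton.hand,
        },
        "joints": list(skeleton.joint_names),
        "constraints_rad": {
            j: [lim.min_angle, lim.max_angle] for j, lim in limits.items()
        },
        "muscle_geometry": [
            {
                "muscle": g.muscle, "joint": g.joint,
                "lmt_0_cm": g.lmt_0, "moment_arm_cm": g.moment_arm,
                "segment": g.segment,
            }
            for g in geometry.values()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_model_file(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
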