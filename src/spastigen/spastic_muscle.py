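"""Hill-type musculotendon model with a delayed velocity-feedback stretch reflex.

The muscle is a rigid-tendon Hill model: tendon fixed at slack length, so
fiber kinematics follow directly from musculotendon length. Active force is
activation x force-length x force-velocity, a parallel passive element adds
exponentially above optimal length, and excitation-to-activation is a
first-order lag with distinct activation/deactivation time constants.

Spasticity is a reflex controller layered on top: when the *delayed*
normalized fiber lengthening velocity exceeds a threshold, a proportional
excitation is injected,

    e_sp(t) = clip( G * max(0, v(t - d) - v_th), 0, 1 ),

with gain G, threshold v_th (optimal fiber lengths per second) and neural
delay d (s). The six Modified Ashworth Scale grades (0, 1, 1+, 2, 3, 4) map
to triples with strictly increasing gain and strictly decreasing threshold,
so higher grades fire earlier and harder on passive stretch — grade 0 has
zero gain (no increase in muscle tone). The grade table is a modelling
choice, not a measured quantity, and is fully configurable.

Sign convention: fiber velocity is positive while lengthening (the stretch
reflex fires on stretch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MuscleParams",
    "SpasticityParams",
    "MASGrade",
    "MuscleSimResult",
    "MAS_GRADE_LABELS",
    "mas_grade_table",
    "grade_parameters",
    "active_force_length",
    "force_velocity_multiplier",
    "passive_force_length",
    "activation_dynamics_step",
    "spastic_excitation",
    "simulate_muscle",
]

# Curve constants (classic first-order Hill/equilibrium-muscle defaults).
GAMMA_FL = 0.45      # force-length Gaussian width
A_F = 0.25           # Hill force-velocity curvature
F_ECC_MAX = 1.4      # eccentric force plateau
K_PE = 5.0           # passive exponential shape
EPS0_PE = 0.6        # passive strain at which the passive multiplier is 1

DEFAULT_TAU_ACT = 0.01    # s
DEFAULT_TAU_DEACT = 0.04  # s

MAS_GRADE_LABELS = ("0", "1", "1+", "2", "3", "4")

#: Default MAS grade -> (gain, threshold, delay) table. Monotone by
#: construction: gains strictly increase, thresholds strictly decrease.
#: Grade 0 has zero gain; its threshold is +inf (the reflex can never fire).
DEFAULT_GRADE_TABLE: dict[str, tuple[float, float, float]] = {
    "0": (0.0, math.inf, 0.03),
    "1": (0.5, 0.20, 0.03),
    "1+": (1.0, 0.15, 0.03),
    "2": (2.0, 0.10, 0.03),
    "3": (4.0, 0.05, 0.03),
    "4": (8.0, 0.02, 0.03),
}

_MAS_DESCRIPTIONS = {
    "0": "No increase in muscle tone",
    "1": "Slight increase in muscle tone, with a catch and release or minimal "
         "resistance at the end of the range of motion",
    "1+": "Slight increase in muscle tone, manifested as a catch, followed by "
          "minimal resistance through the remainder (less than half) of the "
          "range of motion",
    "2": "A marked increase in muscle tone throughout most of the range of "
         "motion, but affected part(s) are still easily moved",
    "3": "Considerable increase in muscle tone, passive movement difficult",
    "4": "Affected part(s) rigid in flexion or extension",
}


@dataclass(frozen=True)
class MuscleParams:
    """Hill-muscle constants for one musculotendon actuator.

    Lengths in cm, force in N, velocity in optimal fiber lengths per
    second, pennation in radians, time constants in seconds.
    """

    name: str
    f_max: float
    l_opt: float
    l_slack: float
    v_max: float = 10.0
    pennation: float = 0.0
    tau_act: float = DEFAULT_TAU_ACT
    tau_deact: float = DEFAULT_TAU_DEACT

    def __post_init__(self) -> None:
        for f in ("f_max", "l_opt", "l_slack", "v_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be > 0")
        if not (0 < self.tau_act <= self.tau_deact):
            raise ValueError(
                f"{self.name}: need 0 < tau_act <= tau_deact "
                f"({self.tau_act}, {self.tau_deact})"
            )


@dataclass(frozen=True)
class SpasticityParams:
    """Reflex controller constants: gain G, threshold v_th, delay d (s)."""

    gain: float
    threshold: float
    delay: float

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError(f"gain must be >= 0, got {self.gain}")
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")


@dataclass(frozen=True)
class MASGrade:
    label: str
    description: str


def mas_grade_table() -> list[MASGrade]:
    """The six Modified Ashworth Scale grades."""
    return [MASGrade(lbl, _MAS_DESCRIPTIONS[lbl]) for lbl in MAS_GRADE_LABELS]


def grade_parameters(
    grade: MASGrade | str,
    table: Mapping[str, tuple[float, float, float]] | None = None,
) -> SpasticityParams:
    """Reflex parameters for a MAS grade (configurable table)."""
    label = grade.label if isinstance(grade, MASGrade) else str(grade)
    table = DEFAULT_GRADE_TABLE if table is None else table
    try:
        g, v_th, d = table[label]
    except KeyError as exc:
        raise KeyError(
            f"unknown MAS grade {label!r}; valid: {list(table)}"
        ) from exc
    return SpasticityParams(gain=g, threshold=v_th, delay=d)


@dataclass(frozen=True)
class MuscleSimResult:
    """Per-muscle state time series from a forward simulation."""

    muscle: str
    times: np.ndarray               # (n,) s
    excitation: np.ndarray          # (n,) in [0, 1]
    activation: np.ndarray          # (n,) in [0, 1]
    fiber_length_norm: np.ndarray   # (n,) l_m / l_opt
    fiber_velocity_norm: np.ndarray  # (n,) l_opt/s, lengthening positive
    force: np.ndarray               # (n,) N

    def __post_init__(self) -> None:
        n = np.asarray(self.times).size
        for f in ("excitation", "activation", "fiber_length_norm",
                  "fiber_velocity_norm", "force"):
            if np.asarray(getattr(self, f)).shape != (n,):
                raise ValueError(f"{f} must have shape ({n},)")


def active_force_length(l_norm):
    """Active force-length multiplier: Gaussian about optimal fiber length."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalized fiber length must be positive")
    return np.exp(-((l_norm - 1.0) ** 2) / GAMMA_FL)


def force_velocity_multiplier(v_norm):
    """Hill force-velocity multiplier, ``v_norm`` = fiber velocity / v_max.

    Concentric branch (v_norm < 0): (1 + v)/(1 - v/a_f), clipped at 0 for
    v <= -1 (no force at or beyond maximal shortening velocity).
    Eccentric branch (v_norm > 0): saturates at F_ECC_MAX.
    """
    v = np.asarray(v_norm, dtype=float)
    v_c = np.minimum(v, 0.0)  # keep the hyperbola's denominator positive
    conc = np.clip((1.0 + v_c) / (1.0 - v_c / A_F), 0.0, None)
    # Eccentric hyperbola rising from 1 at v=0 to F_ECC_MAX as v -> inf,
    # slope-matched scale b chosen for a steep initial rise (classic shape).
    b = 0.15
    ecc = F_ECC_MAX - (F_ECC_MAX - 1.0) * b / (b + v)
    out = np.where(v < 0, conc, ecc)
    return float(out) if np.isscalar(v_norm) else out


def passive_force_length(l_norm):
    """Passive force-length multiplier: 0 below optimum, exponential above.

    Normalised so that a strain of EPS0_PE (l_norm = 1.6) gives exactly 1.
    """
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalized fiber length must be positive")
    strain = l_norm - 1.0
    raw = (np.exp(K_PE * np.clip(strain, 0.0, None)) - 1.0) / (
        np.exp(K_PE * EPS0_PE) - 1.0
    )
    out = np.where(strain <= 0, 0.0, raw)
    return float(out) if np.isscalar(l_norm) else out


def activation_dynamics_step(a, e, dt: float, tau_act: float, tau_deact: float):
    """One sample of the first-order excitation-to-activation lag.

    Solves da/dt = (e - a)/tau exactly over the step (zero-order hold on
    e), with tau = tau_act while e > a and tau_deact otherwise:
    a' = e + (a - e) * exp(-dt/tau). The update is contractive, so a stays
    in [0, 1] whenever e does; the result is clipped defensively anyway.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    tau = np.where(e > a, tau_act, tau_deact)
    a_next = e + (a - e) * np.exp(-dt / tau)
    out = np.clip(a_next, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _delayed(signal: np.ndarray, times: np.ndarray, delay: float) -> np.ndarray:
    """Signal evaluated at t - delay with quiescent (zero) history before t=0."""
    if delay == 0:
        return np.asarray(signal, dtype=float)
    t = np.asarray(times, dtype=float)
    return np.interp(t - delay, t, np.asarray(signal, dtype=float), left=0.0)


def spastic_excitation(
    v_norm: np.ndarray | Sequence[float],
    times: np.ndarray | Sequence[float],
    params: SpasticityParams,
) -> np.ndarray:
    """Reflex excitation time series from a normalized fiber-velocity history.

    e_sp(t) = clip(G * max(0, v(t - d) - v_th), 0, 1); before the delay has
    elapsed the reflex sees quiescent (zero-velocity) history.
    """
    v_d = _delayed(np.asarray(v_norm, dtype=float), np.asarray(times, dtype=float),
                   params.delay)
    if params.gain == 0.0:
        return np.zeros_like(v_d)
    over = np.clip(v_d - params.threshold, 0.0, None)
    return np.clip(params.gain * over, 0.0, 1.0)


class FiberGeometryError(ValueError):
    """Musculotendon path shorter than the tendon: fiber length would vanish."""


def simulate_muscle(
    lmt_series: np.ndarray,
    times: np.ndarray,
    muscle: MuscleParams,
    spastic: SpasticityParams | None = None,
    baseline_excitation: float = 0.0,
    initial_activation: float = 0.0,
) -> MuscleSimResult:
    """Forward-simulate one muscle along a prescribed musculotendon length path.

    Rigid-tendon kinematics give the fiber state per frame
    (l_m cos(pennation) = l_mt - l_slack); normalized fiber velocity comes
    from finite differences; total excitation is the clipped sum of the
    baseline and the reflex; activation integrates the first-order lag; and
    force = f_max (a f_L f_V + f_P) cos(pennation), floored at zero.

    Parameters
    ----------
    lmt_series : array (n,)
        Musculotendon length per frame, cm, uniformly sampled.
    times : array (n,)
        Sample times, s.
    spastic : SpasticityParams, optional
        ``None`` disables the reflex entirely (identical to gain 0).
    """
    lmt = np.asarray(lmt_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if lmt.shape != t.shape or lmt.ndim != 1 or t.size < 2:
        raise ValueError("lmt_series and times must be equal-length 1-D, n >= 2")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
        raise ValueError("times must be uniformly sampled")
    if not 0.0 <= baseline_excitation <= 1.0:
        raise ValueError("baseline_excitation must be in [0, 1]")
    dt = float(dts[0])

    cos_penn = math.cos(muscle.pennation)
    fiber = (lmt - muscle.l_slack) / cos_penn
    if np.any(fiber <= 0):
        bad = int(np.argmax(fiber <= 0))
        raise FiberGeometryError(
            f"{muscle.name}: musculotendon length {lmt[bad]:.3f} cm at frame {bad} "
            f"does not exceed tendon slack length {muscle.l_slack:.3f} cm"
        )
    l_norm = fiber / muscle.l_opt
    v_norm = np.gradient(l_norm, t)  # l_opt/s, lengthening positive

    if spastic is None:
        e_sp = np.zeros_like(v_norm)
    else:
        e_sp = spastic_excitation(v_norm, t, spastic)
    excitation = np.clip(baseline_excitation + e_sp, 0.0, 1.0)

    activation = np.empty_like(excitation)
    activation[0] = float(np.clip(initial_activation, 0.0, 1.0))
    a = activation[0]
    for k in range(1, t.size):
        a = activation_dynamics_step(
            a, excitation[k - 1], dt, muscle.tau_act, muscle.tau_deact
        )
        activation[k] = a

    f_l = active_force_length(l_norm)
    f_v = force_velocity_multiplier(v_norm / muscle.v_max)
    f_p = passive_force_length(l_norm)
    force = np.clip(
        muscle.f_max * (activation * f_l * f_v + f_p) * cos_penn, 0.0, None
    )
    return MuscleSimResult(
        muscle=muscle.name,
        times=t,
        excitation=excitation,
        activation=activation,
        fiber_length_norm=l_norm,
        fiber_velocity_norm=v_norm,
        force=force,
    )
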