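"""Hill-muscle curves, activation dynamics and the spastic reflex."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spastigen.spastic_muscle import (
    DEFAULT_GRADE_TABLE,
    FiberGeometryError,
    MAS_GRADE_LABELS,
    MuscleParams,
    SpasticityParams,
    activation_dynamics_step,
    active_force_length,
    force_velocity_multiplier,
    grade_parameters,
    mas_grade_table,
    passive_force_length,
    simulate_muscle,
    spastic_excitation,
)


TEST_MUSCLE = MuscleParams(
    name="test", f_max=100.0, l_opt=10.0, l_slack=20.0, v_max=10.0,
    pennation=0.0, tau_act=0.01, tau_deact=0.04,
)


class TestCurves:
    def test_force_length_optimum_and_symmetry(self):
        assert active_force_length(1.0) == 1.0
        assert active_force_length(0.5) == pytest.approx(math.exp(-0.25 / 0.45))
        assert active_force_length(0.5) == pytest.approx(active_force_length(1.5))

    def test_force_length_positive_domain(self):
        with pytest.raises(ValueError):
            active_force_length(0.0)

    def test_force_velocity_isometric_and_limits(self):
        assert force_velocity_multiplier(0.0) == 1.0
        assert force_velocity_multiplier(-1.0) == 0.0
        assert force_velocity_multiplier(-2.0) == 0.0  # beyond max shortening
        assert force_velocity_multiplier(1e9) == pytest.approx(1.4, rel=1e-6)

    def test_force_velocity_monotone(self):
        v = np.linspace(-1.5, 3.0, 400)
        f = force_velocity_multiplier(v)
        assert np.all(np.diff(f) >= -1e-12)

    def test_passive_slack_then_exponential(self):
        assert passive_force_length(0.9) == 0.0
        assert passive_force_length(1.0) == 0.0
        assert passive_force_length(1.6) == pytest.approx(1.0)
        l = np.linspace(0.5, 2.0, 300)
        assert np.all(np.diff(passive_force_length(l)) >= 0.0)


class TestActivationDynamics:
    def test_equilibrium(self):
        assert activation_dynamics_step(0.5, 0.5, 0.01, 0.01, 0.04) == 0.5

    def test_step_response_matches_closed_form(self):
        # a(t) = 1 - exp(-t/tau_act) for a(0)=0, e=1
        a, dt, tau = 0.0, 0.01, 0.01
        for k in range(1, 51):
            a = activation_dynamics_step(a, 1.0, dt, tau, 0.04)
            assert a == pytest.approx(1.0 - math.exp(-k * dt / tau), abs=1e-12)

    def test_decay_uses_slow_constant_and_floors_at_zero(self):
        a = 1.0
        for k in range(1, 11):
            a = activation_dynamics_step(a, 0.0, 0.01, 0.01, 0.04)
            assert a == pytest.approx(math.exp(-k * 0.01 / 0.04), abs=1e-12)
        for _ in range(2000):
            a = activation_dynamics_step(a, 0.0, 0.05, 0.01, 0.04)
        assert 0.0 <= a < 1e-10

    @given(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0),
        st.floats(1e-4, 0.1),
    )
    def test_stays_in_unit_interval(self, a, e, dt):
        out = activation_dynamics_step(a, e, dt, 0.01, 0.04)
        assert 0.0 <= out <= 1.0

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            activation_dynamics_step(0.1, 0.2, 0.0, 0.01, 0.04)


class TestReflex:
    def test_zero_gain_always_silent(self):
        t = np.linspace(0, 6, 601)
        v = np.sin(t) * 5.0
        p = SpasticityParams(gain=0.0, threshold=0.1, delay=0.03)
        assert np.all(spastic_excitation(v, t, p) == 0.0)

    def test_below_threshold_silent(self):
        t = np.linspace(0, 6, 601)
        p = SpasticityParams(gain=5.0, threshold=0.3, delay=0.0)
        v = np.full_like(t, 0.2)  # threshold - 0.1
        assert np.all(spastic_excitation(v, t, p) == 0.0)

    def test_delayed_step_closed_form(self):
        # v steps to threshold+0.2 at t=1 s; gain 2, delay 0.03 s
        # -> e_sp = 0 before 1.03 s, 0.4 after
        t = np.arange(0, 3.0 + 1e-12, 0.01)
        v = np.where(t >= 1.0, 0.3, 0.0)
        p = SpasticityParams(gain=2.0, threshold=0.1, delay=0.03)
        e = spastic_excitation(v, t, p)
        assert np.all(e[t < 1.03 - 1e-9] == 0.0)
        assert np.all(e[t >= 1.03 + 1e-9] == pytest.approx(0.4))

    def test_causality_quiescent_history(self):
        # outputs on [0, d) are independent of the velocity signal
        t = np.arange(0, 1.0, 0.01)
        p = SpasticityParams(gain=3.0, threshold=0.0, delay=0.5)
        e1 = spastic_excitation(np.full_like(t, 9.9), t, p)
        e2 = spastic_excitation(np.full_like(t, 0.1), t, p)
        pre = t < 0.5 - 0.011  # interp straddles one sample at the boundary
        assert np.allclose(e1[pre], e2[pre])

    def test_clipped_at_one(self):
        t = np.arange(0, 1.0, 0.01)
        p = SpasticityParams(gain=100.0, threshold=0.0, delay=0.0)
        assert spastic_excitation(np.full_like(t, 5.0), t, p).max() == 1.0


class TestGradeTable:
    def test_six_distinct_grades(self):
        table = mas_grade_table()
        assert [g.label for g in table] == list(MAS_GRADE_LABELS)
        triples = {DEFAULT_GRADE_TABLE[g.label] for g in table}
        assert len(triples) == 6

    def test_grade0_null_reflex(self):
        assert grade_parameters("0").gain == 0.0

    def test_gains_increase_thresholds_decrease(self):
        params = [grade_parameters(g) for g in MAS_GRADE_LABELS]
        gains = [p.gain for p in params]
        thresholds = [p.threshold for p in params]
        assert all(a < b for a, b in zip(gains, gains[1:]))
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_one_plus_distinct(self):
        p = grade_parameters("1+")
        assert p != grade_parameters("1") and p != grade_parameters("2")

    def test_unknown_grade(self):
        with pytest.raises(KeyError, match="valid"):
            grade_parameters("5")


def _stretch_lmt(n=301, rate=100.0, amp=3.0):
    """Lengthening-then-return musculotendon path above slack + optimum."""
    t = np.arange(n) / rate
    lmt = 30.0 + amp * np.sin(np.pi * t / t[-1]) ** 2
    return lmt, t


class TestSimulateMuscle:
    def test_constant_length_no_drive_gives_passive_only(self):
        t = np.arange(0, 1.0, 0.01)
        lmt = np.full_like(t, 36.0)  # l_norm = 1.6 -> passive multiplier 1
        res = simulate_muscle(lmt, t, TEST_MUSCLE, SpasticityParams(0.0, 0.1, 0.03), 0.0)
        assert np.all(res.activation == 0.0)
        assert np.allclose(res.force, TEST_MUSCLE.f_max)  # f_P(1.6) = 1

    def test_constant_length_grade_invariant(self):
        t = np.arange(0, 1.0, 0.01)
        lmt = np.full_like(t, 32.0)
        r0 = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters("0"), 0.0)
        r3 = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters("3"), 0.0)
        assert np.array_equal(r0.force, r3.force)
        assert np.array_equal(r0.activation, r3.activation)

    def test_grade0_identical_to_reflex_off(self):
        lmt, t = _stretch_lmt()
        on = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters("0"), 0.1)
        off = simulate_muscle(lmt, t, TEST_MUSCLE, None, 0.1)
        for f in ("excitation", "activation", "force"):
            assert np.array_equal(getattr(on, f), getattr(off, f))

    def test_grade_monotonicity_pointwise(self):
        lmt, t = _stretch_lmt()
        prev = None
        for g in MAS_GRADE_LABELS:
            res = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters(g), 0.0)
            if prev is not None:
                assert np.all(res.excitation >= prev.excitation - 1e-15)
            prev = res
        g0 = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters("0"), 0.0)
        g4 = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters("4"), 0.0)
        assert np.any(g4.activation > g0.activation)

    def test_fiber_vanishing_rejected(self):
        t = np.arange(0, 0.5, 0.01)
        lmt = np.linspace(30.0, 19.0, t.size)  # crosses slack length 20
        with pytest.raises(FiberGeometryError, match="slack"):
            simulate_muscle(lmt, t, TEST_MUSCLE, None, 0.0)

    def test_force_nonnegative_and_bounded_states(self):
        lmt, t = _stretch_lmt(amp=8.0)
        res = simulate_muscle(lmt, t, TEST_MUSCLE, grade_parameters("4"), 0.3)
        assert res.force.min() >= 0.0
        for f in (res.excitation, res.activation):
            assert f.min() >= 0.0 and f.max() <= 1.0

    def test_randomized_sweep_activation_bounds(self, rng):
        """1,000 random short simulations never leave the unit interval."""
        t = np.arange(0, 0.5, 0.01)
        for _ in range(1000):
            base = rng.uniform(25.0, 40.0)
            amp = rng.uniform(0.0, 6.0)
            phase = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.3, 4.0)
            lmt = base + amp * np.sin(2 * np.pi * freq * t + phase)
            lmt = np.clip(lmt, 20.5, None)
            p = SpasticityParams(
                gain=rng.uniform(0, 10), threshold=rng.uniform(0, 0.5),
                delay=rng.uniform(0, 0.1),
            )
            res = simulate_muscle(lmt, t, TEST_MUSCLE, p, rng.uniform(0, 1))
            assert res.excitation.min() >= 0.0 and res.excitation.max() <= 1.0
            assert res.activation.min() >= 0.0 and res.activation.max() <= 1.0
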