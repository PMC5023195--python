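import math

import numpy as np
import pytest

from crossbridge.energy_landscape import EnergyParams, ParameterError, Scenario
from crossbridge.langevin_engine import ChemState, initial_ensemble
from crossbridge.markov_engine import initial_markov_ensemble
from crossbridge.rate_theory import AttachDetachParams
from crossbridge.sarcomere import (
    SarcomereGeometry,
    UnloadedSarcomereError,
    detect_isotonic_phases,
    hill_fit,
    run_isometric,
    run_isotonic,
    run_length_step,
    solve_equilibrium_z,
    total_tension,
)

SMALL = SarcomereGeometry(N_Fil=2, N_XB=20)


def attached_ensemble(xs, p, seed=1):
    e = initial_ensemble(len(xs), p, seed)
    e.chem[:] = ChemState.S
    e.x[:] = xs
    e.x0[:] = xs
    e.well[:] = 0
    return e


class TestMechanics:
    def test_tension_zero_without_attachment(self, p_ref):
        e = initial_ensemble(10, p_ref, 1)
        assert total_tension(e, p_ref) == 0.0

    def test_single_motor_tension(self, p_ref):
        e = attached_ensemble([3.0], p_ref)
        assert total_tension(e, p_ref) == pytest.approx(6.0)  # k+ = 2

    def test_compressed_motor_contributes_negative(self, p_ref):
        e = attached_ensemble([-1.0], p_ref)
        assert total_tension(e, p_ref) == pytest.approx(-p_ref.k_minus)

    def test_single_spring_algebra(self, p_ref):
        e = attached_ensemble([3.0], p_ref)
        F = 10.0
        dz = solve_equilibrium_z(e, F, p_ref)
        assert dz == pytest.approx((F - 6.0) / p_ref.k_plus)

    def test_force_equal_tension_leaves_z(self, p_ref):
        e = attached_ensemble([3.0, 1.0, 2.0], p_ref)
        F = total_tension(e, p_ref)
        assert solve_equilibrium_z(e, F, p_ref) == pytest.approx(0.0, abs=1e-9)

    def test_synchronized_strokes_slide_by_step(self, p_ref):
        """If every attached motor completes one stroke of displacement
        d between equilibrium solves, the filament slides back by
        exactly d (the sliding-velocity identity, machine precision)."""
        xs = np.array([1.0, 2.0, 3.0, 1.5])
        e = attached_ensemble(xs, p_ref)
        F = total_tension(e, p_ref)
        e.x[:] += p_ref.d  # one forward power stroke each
        dz = solve_equilibrium_z(e, F, p_ref)
        assert dz == pytest.approx(-p_ref.d, abs=1e-12)

    def test_no_attachment_raises(self, p_ref):
        e = initial_ensemble(5, p_ref, 1)
        with pytest.raises(UnloadedSarcomereError):
            solve_equilibrium_z(e, 5.0, p_ref)

    def test_markov_ensemble_supported(self, p_fiber):
        e = initial_markov_ensemble(4, Scenario.SL, p_fiber, 1)
        e.chem[:] = 2
        e.xs[:] = 2.0
        assert total_tension(e, p_fiber) == pytest.approx(4 * 2 * 2.0)
        dz = solve_equilibrium_z(e, 8.0, p_fiber)
        e.xs[:] += dz
        assert total_tension(e, p_fiber) == pytest.approx(8.0, abs=1e-6)


class TestIsometric:
    def test_population_conservation_and_determinism(self, p_fiber, ap_default):
        r1 = run_isometric(Scenario.SL, "markov", 5e7, 4, SMALL,
                           p=p_fiber, ap=ap_default)
        np.testing.assert_allclose(r1.populations.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(r1.S_TOT, r1.populations[:, 2:].sum(axis=1))
        r2 = run_isometric(Scenario.SL, "markov", 5e7, 4, SMALL,
                           p=p_fiber, ap=ap_default)
        np.testing.assert_array_equal(r1.tension, r2.tension)
        np.testing.assert_array_equal(r1.populations, r2.populations)

    def test_tension_rises_to_positive_plateau(self, p_fiber, ap_default):
        r = run_isometric(Scenario.SRII, "markov", 2e8, 2, SMALL,
                          p=p_fiber, ap=ap_default)
        assert r.T0 > 0
        early = r.tension[: r.tension.size // 10].mean()
        assert r.T0 > early
        assert 0 < r.plateau_populations[2:].sum() < 1


class TestIsotonic:
    def test_clamp_at_isometric_tension_stalls(self, p_fiber, ap_default):
        """At F = T0 the shortening velocity sits at the noise floor."""
        kw = dict(geometry=SarcomereGeometry(), rise_duration=4e8,
                  p=p_fiber, ap=ap_default)
        stall = run_isotonic(Scenario.SRII, "markov", 4e8, 6,
                             force_frac=1.0, **kw)
        fast = run_isotonic(Scenario.SRII, "markov", 4e8, 6,
                            force_frac=0.2, **kw)
        v_stall, v_fast = stall.summaries["v"], fast.summaries["v"]
        # the clamp point shows no net shortening, only a creep/noise
        # band bounded by the low-load velocity
        assert v_stall < 0.5 * v_fast
        assert abs(v_stall) < v_fast

    def test_argument_validation(self, p_fiber):
        with pytest.raises(ParameterError):
            run_isotonic(Scenario.SL, "markov", 1e6, 1, SMALL, p=p_fiber)
        with pytest.raises(ParameterError):
            run_isotonic(Scenario.SL, "markov", 1e6, 1, SMALL, F=1.0,
                         force_frac=0.5, p=p_fiber)

    def test_langevin_engine_rejects_sharp_scenarios(self, p_fiber):
        with pytest.raises(ParameterError):
            run_isometric(Scenario.SRI, "langevin", 1e6, 1, SMALL, p=p_fiber)


class TestLengthStep:
    def test_zero_step_recovers_isometric_values(self, p_fiber, ap_default):
        """With delta = 0 the post-'step' tension continues the
        isometric plateau within its own fluctuation band."""
        r = run_length_step(Scenario.SL, "markov", 0.0, 3,
                            SarcomereGeometry(), rise_duration=3e8,
                            window=2e8, p=p_fiber, ap=ap_default)
        s = r.summaries
        post = r.tension[r.t > s["t_step"]]
        assert np.mean(post) == pytest.approx(s["T0"], rel=0.3)
        if not s.get("undefined"):
            assert s["T2"] == pytest.approx(s["T0"], rel=0.4)

    def test_release_drops_then_recovers(self, p_fiber, ap_default):
        r = run_length_step(Scenario.SL, "markov", 5.6, 3, SMALL,
                            rise_duration=3e8, window=1.5e8,
                            p=p_fiber, ap=ap_default)
        s = r.summaries
        assert s["T1"] < 0.5 * s["T0"]
        assert not s.get("undefined")
        assert s["T2"] > s["T1"]
        assert s["r"] > 0


class TestPhaseDetection:
    def test_synthetic_four_phase_transient(self):
        """A constructed z(t) with an elastic drop, fast shortening, a
        pause and a steady ramp is segmented into all four phases."""
        t = np.linspace(0, 1e6, 4000)
        z = (-2.0                                  # elastic drop
             - 3.0 * (1 - np.exp(-t / 2e4))       # rapid early shortening
             - 1e-6 * t * (t > 3e5)               # steady phase after a pause
             )
        ph = detect_isotonic_phases(t + 5e4, z, 5e4)
        assert ph["elastic_drop"] and ph["rapid_early"]
        assert ph["pause"] and ph["steady"]
        assert ph["all_four"]

    def test_pure_steady_ramp_is_not_four_phases(self):
        t = np.linspace(0, 1e6, 2000)
        z = -1e-5 * t
        ph = detect_isotonic_phases(t, z, 0.0)
        assert ph["steady"]
        assert not ph["all_four"]


class TestHillFit:
    def test_exact_recovery(self):
        a, b, T0 = 40.0, 1.2, 160.0
        F = np.linspace(0, T0, 12)
        v = b * (T0 - F) / (F + a)
        af, bf, vmax = hill_fit(np.c_[F, v], T0)
        assert af == pytest.approx(a, rel=1e-4)
        assert bf == pytest.approx(b, rel=1e-4)
        assert vmax == pytest.approx(b * T0 / a, rel=1e-4)

    def test_curve_passes_through_stall_point(self):
        a, b, T0 = 30.0, 2.0, 100.0
        F = np.linspace(0, T0, 8)
        v = b * (T0 - F) / (F + a)
        af, bf, _ = hill_fit(np.c_[F, v], T0)
        assert bf * (T0 - T0) / (T0 + af) == 0.0

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            hill_fit([(0.0, 1.0), (1.0, 0.5)], 1.0)
        with pytest.raises(ParameterError):
            hill_fit([(0.0, 1.0), (1.0, -0.5), (2.0, 0.1), (3.0, 0.0)], 3.0)
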