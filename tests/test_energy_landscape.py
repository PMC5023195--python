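import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from crossbridge.energy_landscape import (
    KB,
    KBT0,
    DegenerateLandscapeError,
    EnergyParams,
    ParameterError,
    Scenario,
    UnsupportedScenarioError,
    biochemical_energy,
    biochemical_force,
    effective_stiffness,
    elastic_energy,
    locate_extrema,
    parabolic_shift,
    shifted_minimum,
    total_energy,
)


class TestBiochemicalEnergy:
    def test_unbiased_minimum_value(self):
        p = EnergyParams(F_ATP=0.0)
        assert p.alpha_d == pytest.approx(1.5 * math.pi)
        assert biochemical_energy(0.0, 0.0, p) == pytest.approx(-p.H)

    def test_periodicity_with_linear_bias(self):
        p = EnergyParams()
        for x in np.linspace(-1.0, p.d + 1.0, 17):
            dE = biochemical_energy(x + p.d, 0.0, p) - biochemical_energy(x, 0.0, p)
            assert dE == pytest.approx(p.F_ATP * p.d, rel=1e-12)

    def test_minima_exactly_at_anchor_multiples(self):
        """Root-finding on E_c' confirms the derived phase constant puts
        stationary minima exactly at x0 + n d."""
        p = EnergyParams()
        h = 1e-6
        for n in range(3):
            xm = n * p.d
            grad = (biochemical_energy(xm + h, 0.0, p)
                    - biochemical_energy(xm - h, 0.0, p)) / (2 * h)
            curv = (biochemical_energy(xm + h, 0.0, p)
                    - 2 * biochemical_energy(xm, 0.0, p)
                    + biochemical_energy(xm - h, 0.0, p)) / h**2
            assert abs(grad) < 1e-6
            assert curv > 0
            # bracketed root of the analytic derivative
            root = brentq(lambda x: -biochemical_force(x, 0.0, p),
                          xm - 0.4 * p.d, xm + 0.4 * p.d)
            assert root == pytest.approx(xm, abs=1e-9)

    def test_minima_energies_decrease_by_bias_per_step(self):
        p = EnergyParams()
        e = [biochemical_energy(n * p.d, 0.0, p) for n in range(3)]
        assert e[0] > e[1] > e[2]
        assert e[1] - e[0] == pytest.approx(p.F_ATP * p.d)
        assert e[2] - e[1] == pytest.approx(p.F_ATP * p.d)

    def test_wall_continuation_confines(self):
        p = EnergyParams()
        inside = biochemical_energy(2 * p.d, 0.0, p)
        assert biochemical_energy(2 * p.d + 3 * p.d, 0.0, p) > inside + 100 * p.kBT
        assert biochemical_energy(-3 * p.d, 0.0, p) > inside + 100 * p.kBT

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            EnergyParams(H=-1.0)
        with pytest.raises(ParameterError):
            EnergyParams(F_ATP=-100.0)  # destroys the minima


class TestElasticEnergy:
    def test_zero_at_origin(self, p_ref):
        assert elastic_energy(0.0, p_ref) == 0.0

    def test_tensile_value(self, p_ref):
        assert elastic_energy(1.0, p_ref) == pytest.approx(1.0)  # 0.5*2*1^2

    def test_symmetry_only_when_stiffnesses_equal(self):
        p_sym = EnergyParams(k_minus=2.0)
        p_asym = EnergyParams()
        assert elastic_energy(-1.0, p_sym) == pytest.approx(elastic_energy(1.0, p_sym))
        assert elastic_energy(-1.0, p_asym) == pytest.approx(0.5 * p_asym.k_minus)
        assert elastic_energy(-1.0, p_asym) != elastic_energy(1.0, p_asym)

    @given(x=st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_continuous(self, x):
        p = EnergyParams()
        assert elastic_energy(x, p) >= 0.0


class TestTotalEnergy:
    def test_additivity_at_random_points(self, rng):
        p = EnergyParams()
        xs = rng.uniform(-8, 14, size=100)
        for x in xs:
            assert total_energy(x, 1.3, p) == pytest.approx(
                biochemical_energy(x, 1.3, p) + elastic_energy(x, p))

    def test_sharp_scenarios_rejected(self, p_ref):
        for s in (Scenario.SRI, Scenario.SRII):
            with pytest.raises(UnsupportedScenarioError):
                total_energy(0.0, 0.0, p_ref, s)

    def test_unloaded_with_no_bias_equals_minus_H(self):
        p = EnergyParams(F_ATP=0.0)
        assert total_energy(0.0, 0.0, p) == pytest.approx(-p.H)

    def test_compressed_anchor_raises_first_minimum(self, p_ref):
        """With x0 = -2 nm the pre-power-stroke well sits on the elastic
        parabola and its energy rises relative to the unloaded case."""
        ex_loaded = locate_extrema(-2.0, p_ref)
        ex_free = locate_extrema(-2.0, p_ref.unloaded())
        assert np.all(ex_loaded.energies_minima >= ex_free.energies_minima)
        assert ex_loaded.energies_minima[1] > ex_free.energies_minima[1]


class TestLocateExtrema:
    def test_unloaded_minima_at_exact_positions(self, p_ref):
        ex = locate_extrema(1.7, p_ref.unloaded())
        np.testing.assert_allclose(ex.minima, 1.7 + p_ref.d * np.arange(3),
                                   atol=1e-4)
        assert ex.maxima.size == ex.minima.size - 1

    def test_interleaving_and_barriers_on_grid(self, p_ref):
        for x0 in np.linspace(-12, 10, 12):
            ex = locate_extrema(float(x0), p_ref)
            order = np.ravel([ex.minima[:2], ex.maxima], order="F")
            assert np.all(np.diff(np.r_[order, ex.minima[2]]) > 0)
            for n in range(2):
                assert ex.energies_maxima[n] > ex.energies_minima[n]
                assert ex.energies_maxima[n] > ex.energies_minima[n + 1]

    def test_elastic_annihilation_reported(self, p_ref):
        with pytest.raises(DegenerateLandscapeError) as err:
            locate_extrema(18.0, p_ref)
        assert err.value.well is not None

    def test_wide_minima_barrier_below_sharp_effective_barrier(self):
        """Because the wide-minima landscape relaxes its maximum to a
        position of lower mechanical energy, the forward barrier out of
        S0 stays below the sharp-minima effective barrier (flat-top
        biochemical energy plus the elastic maximum over the step), and
        the gap widens with stretch."""
        p = EnergyParams(k_minus=2.0)
        grid = np.linspace(0.0, p.d, 2001)
        ec_top = float(np.max(biochemical_energy(grid, 0.0, p)))
        ec_min = biochemical_energy(0.0, 0.0, p)
        gaps = []
        for x0 in (-2.0, 0.0, 2.0, 4.0):
            ex = locate_extrema(x0, p)
            sl_barrier = ex.energies_maxima[0] - ex.energies_minima[0]
            span = np.linspace(x0, x0 + p.d, 501)
            sharp_barrier = (ec_top + float(np.max(elastic_energy(span, p)))
                             - (ec_min + elastic_energy(x0, p)))
            assert sl_barrier < sharp_barrier
            gaps.append(sharp_barrier - sl_barrier)
        assert gaps == sorted(gaps)


class TestParabolicShift:
    def test_infinite_sharpness_gives_zero(self):
        assert parabolic_shift(-4.5, 2.0, math.inf) == 0.0

    def test_zero_anchor_gives_zero(self):
        assert parabolic_shift(0.0, 2.0, 48.0) == 0.0

    @pytest.mark.parametrize("x0bar", [-4.5, -2.0, 2.0, 4.5])
    def test_matches_numerically_located_minimum(self, x0bar):
        """The analytic shift reproduces the located minimum within 5%
        of d in the weak-coupling regime k/k_c <= 0.1."""
        p = EnergyParams(k_minus=2.0)  # symmetric so k = 2 either side
        assert 2.0 / p.k_c <= 0.1
        n = round((x0bar + 4.5) / p.d)  # which well has this unloaded position
        x0 = x0bar - n * p.d
        ex = locate_extrema(x0, p)
        predicted = shifted_minimum(x0bar, 2.0, p.k_c)
        assert abs(ex.minima[n] - predicted) <= 0.05 * p.d


class TestEffectiveStiffness:
    def test_printed_value_within_rounding(self):
        kc = effective_stiffness(6.0 * KBT0, 4.5)
        assert kc == pytest.approx(48.0, rel=0.05)

    def test_scalings(self):
        base = effective_stiffness(10.0, 4.5)
        assert effective_stiffness(20.0, 4.5) == pytest.approx(2 * base)
        assert effective_stiffness(10.0, 9.0) == pytest.approx(base / 4)

    def test_invalid(self):
        with pytest.raises(ParameterError):
            effective_stiffness(0.0, 4.5)
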