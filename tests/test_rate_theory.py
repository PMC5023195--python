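import math
from dataclasses import replace

import numpy as np
import pytest

from crossbridge.energy_landscape import (
    EnergyParams,
    ParameterError,
    Scenario,
    elastic_energy,
    locate_extrema,
)
from crossbridge.rate_theory import (
    AttachDetachParams,
    RateTable,
    attach_detach_rates,
    calibrate_unloaded,
    ks_rate,
    q10_scale,
    sri_rate,
    srii_rate,
    stationary_split,
    tabulate_rates,
    _sharp_delta_Et,
)


def sharp_ratio(i, j, x0, p):
    """Sharp-minima detailed-balance factor exp(-beta dE_t) at the
    unshifted minima (independent reference for the rate ratios)."""
    return math.exp(-p.beta * _sharp_delta_Et(i, j, x0, p))


class TestStationarySplit:
    def test_symmetric_unbiased_double_well(self):
        p = EnergyParams(F_ATP=0.0).unloaded()
        pi1, pi2 = stationary_split(0.0, p, wells=(0, 1))
        assert pi1 == pytest.approx(0.5, abs=1e-6)
        assert pi1 + pi2 == pytest.approx(1.0)

    def test_deep_forward_bias(self):
        p = EnergyParams(F_ATP=-20.0).unloaded()
        _, pi2 = stationary_split(0.0, p, wells=(0, 1))
        assert pi2 > 0.999

    def test_detailed_balance_against_ks_rates(self, p_ref):
        for x0 in (-3.0, 0.0, 2.5):
            pi1, pi2 = stationary_split(x0, p_ref, wells=(0, 1))
            ratio = ks_rate(0, 1, x0, p_ref) / ks_rate(1, 0, x0, p_ref)
            assert ratio == pytest.approx(pi2 / pi1, rel=1e-6)

    def test_nonadjacent_rejected(self, p_ref):
        with pytest.raises(ParameterError):
            stationary_split(0.0, p_ref, wells=(0, 2))


class TestKSRate:
    def test_symmetric_landscape_symmetric_rates(self):
        p = EnergyParams(F_ATP=0.0).unloaded()
        assert ks_rate(0, 1, 0.0, p) == pytest.approx(ks_rate(1, 0, 0.0, p),
                                                      rel=1e-6)

    def test_high_barrier_kramers_closed_form(self, p_ref):
        """At barriers >= 8 kBT the quadrature rate matches the harmonic
        Kramers formula sqrt(E''min |E''max|)/(2 pi eta) exp(-beta dE)."""
        p = p_ref.unloaded()
        ex = locate_extrema(0.0, p)
        h = 1e-4
        from crossbridge.energy_landscape import biochemical_energy as E

        for i, j in ((0, 1), (1, 0), (1, 2), (2, 1)):
            top = ex.maxima[min(i, j)]
            dE = ex.energies_maxima[min(i, j)] - ex.energies_minima[i]
            assert dE >= 8.0 * p.kBT
            curv = lambda x: (E(x + h, 0.0, p) - 2 * E(x, 0.0, p)
                              + E(x - h, 0.0, p)) / h**2
            k_harm = (math.sqrt(curv(ex.minima[i]) * abs(curv(top)))
                      / (2 * math.pi * p.eta) * math.exp(-p.beta * dE))
            assert ks_rate(i, j, 0.0, p, ex) == pytest.approx(k_harm, rel=0.20)


class TestSharpScenarios:
    def test_srii_ratio_is_sharp_boltzmann(self, p_fiber, rng):
        calib = calibrate_unloaded(p_fiber)
        for x0 in rng.uniform(-8, 8, size=20):
            r = (srii_rate(0, 1, x0, p_fiber, calib)
                 / srii_rate(1, 0, x0, p_fiber, calib))
            assert r == pytest.approx(sharp_ratio(0, 1, x0, p_fiber), rel=1e-6)

    def test_sri_backward_constant_and_ratio(self, p_fiber):
        calib = calibrate_unloaded(p_fiber)
        assert sri_rate(1, 0, -3.0, p_fiber, calib) == sri_rate(
            1, 0, 3.0, p_fiber, calib)
        for x0 in (-4.0, 1.5):
            r = (sri_rate(0, 1, x0, p_fiber, calib)
                 / sri_rate(1, 0, x0, p_fiber, calib))
            assert r == pytest.approx(sharp_ratio(0, 1, x0, p_fiber), rel=1e-9)

    def test_unloaded_rates_match_all_scenarios(self, p_fiber):
        calib = calibrate_unloaded(p_fiber)
        p0 = p_fiber.unloaded()
        for (i, j), k0 in (((0, 1), calib.k01), ((1, 0), calib.k10),
                           ((1, 2), calib.k12), ((2, 1), calib.k21)):
            assert srii_rate(i, j, 0.0, p0, calib) == pytest.approx(k0, rel=1e-9)
            # SRI keeps the sharp detailed balance exact, so its unloaded
            # forward rates match only to the accuracy with which the
            # quadrature basins are congruent (~1e-4)
            assert sri_rate(i, j, 0.0, p0, calib) == pytest.approx(k0, rel=2e-4)

    def test_calibration_scales_inversely_with_drag(self, p_fiber):
        c1 = calibrate_unloaded(p_fiber)
        c2 = calibrate_unloaded(replace(p_fiber, eta=2 * p_fiber.eta))
        for name in ("k01", "k10", "k12", "k21"):
            assert getattr(c2, name) == pytest.approx(
                getattr(c1, name) / 2.0, rel=1e-6)

    def test_sharp_minima_limit_of_wide_ratio(self):
        """Shrinking the well width (at fixed per-step energy drop)
        drives the wide-minima rate ratio monotonically toward the
        sharp-minima Boltzmann factor."""
        x0 = 1.5
        errs = []
        for scale in (1.0, math.sqrt(10.0), 10.0):  # k_c multiplied by 10x
            p = EnergyParams(d=4.5 / scale,
                             F_ATP=EnergyParams.F_ATP * scale)
            # same elastic span d_ref between compared states: use wells 0->1
            ratio = ks_rate(0, 1, x0, p) / ks_rate(1, 0, x0, p)
            target = sharp_ratio(0, 1, x0, p)
            errs.append(abs(math.log(ratio) - math.log(target)))
        assert errs[0] > errs[1] > errs[2]


class TestAttachDetach:
    def test_compressed_never_attaches(self, ap_default):
        k_ws, k_sd, dis = attach_detach_rates(-1.0, ap_default)
        assert k_ws == 0.0
        assert k_sd == ap_default.g_neg
        assert not dis

    def test_dislodging_threshold(self, ap_default):
        assert attach_detach_rates(16.0, ap_default)[2]
        assert attach_detach_rates(-16.0, ap_default)[2]
        assert not attach_detach_rates(14.9, ap_default)[2]

    def test_linear_ramp_midpoint_and_clamp(self, ap_default):
        k_ws, _, _ = attach_detach_rates(ap_default.x_lim / 2, ap_default)
        assert k_ws == pytest.approx(ap_default.f_max / 2)
        k_ws, _, _ = attach_detach_rates(3 * ap_default.x_lim, ap_default)
        assert k_ws == ap_default.f_max

    def test_q10(self):
        assert q10_scale(5.0, 310.15, 310.15, 2.0) == 5.0
        assert q10_scale(5.0, 320.15, 310.15, 2.0) == pytest.approx(10.0)
        assert q10_scale(5.0, 290.0, 310.15, 1.0) == 5.0

    def test_validation(self):
        with pytest.raises(ParameterError):
            AttachDetachParams(activation=1.5)
        with pytest.raises(ParameterError):
            AttachDetachParams(g_neg=1e-12)


class TestRateTable:
    def test_grid_shape(self, sl_table):
        assert sl_table.x0_grid.size == 101
        assert sl_table.x0_grid[0] == -20.0
        assert sl_table.x0_grid[-1] == 20.0

    def test_all_rates_finite_nonnegative(self, tables_fiber):
        for table in tables_fiber.values():
            for name in ("k01", "k10", "k12", "k21"):
                arr = getattr(table, name)
                assert np.all(np.isfinite(arr))
                assert np.all(arr >= 0)

    def test_node_lookup_equals_direct_computation(self, sl_table, p_fiber):
        idx = np.flatnonzero(~sl_table.degenerate)[25]
        x0 = float(sl_table.x0_grid[idx])
        assert sl_table.lookup("k01", x0) == pytest.approx(
            ks_rate(0, 1, x0, p_fiber), rel=1e-9)

    def test_interpolation_within_envelope(self, sl_table, p_fiber):
        i = 40  # interior, non-degenerate, monotone segment
        xm = 0.5 * (sl_table.x0_grid[i] + sl_table.x0_grid[i + 1])
        val = float(sl_table.lookup("k01", xm))
        lo = min(sl_table.k01[i], sl_table.k01[i + 1])
        hi = max(sl_table.k01[i], sl_table.k01[i + 1])
        assert lo <= val <= hi
        direct = ks_rate(0, 1, xm, p_fiber)
        assert lo * 0.9 <= direct <= hi * 1.1

    def test_degenerate_nodes_flagged_and_filled(self, sl_table):
        assert sl_table.degenerate.any()          # high-stretch wells vanish
        assert not sl_table.degenerate.all()
        assert np.all(np.isfinite(sl_table.k01))

    def test_csv_round_trip_bit_exact(self, sl_table, tmp_path):
        path = tmp_path / "rates.csv"
        sl_table.to_csv(path)
        back = RateTable.from_csv(path)
        for name in ("x0_grid", "k01", "k10", "k12", "k21"):
            np.testing.assert_array_equal(getattr(back, name),
                                          getattr(sl_table, name))
        assert back.scenario is sl_table.scenario
        assert back.temperature == sl_table.temperature

    def test_sl_forward_exceeds_srii_when_stretched(self, tables_fiber):
        sl, srii = tables_fiber[Scenario.SL], tables_fiber[Scenario.SRII]
        for x0 in (1.0, 2.0, 4.0):
            assert sl.lookup("k01", x0) > 1.5 * srii.lookup("k01", x0)
        for x0 in (-6.0, -4.0):  # nearly identical under compression
            assert sl.lookup("k01", x0) == pytest.approx(
                srii.lookup("k01", x0), rel=0.10)
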