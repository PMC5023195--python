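"""Transition rates of the cross-bridge cycle.

Power-stroke rates between the attached wells S0 <-> S1 <-> S2 under the
three sharpness hypotheses:

* **SL** — mean-first-passage (Kramers–Smoluchowski) escape rates
  computed by quadrature over the full wide-minima landscape;
* **SRII** — sharp wells on a flat biochemical potential: the well
  integral collapses to a calibrated constant times the Boltzmann factor
  of the elastic energy at the (unshifted) minimum, the barrier integral
  over the elastic energy is kept;
* **SRI** — Huxley–Simmons: backward rates are strain-independent
  constants, forward rates follow from detailed balance with the
  sharp-minima Boltzmann factor.

The free constants of SRI and SRII are calibrated so that all three
scenarios have identical forward and backward rates for the *unloaded*
elastic element (k = 0) — the landscapes then differ only in how strain
reshapes the rates.

Also here: the strain-gated attachment/detachment rules (attach only
when stretched, fast detachment when compressed, mechanical dislodging
beyond +-15 nm), the D <-> W transitions, and Q10 temperature scaling.
All rates are in 1/ns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .energy_landscape import (
    DegenerateLandscapeError,
    EnergyParams,
    ExtremaSet,
    ParameterError,
    Scenario,
    elastic_energy,
    locate_extrema,
    total_energy,
)

__all__ = [
    "AttachDetachParams",
    "RateTable",
    "UnloadedRates",
    "stationary_split",
    "ks_rate",
    "srii_rate",
    "sri_rate",
    "calibrate_unloaded",
    "attach_detach_rates",
    "q10_scale",
    "tabulate_rates",
]

log = logging.getLogger(__name__)

#: Well/basin integrals are truncated where E_t exceeds the local
#: minimum by this many kBT.
ENERGY_CUTOFF_KBT = 25.0

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)

#: Transitions of the two-step power stroke, keyed (from_well, to_well).
FORWARD = ((0, 1), (1, 2))
BACKWARD = ((1, 0), (2, 1))


@dataclass(frozen=True)
class AttachDetachParams:
    """Strain-gated attachment/detachment and D<->W parameters.

    The shipped numeric defaults for ``f_max``, ``x_lim``, ``g_slope``,
    ``g_neg``, ``k_DW``, ``k_WD`` and ``Q10`` are the package's own
    working values chosen to produce a realistic cycling cross-bridge
    population; all are plain config keys and can be overridden.
    """

    f_max: float = 3.0e-7      # 1/ns   (300 /s) attachment scale W->S0
    x_lim: float = 5.0         # nm     attachment ramp saturation
    g_slope: float = 1.5e-8    # 1/(ns*nm) detachment slope for x > 0 (15 /s/nm)
    g_neg: float = 2.0e-6      # 1/ns   (2000 /s) detachment rate for x < 0
    x_dislodge: float = 15.0   # nm     mechanical dislodging threshold
    k_DW: float = 2.0e-7       # 1/ns   (200 /s) D->W, scaled by activation
    k_WD: float = 1.0e-7       # 1/ns   (100 /s) W->D
    activation: float = 1.0    # dimensionless in [0, 1]
    Q10: float = 2.0
    T_ref: float = 277.15      # K; constants are defined at the fiber condition

    def __post_init__(self) -> None:
        if self.x_lim <= 0:
            raise ParameterError("x_lim must be positive")
        if not (0.0 <= self.activation <= 1.0):
            raise ParameterError("activation must be in [0, 1]")
        if self.Q10 <= 0:
            raise ParameterError("Q10 must be positive")
        if self.g_neg < 10.0 * self.g_slope * self.x_lim:
            raise ParameterError(
                "g_neg must dominate the tensile detachment scale (g_slope*x_lim)"
            )


def q10_scale(rate: float, T: float, T_ref: float, Q10: float) -> float:
    """Scale a rate by ``Q10 ** ((T - T_ref)/10)``."""
    if Q10 <= 0:
        raise ParameterError("Q10 must be positive")
    return rate * Q10 ** ((T - T_ref) / 10.0)


def attach_detach_rates(x: float, ap: AttachDetachParams):
    """H57 strain-gated rates at elastic stretch ``x``.

    Returns ``(k_WS, k_SD, dislodged)``: attachment is non-zero only in
    the stretched configuration (0 < x), rising linearly to ``f_max`` at
    ``x_lim``; detachment rises linearly with x > 0 and is the large
    constant ``g_neg`` for x < 0.  ``dislodged`` flags |x| > 15 nm.

    Rates are *not* Q10-scaled here; apply :func:`q10_scale` at the
    working temperature.
    """
    if x > 0.0:
        k_ws = ap.f_max * min(x / ap.x_lim, 1.0)
        k_sd = ap.g_slope * x
    else:
        k_ws = 0.0
        k_sd = ap.g_neg if x < 0.0 else 0.0
    return k_ws, k_sd, abs(x) > ap.x_dislodge


# -- quadrature helpers -------------------------------------------------------

def _cutoff_bound(x_start: float, x0: float, p: EnergyParams, direction: float,
                  e_ref: float) -> float:
    """March outward from ``x_start`` until E_t - e_ref reaches the cutoff,
    then refine by bisection.  The harmonic walls guarantee termination."""
    target = e_ref + ENERGY_CUTOFF_KBT * p.kBT
    step = 0.05 * p.d
    x = x_start
    for _ in range(10000):
        x_next = x + direction * step
        if total_energy(x_next, x0, p) >= target:
            return brentq(lambda xx: total_energy(xx, x0, p) - target, min(x, x_next),
                          max(x, x_next))
        x = x_next
    raise RuntimeError("energy cutoff not reached; landscape unbounded?")  # pragma: no cover


def _basin_bounds(i: int, ex: ExtremaSet, x0: float, p: EnergyParams):
    """Integration bounds of well i's basin: flanking maxima, or the
    25-kBT cutoff on the outer side of the outer wells."""
    e_min = ex.energies_minima[i]
    if i == 0:
        lo = _cutoff_bound(ex.minima[0], x0, p, -1.0, e_min)
        hi = ex.maxima[0]
    elif i == ex.minima.size - 1:
        lo = ex.maxima[-1]
        hi = _cutoff_bound(ex.minima[-1], x0, p, +1.0, e_min)
    else:
        lo, hi = ex.maxima[i - 1], ex.maxima[i]
    return lo, hi


def _well_integral(i: int, ex: ExtremaSet, x0: float, p: EnergyParams) -> float:
    """int_basin(i) exp(-beta (E_t - E_min_i)) dx."""
    lo, hi = _basin_bounds(i, ex, x0, p)
    e0 = ex.energies_minima[i]
    beta = p.beta
    val, _ = quad(lambda xx: math.exp(-beta * (total_energy(xx, x0, p) - e0)),
                  lo, hi, points=[ex.minima[i]], **_QUAD_KW)
    return val


def stationary_split(x0: float, p: EnergyParams, wells: tuple[int, int] = (0, 1)):
    """Equilibrium probabilities (pi_i, pi_j) of two adjacent wells of the
    SL landscape, from adaptive quadrature of the Boltzmann density
    ``N exp(-beta E_t)`` partitioned at the intervening maximum."""
    i, j = sorted(wells)
    if j - i != 1:
        raise ParameterError("wells must be adjacent")
    ex = locate_extrema(x0, p)
    b = ex.maxima[i]
    e_ref = float(min(ex.energies_minima[i], ex.energies_minima[j]))
    beta = p.beta
    lo = _basin_bounds(i, ex, x0, p)[0]
    hi = _basin_bounds(j, ex, x0, p)[1]

    def dens(xx):
        return math.exp(-beta * (total_energy(xx, x0, p) - e_ref))

    wi, _ = quad(dens, lo, b, points=[ex.minima[i]], **_QUAD_KW)
    wj, _ = quad(dens, b, hi, points=[ex.minima[j]], **_QUAD_KW)
    tot = wi + wj
    if not (np.isfinite(tot) and tot > 0):
        raise RuntimeError(
            f"stationary_split quadrature failed at x0={x0:g}: wi={wi}, wj={wj}"
        )
    return wi / tot, wj / tot


def ks_rate(i: int, j: int, x0: float, p: EnergyParams,
            ex: ExtremaSet | None = None) -> float:
    """Kramers-Smoluchowski escape rate from well i to adjacent well j
    over the SL landscape (1/ns).

    ``rate = [beta * eta * W_i * B_ij]^-1`` with
    ``W_i = int_basin(i) exp(-beta E_t) dx`` and
    ``B_ij = int_{min_i}^{min_j} exp(+beta E_t) dx``; both integrals are
    evaluated with the barrier-top energy factored out for stability.
    Detailed balance with :func:`stationary_split` holds by construction.
    """
    if abs(i - j) != 1:
        raise ParameterError("wells must be adjacent")
    if ex is None:
        ex = locate_extrema(x0, p)
    e_top = ex.energies_maxima[min(i, j)]
    e_min = ex.energies_minima[i]
    beta = p.beta
    wi = _well_integral(i, ex, x0, p)
    a, b = sorted((ex.minima[i], ex.minima[j]))
    x_top = ex.maxima[min(i, j)]
    bij, _ = quad(lambda xx: math.exp(beta * (total_energy(xx, x0, p) - e_top)),
                  a, b, points=[x_top], **_QUAD_KW)
    if not (np.isfinite(wi) and np.isfinite(bij) and wi > 0 and bij > 0):
        raise RuntimeError(
            f"ks_rate quadrature failed at x0={x0:g}: W={wi}, B={bij}"
        )
    return math.exp(-beta * (e_top - e_min)) / (beta * p.eta * wi * bij)


# -- sharp-minima scenarios ---------------------------------------------------

@dataclass(frozen=True)
class UnloadedRates:
    """Unloaded (k = 0) power-stroke rates shared by all scenarios, 1/ns."""

    k01: float
    k10: float
    k12: float
    k21: float

    def forward(self, i: int) -> float:
        return (self.k01, self.k12)[i]

    def backward(self, j: int) -> float:
        return (self.k10, self.k21)[j - 1]


_calib_cache: dict[tuple, UnloadedRates] = {}


def calibrate_unloaded(p: EnergyParams) -> UnloadedRates:
    """KS rates of the unloaded SL landscape; these fix the free
    constants of SRI (constant backward rates) and SRII (k0)."""
    key = (p.H, p.d, p.F_ATP, p.alpha_d, p.eta, p.T)
    if key not in _calib_cache:
        p0 = p.unloaded()
        ex = locate_extrema(0.0, p0)
        _calib_cache[key] = UnloadedRates(
            k01=ks_rate(0, 1, 0.0, p0, ex),
            k10=ks_rate(1, 0, 0.0, p0, ex),
            k12=ks_rate(1, 2, 0.0, p0, ex),
            k21=ks_rate(2, 1, 0.0, p0, ex),
        )
    return _calib_cache[key]


def _sharp_delta_Et(i: int, j: int, x0: float, p: EnergyParams) -> float:
    """E_t(x0 + j d, x0) - E_t(x0 + i d, x0) at the unshifted minima.

    The biochemical part reduces to the per-step ATP drop; the elastic
    part uses the asymmetric stiffness.
    """
    xi, xj = x0 + i * p.d, x0 + j * p.d
    d_ec = p.F_ATP * (xj - xi)
    return d_ec + elastic_energy(xj, p) - elastic_energy(xi, p)


def _elastic_barrier_integral(xa: float, xb: float, p: EnergyParams) -> float:
    """int_xa^xb exp(beta (E_e(x) - E_e_max)) dx over one step, with the
    segment maximum factored out (flat biochemical potential)."""
    beta = p.beta
    cands = [xa, xb] + ([0.0] if xa < 0.0 < xb else [])
    e_max = max(elastic_energy(c, p) for c in cands)
    val, _ = quad(lambda xx: math.exp(beta * (elastic_energy(xx, p) - e_max)),
                  xa, xb, **_QUAD_KW)
    return val, e_max


def srii_rate(i: int, j: int, x0: float, p: EnergyParams,
              calib: UnloadedRates | None = None) -> float:
    """Sharp-minima flat-potential (KS-approximated) rate i -> j (1/ns).

    The sharp well contributes its calibrated unloaded constant times
    ``exp(+beta E_e)`` at the unshifted minimum i; the barrier integral
    of ``exp(+beta E_e)`` between the two minima (analytic for a
    parabola, evaluated here by quadrature) carries the remaining strain
    dependence.  Forward/backward ratios satisfy the sharp-minima
    detailed balance exactly.
    """
    if abs(i - j) != 1:
        raise ParameterError("wells must be adjacent")
    if calib is None:
        calib = calibrate_unloaded(p)
    k0 = calib.forward(min(i, j)) if j > i else calib.backward(max(i, j))
    xi = x0 + i * p.d
    xa, xb = sorted((xi, x0 + j * p.d))
    bint, e_max = _elastic_barrier_integral(xa, xb, p)
    # unloaded: E_e == 0 -> bint = d, e_max = 0 -> rate == k0
    return k0 * math.exp(-p.beta * (e_max - elastic_energy(xi, p))) * p.d / bint


def sri_rate(i: int, j: int, x0: float, p: EnergyParams,
             calib: UnloadedRates | None = None) -> float:
    """Huxley-Simmons rate i -> j (1/ns): backward rates are constant and
    strain-independent; forward rates are ``k_b * exp(-beta dE_t)`` with
    the energy difference taken at the unshifted minima (sharp-minima
    detailed balance)."""
    if abs(i - j) != 1:
        raise ParameterError("wells must be adjacent")
    if calib is None:
        calib = calibrate_unloaded(p)
    if j < i:  # backward
        return calib.backward(i)
    kb = calib.backward(j)
    return kb * math.exp(-p.beta * _sharp_delta_Et(i, j, x0, p))


def scenario_rate(s: Scenario, i: int, j: int, x0: float, p: EnergyParams,
                  calib: UnloadedRates | None = None) -> float:
    """Power-stroke rate i -> j for any scenario (SL via full KS quadrature)."""
    s = Scenario(s)
    if s is Scenario.SL:
        return ks_rate(i, j, x0, p)
    if s is Scenario.SRI:
        return sri_rate(i, j, x0, p, calib)
    return srii_rate(i, j, x0, p, calib)


# -- tabulation ---------------------------------------------------------------

_TRANSITIONS = (("k01", 0, 1), ("k10", 1, 0), ("k12", 1, 2), ("k21", 2, 1))


@dataclass
class RateTable:
    """Power-stroke rates tabulated on a uniform x0 grid (1/ns).

    Lookups between nodes use linear interpolation.  ``degenerate``
    marks grid nodes where the loaded landscape lost a well and the
    rates were extrapolated from valid neighbours.
    """

    x0_grid: np.ndarray
    k01: np.ndarray
    k10: np.ndarray
    k12: np.ndarray
    k21: np.ndarray
    scenario: Scenario
    temperature: float
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.x0_grid, float)
        if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
            raise ParameterError("x0_grid must be strictly increasing")
        for name in ("k01", "k10", "k12", "k21"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != g.shape:
                raise ParameterError(f"{name} shape mismatch")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ParameterError(f"{name} must be finite and non-negative")
        if self.degenerate is None:
            self.degenerate = np.zeros(g.size, dtype=bool)

    def lookup(self, name: str, x0) -> np.ndarray:
        return np.interp(x0, self.x0_grid, getattr(self, name))

    def rates_at(self, x0: float) -> tuple[float, float, float, float]:
        return tuple(float(self.lookup(n, x0)) for n in ("k01", "k10", "k12", "k21"))

    def as_matrix(self) -> np.ndarray:
        """(4, n) array ordered k01, k10, k12, k21 — the kernel-facing view."""
        return np.vstack([self.k01, self.k10, self.k12, self.k21])

    # CSV round-trip: full 17-significant-digit decimal reprs so the
    # double-precision values survive bit-exactly.
    _COLUMNS = ("x0_nm", "k01", "k10", "k12", "k21", "scenario", "temperature_K")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(",".join(self._COLUMNS) + "\n")
            for n in range(self.x0_grid.size):
                fh.write(
                    f"{self.x0_grid[n]:.17g},{self.k01[n]:.17g},{self.k10[n]:.17g},"
                    f"{self.k12[n]:.17g},{self.k21[n]:.17g},"
                    f"{self.scenario.value},{self.temperature:.17g}\n"
                )

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        raw = np.genfromtxt(path, delimiter=",", names=True, dtype=None,
                            encoding="utf-8")
        raw = np.atleast_1d(raw)
        scen = Scenario(str(raw["scenario"][0]))
        return cls(
            x0_grid=np.asarray(raw["x0_nm"], float),
            k01=np.asarray(raw["k01"], float),
            k10=np.asarray(raw["k10"], float),
            k12=np.asarray(raw["k12"], float),
            k21=np.asarray(raw["k21"], float),
            scenario=scen,
            temperature=float(raw["temperature_K"][0]),
        )


def _extrapolate_flagged(values: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Fill flagged nodes by log-linear extrapolation from the two nearest
    valid nodes on the valid side (rates stay positive)."""
    out = values.copy()
    valid = np.flatnonzero(~flagged)
    if valid.size == 0:
        raise RuntimeError("every grid node is degenerate; nothing to extrapolate from")
    logv = np.log(np.maximum(values, 1e-300))
    for idx in np.flatnonzero(flagged):
        below = valid[valid < idx]
        above = valid[valid > idx]
        if above.size >= 2 and (below.size == 0 or above[0] - idx < idx - below[-1]):
            a, b = above[0], above[1]
        elif below.size >= 2:
            a, b = below[-2], below[-1]
        else:
            out[idx] = values[valid[np.argmin(np.abs(valid - idx))]]
            continue
        slope = (logv[b] - logv[a]) / (b - a)
        out[idx] = math.exp(logv[a] + slope * (idx - a))
    return out


_table_cache: dict[tuple, RateTable] = {}


def tabulate_rates(s: Scenario, p: EnergyParams,
                   n_intervals: int = 100, lo: float = -20.0, hi: float = 20.0,
                   use_cache: bool = True) -> RateTable:
    """Tabulate k01, k10, k12, k21 over ``n_intervals`` uniform intervals
    of x0 in [lo, hi] (101 nodes by default).

    SL nodes where the loaded landscape is degenerate are flagged and
    filled by extrapolation from valid neighbours (with a log warning).
    Power-stroke rates carry no Q10 factor: temperature enters through
    beta and the calibration.
    """
    s = Scenario(s)
    key = (s, p.H, p.d, p.F_ATP, p.alpha_d, p.k_plus, p.k_minus, p.eta, p.T,
           n_intervals, lo, hi)
    if use_cache and key in _table_cache:
        return _table_cache[key]

    grid = np.linspace(lo, hi, n_intervals + 1)
    calib = calibrate_unloaded(p)
    cols = {name: np.empty(grid.size) for name, _, _ in _TRANSITIONS}
    flagged = np.zeros(grid.size, dtype=bool)
    for n, x0 in enumerate(grid):
        if s is Scenario.SL:
            try:
                ex = locate_extrema(float(x0), p)
                for name, i, j in _TRANSITIONS:
                    cols[name][n] = ks_rate(i, j, float(x0), p, ex)
            except DegenerateLandscapeError:
                flagged[n] = True
                for name, _, _ in _TRANSITIONS:
                    cols[name][n] = np.nan
        else:
            for name, i, j in _TRANSITIONS:
                cols[name][n] = scenario_rate(s, i, j, float(x0), p, calib)
    if flagged.any():
        log.warning(
            "%s: %d/%d grid nodes degenerate (x0 in [%g, %g]); rates extrapolated",
            s.value, int(flagged.sum()), grid.size,
            grid[flagged].min(), grid[flagged].max(),
        )
        for name, _, _ in _TRANSITIONS:
            cols[name] = _extrapolate_flagged(cols[name], flagged)
    table = RateTable(x0_grid=grid, scenario=s, temperature=p.T,
                      degenerate=flagged, **cols)
    if use_cache:
        _table_cache[key] = table
    return table
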