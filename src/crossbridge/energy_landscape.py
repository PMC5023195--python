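"""Multi-well energy landscape of the actomyosin complex.

The attached myosin head is reduced to a single mechanical coordinate
``x`` (nm), the stretch of the myosin elastic element.  Its potential
energy is the sum of two parts:

* a *biochemical* energy ``E_c(x, x0)``: a sinusoid of amplitude ``H``
  and period ``d`` (the power-stroke step) tilted by a linear ATP bias
  ``F_ATP * (x - x0)``, producing three minima — the pre-power-stroke
  state S0 at ``x0`` and the post-power-stroke states S1, S2 at
  ``x0 + d`` and ``x0 + 2 d`` — with strictly decreasing energies;
* an *elastic* energy ``E_e(x)``: an asymmetric quadratic with tensile
  stiffness ``k_plus`` for ``x > 0`` and compressive stiffness
  ``k_minus`` for ``x < 0``.

Three scenarios share the same minima positions and energy drops and
differ only in the sharpness of the biochemical wells: SL keeps the
finite-curvature sinusoid above, while SRI and SRII treat the wells as
infinitely sharp (their physics lives entirely in the rate expressions,
see :mod:`crossbridge.rate_theory`).

Units are fixed project-wide: pN, nm, ns, K; energies in pN*nm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "KB",
    "T0_REF",
    "KBT0",
    "ParameterError",
    "UnsupportedScenarioError",
    "DegenerateLandscapeError",
    "Scenario",
    "EnergyParams",
    "ExtremaSet",
    "biochemical_energy",
    "biochemical_force",
    "elastic_energy",
    "elastic_force",
    "total_energy",
    "total_force",
    "total_stiffness",
    "locate_extrema",
    "parabolic_shift",
    "effective_stiffness",
]

#: Boltzmann constant in pN*nm/K.
KB = 0.0138065
#: Reference temperature (K) at which the barrier amplitude is defined.
T0_REF = 310.15
#: Thermal energy at the reference temperature, pN*nm.
KBT0 = KB * T0_REF

#: Wall stiffness multiplier: beyond half a period past each outer
#: minimum the sinusoid is continued C1-smoothly by a steep harmonic
#: wall of stiffness WALL_FACTOR * k_c so trajectories cannot leave the
#: modeled landscape.
WALL_FACTOR = 100.0

#: A well is declared degenerate when the barrier protecting it falls
#: below this multiple of kBT.
DEGENERACY_BARRIER_KBT = 0.1


class ParameterError(ValueError):
    """Invalid physical parameters."""


class UnsupportedScenarioError(ValueError):
    """Operation asked for a scenario it is not defined for."""


class DegenerateLandscapeError(RuntimeError):
    """An energy well was annihilated (or nearly so) by the elastic load."""

    def __init__(self, message: str, well: int | None = None):
        super().__init__(message)
        self.well = well


class Scenario(str, enum.Enum):
    """The three biochemical-energy shapes under comparison."""

    SL = "SL"    #: wide (finite-curvature) minima
    SRI = "SRI"  #: sharp minima, constant backward rates (Huxley-Simmons)
    SRII = "SRII"  #: sharp minima, flat-potential Kramers-Smoluchowski rates

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def effective_stiffness(H: float, d: float) -> float:
    """Stiffness ``k_c = H (2 pi / d)^2`` of the parabolic approximation
    to a biochemical-energy minimum (pN/nm)."""
    if H <= 0 or d <= 0:
        raise ParameterError("H and d must be positive")
    return H * (2.0 * math.pi / d) ** 2


def _alpha_from_stationarity(H: float, d: float, F_ATP: float) -> float:
    """Phase constant placing the first E_c minimum exactly at x = x0.

    Solves E_c'(x0, x0) = 0 with E_c'' > 0:
    cos(alpha) = -F_ATP d / (2 pi H), sin(alpha) < 0.
    """
    c = -F_ATP * d / (2.0 * math.pi * H)
    if abs(c) >= 1.0:
        raise ParameterError(
            "|F_ATP| >= 2*pi*H/d: the ATP bias destroys the sinusoidal minima"
        )
    return 2.0 * math.pi - math.acos(c)


@dataclass(frozen=True)
class EnergyParams:
    """All landscape and elastic constants.

    Defaults: barrier amplitude ``H = 6 kB T0`` (T0 = 310.15 K), step
    ``d = 4.5`` nm, ATP bias giving a total S0->S2 drop of ``16 kB T0``
    split evenly over the two steps, tensile stiffness 2 pN/nm,
    compressive stiffness 0.2 pN/nm, drag 70 pN*ns/nm.
    """

    H: float = 6.0 * KBT0          # pN*nm
    d: float = 4.5                 # nm
    n_minima: int = 3
    F_ATP: float = -8.0 * KBT0 / 4.5  # pN (negative: bias toward larger x)
    alpha_d: float | None = None   # rad; derived from stationarity if None
    k_plus: float = 2.0            # pN/nm
    k_minus: float = 0.2           # pN/nm
    eta: float = 70.0              # pN*ns/nm
    T: float = T0_REF              # K

    def __post_init__(self) -> None:
        if self.H <= 0 or self.d <= 0 or self.eta <= 0 or self.T <= 0:
            raise ParameterError("H, d, eta, T must all be positive")
        if self.k_plus < 0 or self.k_minus < 0:
            raise ParameterError("stiffnesses must be non-negative")
        if self.n_minima != 3:
            raise ParameterError("the model is defined for exactly 3 minima")
        if abs(self.F_ATP) >= self.H * 2.0 * math.pi / self.d:
            raise ParameterError(
                "|F_ATP| must be below H*(2*pi/d) for three distinct minima"
            )
        if self.alpha_d is None:
            object.__setattr__(
                self, "alpha_d", _alpha_from_stationarity(self.H, self.d, self.F_ATP)
            )

    @property
    def kBT(self) -> float:
        """Thermal energy at the working temperature, pN*nm."""
        return KB * self.T

    @property
    def beta(self) -> float:
        """Inverse thermal energy, 1/(pN*nm)."""
        return 1.0 / self.kBT

    @property
    def k_c(self) -> float:
        """Parabolic stiffness of one biochemical well, pN/nm."""
        return effective_stiffness(self.H, self.d)

    def minima_unshifted(self, x0: float = 0.0) -> np.ndarray:
        """Unloaded minima positions ``x0 + n d``, n = 0, 1, 2."""
        return x0 + self.d * np.arange(self.n_minima)

    def with_temperature(self, T: float) -> "EnergyParams":
        return replace(self, T=T)

    def unloaded(self) -> "EnergyParams":
        """Same landscape with the elastic element removed (k = 0)."""
        return replace(self, k_plus=0.0, k_minus=0.0)


# -- energies -----------------------------------------------------------------

def _central_extent(p: EnergyParams) -> tuple[float, float]:
    """Support of the sinusoidal part in the well-frame u = x - x0:
    half a period beyond each outer minimum."""
    return -0.5 * p.d, (p.n_minima - 1) * p.d + 0.5 * p.d


def biochemical_energy(x, x0, p: EnergyParams):
    """E_c(x, x0) = H sin(2 pi (x - x0)/d + alpha_d) + F_ATP (x - x0).

    Inside the central region (half a period beyond each outer minimum);
    outside, a C1 harmonic wall of stiffness ``WALL_FACTOR * k_c``.
    """
    u = np.asarray(x, dtype=float) - x0
    lo, hi = _central_extent(p)
    w = 2.0 * math.pi / p.d
    kw = WALL_FACTOR * p.k_c

    def _sin(uu):
        return p.H * np.sin(w * uu + p.alpha_d) + p.F_ATP * uu

    def _dsin(uu):
        return p.H * w * np.cos(w * uu + p.alpha_d) + p.F_ATP

    e = _sin(np.clip(u, lo, hi))
    below = u < lo
    above = u > hi
    if np.any(below):
        du = u - lo
        e = np.where(below, _sin(lo) + _dsin(lo) * du + 0.5 * kw * du**2, e)
    if np.any(above):
        du = u - hi
        e = np.where(above, _sin(hi) + _dsin(hi) * du + 0.5 * kw * du**2, e)
    return e if e.ndim else float(e)


def biochemical_force(x, x0, p: EnergyParams):
    """-dE_c/dx (pN)."""
    u = np.asarray(x, dtype=float) - x0
    lo, hi = _central_extent(p)
    w = 2.0 * math.pi / p.d
    kw = WALL_FACTOR * p.k_c

    def _dsin(uu):
        return p.H * w * np.cos(w * uu + p.alpha_d) + p.F_ATP

    g = _dsin(np.clip(u, lo, hi))
    g = np.where(u < lo, _dsin(lo) + kw * (u - lo), g)
    g = np.where(u > hi, _dsin(hi) + kw * (u - hi), g)
    out = -g
    return out if out.ndim else float(out)


def elastic_energy(x, p: EnergyParams):
    """Asymmetric elastic energy: (1/2) k+ x^2 for x >= 0, (1/2) k- x^2 for x < 0."""
    xa = np.asarray(x, dtype=float)
    k = np.where(xa >= 0.0, p.k_plus, p.k_minus)
    e = 0.5 * k * xa**2
    return e if e.ndim else float(e)


def elastic_force(x, p: EnergyParams):
    """-dE_e/dx (pN)."""
    xa = np.asarray(x, dtype=float)
    k = np.where(xa >= 0.0, p.k_plus, p.k_minus)
    out = -k * xa
    return out if out.ndim else float(out)


def total_energy(x, x0, p: EnergyParams, s: Scenario = Scenario.SL):
    """E_t(x, x0) = E_c(x, x0) + E_e(x).

    Only defined for the wide-minima scenario; the sharp scenarios have
    no finite landscape to evaluate.
    """
    if Scenario(s) is not Scenario.SL:
        raise UnsupportedScenarioError(
            f"total_energy is only defined for SL, got {Scenario(s)}"
        )
    return biochemical_energy(x, x0, p) + elastic_energy(x, p)


def total_force(x, x0, p: EnergyParams):
    """-dE_t/dx (pN) for the SL landscape."""
    return biochemical_force(x, x0, p) + elastic_force(x, p)


def total_stiffness(x, x0, p: EnergyParams):
    """d^2 E_t / dx^2 (pN/nm) for the SL landscape."""
    u = np.asarray(x, dtype=float) - x0
    lo, hi = _central_extent(p)
    w = 2.0 * math.pi / p.d
    kcurv = -p.H * w * w * np.sin(w * np.clip(u, lo, hi) + p.alpha_d)
    kcurv = np.where((u < lo) | (u > hi), WALL_FACTOR * p.k_c, kcurv)
    xa = np.asarray(x, dtype=float)
    ke = np.where(xa >= 0.0, p.k_plus, p.k_minus)
    out = kcurv + ke
    return out if out.ndim else float(out)


# -- extrema ------------------------------------------------------------------

@dataclass(frozen=True)
class ExtremaSet:
    """Stationary points of E_t for one value of x0.

    ``minima`` and ``maxima`` strictly interleave:
    min[0] < max[0] < min[1] < max[1] < min[2].
    """

    x0: float
    minima: np.ndarray          # positions, nm (length 3)
    maxima: np.ndarray          # positions, nm (length 2)
    energies_minima: np.ndarray  # pN*nm
    energies_maxima: np.ndarray  # pN*nm

    def barrier(self, i: int, j: int) -> float:
        """Energy barrier (pN*nm) seen from well i crossing toward adjacent well j."""
        if abs(i - j) != 1:
            raise ValueError("wells must be adjacent")
        return float(self.energies_maxima[min(i, j)] - self.energies_minima[i])


_XATOL = 1e-6  # nm; comfortably tighter than the 1e-4 nm contract


def locate_extrema(x0: float, p: EnergyParams) -> ExtremaSet:
    """Numerically locate the three minima and two maxima of E_t(., x0).

    Each extremum is bracketed within its own sinusoid period.  Raises
    :class:`DegenerateLandscapeError` naming the vanished well when the
    elastic load annihilates a minimum or pushes a protecting barrier
    below ``DEGENERACY_BARRIER_KBT * kBT``.
    """
    d = p.d
    minima = []
    for n in range(p.n_minima):
        a, b = x0 + n * d - 0.5 * d, x0 + n * d + 0.5 * d
        res = minimize_scalar(
            lambda xx: total_energy(xx, x0, p),
            bounds=(a, b), method="bounded",
            options={"xatol": _XATOL},
        )
        xm = float(res.x)
        if min(xm - a, b - xm) < 50 * _XATOL or abs(total_force(xm, x0, p)) > 1e-3 * (
            1.0 + abs(p.F_ATP)
        ):
            raise DegenerateLandscapeError(
                f"well S{n} annihilated by the elastic load at x0={x0:g} nm", well=n
            )
        minima.append(xm)
    maxima = []
    for n in range(p.n_minima - 1):
        a, b = minima[n], minima[n + 1]
        res = minimize_scalar(
            lambda xx: -total_energy(xx, x0, p),
            bounds=(a, b), method="bounded",
            options={"xatol": _XATOL},
        )
        maxima.append(float(res.x))
    e_min = np.array([total_energy(m, x0, p) for m in minima])
    e_max = np.array([total_energy(m, x0, p) for m in maxima])
    for n in range(p.n_minima - 1):
        lo_barrier = min(e_max[n] - e_min[n], e_max[n] - e_min[n + 1])
        if lo_barrier < DEGENERACY_BARRIER_KBT * p.kBT:
            well = n if e_min[n] > e_min[n + 1] else n + 1
            raise DegenerateLandscapeError(
                f"barrier between S{n} and S{n+1} below "
                f"{DEGENERACY_BARRIER_KBT} kBT at x0={x0:g} nm (well S{well})",
                well=well,
            )
    return ExtremaSet(
        x0=float(x0),
        minima=np.array(minima),
        maxima=np.array(maxima),
        energies_minima=e_min,
        energies_maxima=e_max,
    )


def parabolic_shift(x0bar: float, k: float, k_c: float) -> float:
    """Analytic shift of a minimum under elastic load.

    With the well approximated by a parabola of stiffness ``k_c``
    centred on the unloaded position ``x0bar = x0 + n d``, superposing
    the elastic parabola of stiffness ``k`` moves the minimum toward the
    origin by ``delta_d = (1 - 1/(k/k_c + 1)) * x0bar``.  ``k_c`` may be
    infinite (sharp minima), giving zero shift.
    """
    if k < 0:
        raise ParameterError("k must be non-negative")
    if not (k_c > 0):
        raise ParameterError("k_c must be positive (possibly inf)")
    if math.isinf(k_c):
        return 0.0
    q = k / k_c
    return (1.0 - 1.0 / (q + 1.0)) * x0bar


def shifted_minimum(x0bar: float, k: float, k_c: float) -> float:
    """Loaded minimum position ``x0bar - parabolic_shift`` = x0bar/(1 + k/k_c)."""
    return x0bar - parabolic_shift(x0bar, k, k_c)
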