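"""Overdamped Langevin dynamics of the wide-minima (SL) scenario.

Each myosin head is a material point in a viscous medium:

    eta dx/dt = -omega(t) E_c'(x, x0) - E_e'(x) + sqrt(eta kBT) Gamma(t)

with white noise <Gamma> = 0, <Gamma(t1) Gamma(t2)> = 2 delta(t1 - t2),
and omega = 1 only while strongly attached.  Attachment/detachment and
D <-> W chemistry are operator-split from the diffusion at every step.

The integrator is the Leimkuhler–Matthews (averaged-noise) scheme,
x_{n+1} = x_n + dt F/eta + sigma (xi_n + xi_{n+1})/2, whose stationary
statistics are exact for harmonic wells at any stable step size; in the
steep wall regions where dt E_t''/eta is large the drift is applied
through a linearized implicit update instead, so trajectories cannot
blow up.  Default dt = 0.5 ns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .energy_landscape import (
    DegenerateLandscapeError,
    EnergyParams,
    ParameterError,
    Scenario,
    _central_extent,
    locate_extrema,
    WALL_FACTOR,
)
from .rate_theory import AttachDetachParams, q10_scale

__all__ = [
    "ChemState",
    "EnsembleState",
    "Trajectory",
    "initial_ensemble",
    "langevin_step",
    "chemistry_step",
    "classify_well",
    "run_single_molecule",
    "DT_DEFAULT",
]

DT_DEFAULT = 0.5  # ns
#: Hard cap on any single-step transition probability.
P_STEP_CAP = 0.1

WELL_LABELS = ("S0", "S1", "S2")


class ChemState(enum.IntEnum):
    D = 0
    W = 1
    S = 2


@dataclass
class EnsembleState:
    """All motors plus the shared filament sliding coordinate.

    Arrays are per motor: ``x`` elastic stretch (nm), ``chem`` 0/1/2 for
    D/W/S, ``x0`` pre-power-stroke anchor (nm, valid while attached),
    ``t_attach`` (ns), ``well`` current attached well index (-1 when
    detached), ``xi_prev`` the integrator's carried noise variate.
    """

    x: np.ndarray
    chem: np.ndarray
    x0: np.ndarray
    t_attach: np.ndarray
    well: np.ndarray
    xi_prev: np.ndarray
    z: float = 0.0
    t: float = 0.0
    counters: np.ndarray = field(
        default_factory=lambda: np.zeros(K.N_COUNTERS, dtype=np.int64))
    pm_attach: np.ndarray | None = None
    pm_back: np.ndarray | None = None
    _seed_seq: np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        if self.pm_attach is None:
            self.pm_attach = np.zeros(n, dtype=np.int64)
        if self.pm_back is None:
            self.pm_back = np.zeros(n, dtype=np.int64)

    @property
    def n_motors(self) -> int:
        return self.x.shape[0]

    @property
    def n_attached(self) -> int:
        return int(np.sum(self.chem == ChemState.S))

    def next_seed(self) -> int:
        """Fresh 32-bit kernel seed, deterministically derived."""
        if self._seed_seq is None:
            self._seed_seq = np.random.SeedSequence(0)
        (child,) = self._seed_seq.spawn(1)
        return int(child.generate_state(1, dtype=np.uint32)[0])


def initial_ensemble(n: int, p: EnergyParams, seed: int) -> EnsembleState:
    """All motors detached (D), positions drawn from the bare-elastic
    Boltzmann distribution at the working temperature."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sp = np.sqrt(p.kBT / p.k_plus) if p.k_plus > 0 else 0.0
    sm = np.sqrt(p.kBT / p.k_minus) if p.k_minus > 0 else 0.0
    side = rng.random(n) < (sp / (sp + sm) if sp + sm > 0 else 1.0)
    x = np.where(side, np.abs(rng.standard_normal(n)) * sp,
                 -np.abs(rng.standard_normal(n)) * sm)
    return EnsembleState(
        x=x.astype(float),
        chem=np.zeros(n, dtype=np.int64),
        x0=np.zeros(n),
        t_attach=np.zeros(n),
        well=np.full(n, -1, dtype=np.int64),
        xi_prev=rng.standard_normal(n),
        _seed_seq=ss,
    )


# -- well boundaries ----------------------------------------------------------

_boundary_cache: dict[tuple, tuple] = {}


def well_boundary_tables(p: EnergyParams, lo: float = -30.0, hi: float = 30.0,
                         step: float = 0.25):
    """Tabulated positions (relative to x0) of the two E_t maxima that
    separate S0|S1 and S1|S2, on a uniform x0 grid for kernel lookup.

    Where the loaded landscape is degenerate the boundaries fall back to
    the midpoints between the unshifted minima (nearest-minimum
    classification)."""
    key = (p.H, p.d, p.F_ATP, p.alpha_d, p.k_plus, p.k_minus, p.T, lo, hi, step)
    if key in _boundary_cache:
        return _boundary_cache[key]
    grid = np.arange(lo, hi + 0.5 * step, step)
    b1 = np.empty(grid.size)
    b2 = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        try:
            ex = locate_extrema(float(x0), p)
            b1[i] = ex.maxima[0] - x0
            b2[i] = ex.maxima[1] - x0
        except DegenerateLandscapeError:
            b1[i] = 0.5 * p.d
            b2[i] = 1.5 * p.d
    out = (float(grid[0]), float(step), b1, b2)
    _boundary_cache[key] = out
    return out


def classify_well(x: float, x0: float, p: EnergyParams) -> str:
    """Label the attached well containing ``x``: the E_t maxima are the
    boundaries, a position exactly on a maximum belongs to the forward
    well.  Falls back to nearest-minimum classification when the loaded
    landscape is degenerate."""
    try:
        ex = locate_extrema(x0, p)
        b1, b2 = ex.maxima
    except DegenerateLandscapeError:
        b1, b2 = x0 + 0.5 * p.d, x0 + 1.5 * p.d
    return WELL_LABELS[0 if x < b1 else (1 if x < b2 else 2)]


# -- effective chemistry ------------------------------------------------------

def effective_chem_rates(ap: AttachDetachParams, T: float) -> tuple:
    """Q10- and activation-scaled chemistry rates at temperature T (1/ns)."""
    q = ap.Q10 ** ((T - ap.T_ref) / 10.0)
    return (ap.k_DW * q * ap.activation, ap.k_WD * q, ap.f_max * q, ap.x_lim,
            ap.g_slope * q, ap.g_neg * q, ap.x_dislodge)


def _check_dt(dt: float, ap: AttachDetachParams, T: float) -> None:
    if dt <= 0:
        raise ParameterError("dt must be positive")
    kdw, kwd, fmax, _, gslope, gneg, xdis = effective_chem_rates(ap, T)
    rmax = max(kdw, kwd + fmax, gslope * xdis + gneg)
    if rmax * dt >= P_STEP_CAP:
        raise ParameterError(
            f"dt={dt} ns gives per-step transition probability "
            f"{rmax * dt:.3g} >= {P_STEP_CAP}"
        )


def _landscape_args(p: EnergyParams):
    ulo, uhi = _central_extent(p)
    return (p.H, p.d, p.alpha_d, p.F_ATP, p.k_plus, p.k_minus, p.eta, p.kBT,
            WALL_FACTOR * p.k_c, ulo, uhi)


_NO_SAMP = (0, np.empty(0), np.empty(0), np.empty(0),
            np.empty((0, 5), dtype=np.int64), np.zeros(1, dtype=np.int64))
_NO_REC = (0, np.empty(0), np.empty(0, dtype=np.int64),
           np.empty(0, dtype=np.int64), np.zeros(1, dtype=np.int64))


#: Per-step bound on the equilibrium slide of z; only binds when the
#: attached set collapses under load (see sarcomere module).
DZ_CAP = 5.0  # nm


#: Noise is pre-drawn (numpy ziggurat) in blocks of at most this many
#: variates and streamed to the kernel.
_NOISE_BLOCK = 4_000_000


def _advance(e: EnsembleState, n_steps: int, dt: float, p: EnergyParams,
             ap: AttachDetachParams, do_diff: bool, do_chem: bool,
             z_mode: int = 0, F_ext: float = 0.0,
             sample=None, record=None, chem_every: int = 8) -> None:
    bg0, bdg, b1g, b2g = well_boundary_tables(p)
    zt = np.array([e.z, e.t])
    n = e.n_motors
    block = max(1, _NOISE_BLOCK // max(n, 1))
    done = 0
    while done < n_steps:
        b = min(block, n_steps - done)
        if do_diff:
            rng = np.random.default_rng(e.next_seed())
            noise = rng.standard_normal((b, n))
        else:
            noise = np.zeros((1, n))
        K.langevin_run(
            e.next_seed(),
            e.x, e.chem, e.x0, e.t_attach, e.xi_prev, e.well, zt,
            noise, done,
            b, dt, 1 if do_diff else 0, 1 if do_chem else 0, chem_every,
            *_landscape_args(p),
            *effective_chem_rates(ap, p.T),
            z_mode, F_ext, DZ_CAP,
            bg0, bdg, b1g, b2g,
            *(sample if sample is not None else _NO_SAMP),
            e.counters, e.pm_attach, e.pm_back,
            *(record if record is not None else _NO_REC),
        )
        done += b
    e.z, e.t = float(zt[0]), float(zt[1])


def langevin_step(e: EnsembleState, dt: float, p: EnergyParams) -> EnsembleState:
    """Advance every motor one diffusion step (no chemistry).

    Attached motors feel the full landscape force, detached ones only
    the elastic restoring force; both get the same thermal noise with
    per-step variance ``2 kBT dt / eta``.  Mutates and returns ``e``.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    _advance(e, 1, dt, p, AttachDetachParams(), do_diff=True, do_chem=False,
             chem_every=1)
    return e


def chemistry_step(e: EnsembleState, dt: float, ap: AttachDetachParams,
                   p: EnergyParams) -> EnsembleState:
    """Sample D<->W, W->S0 (anchor set to the current position) and S->D
    transitions over one step; apply mechanical dislodging.  Mutates and
    returns ``e``."""
    _check_dt(dt, ap, p.T)
    _advance(e, 1, dt, p, ap, do_diff=False, do_chem=True, chem_every=1)
    return e


# -- single-molecule protocol -------------------------------------------------

@dataclass
class Trajectory:
    """Decimated single-motor time series with event tallies."""

    t: np.ndarray
    x: np.ndarray
    chem_state: np.ndarray   # 0/1/2 = D/W/S
    well: np.ndarray         # -1 detached, else 0/1/2
    counters: np.ndarray     # attach, detach, dislodge, fwd, back, noatt

    @property
    def n_attachments(self) -> int:
        return int(self.counters[K.C_ATTACH])

    @property
    def n_backward(self) -> int:
        return int(self.counters[K.C_BACK])

    @property
    def n_forward(self) -> int:
        return int(self.counters[K.C_FWD])


def run_single_molecule(duration: float, seed: int, p: EnergyParams,
                        ap: AttachDetachParams, dt: float = DT_DEFAULT,
                        decimation: int = 100,
                        x0_clamp: float | None = None) -> Trajectory:
    """Isometric (z = 0) single-motor run of ``duration`` ns.

    With ``x0_clamp`` set, the motor is started attached with its anchor
    clamped there and chemistry is switched off — the pure-diffusion
    mode used to probe Boltzmann stationarity of the integrator.
    Bitwise reproducible for a fixed seed.
    """
    _check_dt(dt, ap, p.T)
    e = initial_ensemble(1, p, seed)
    do_chem = True
    if x0_clamp is not None:
        e.chem[0] = ChemState.S
        e.x0[0] = x0_clamp
        e.x[0] = x0_clamp
        e.well[0] = 0
        do_chem = False
    n_steps = int(round(duration / dt))
    n_rec = n_steps // decimation
    rec = (decimation, np.empty(n_rec), np.empty(n_rec, dtype=np.int64),
           np.empty(n_rec, dtype=np.int64), np.zeros(1, dtype=np.int64))
    _advance(e, n_steps, dt, p, ap, do_diff=True, do_chem=do_chem, record=rec,
             chem_every=2)
    m = int(rec[4][0])
    t = e.t - dt * decimation * (np.arange(m)[::-1])
    return Trajectory(t=t, x=rec[1][:m], chem_state=rec[2][:m], well=rec[3][:m],
                      counters=e.counters.copy())
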