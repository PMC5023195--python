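"""Jump-process approximation of the cross-bridge cycle.

Motors hop on {D, W, S0, S1, S2} with power-stroke rates interpolated
from a pre-tabulated :class:`~crossbridge.rate_theory.RateTable` at the
motor's anchor x0, while the within-state position is redrawn every step
from the local Boltzmann distribution — a Gaussian of variance
``kBT/(k_c + k)`` around the elastically shifted minimum for the
wide-minima scenario, a point mass at the unshifted minimum for the
sharp scenarios.  Strain-dependent attachment and detachment are
evaluated at the *sampled* position, so they see thermal fluctuations
of the elastic stretch; that is the purpose of the positional draw.

Time stepping is fixed-step (not Gillespie) because rates move with the
filament coordinate z; the step adapts so that no motor's total exit
probability exceeds 0.1 per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .energy_landscape import (
    EnergyParams,
    ParameterError,
    Scenario,
    locate_extrema,
    shifted_minimum,
    total_energy,
)
from .langevin_engine import DZ_CAP, effective_chem_rates
from .rate_theory import AttachDetachParams, RateTable, tabulate_rates

__all__ = [
    "STATE_NAMES",
    "DIRECTION_NAMES",
    "JumpEvent",
    "EventLog",
    "MarkovEnsemble",
    "initial_markov_ensemble",
    "markov_step",
    "advance_markov",
    "sample_well_position",
    "rejection_sample_well",
    "compare_engines",
]

STATE_NAMES = ("D", "W", "S0", "S1", "S2")
DIRECTION_NAMES = ("attach", "detach", "dislodge", "forward", "backward")

P_STEP_CAP = 0.1
DT_MAX_DEFAULT = 2000.0  # ns


@dataclass(frozen=True)
class JumpEvent:
    """One logged transition of one motor."""

    t: float
    motor_id: int
    from_state: str
    to_state: str
    direction: str


@dataclass
class EventLog:
    """Column-oriented log of jump events (kernel-facing)."""

    t: np.ndarray
    motor_id: np.ndarray
    from_state: np.ndarray  # int codes into STATE_NAMES
    to_state: np.ndarray
    direction: np.ndarray   # int codes into DIRECTION_NAMES
    truncated: bool = False

    def __len__(self) -> int:
        return self.t.shape[0]

    def __iter__(self):
        for i in range(len(self)):
            yield JumpEvent(
                t=float(self.t[i]),
                motor_id=int(self.motor_id[i]),
                from_state=STATE_NAMES[int(self.from_state[i])],
                to_state=STATE_NAMES[int(self.to_state[i])],
                direction=DIRECTION_NAMES[int(self.direction[i])],
            )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_ns": self.t,
            "motor_id": self.motor_id,
            "from": [STATE_NAMES[i] for i in self.from_state],
            "to": [STATE_NAMES[i] for i in self.to_state],
            "direction": [DIRECTION_NAMES[i] for i in self.direction],
        })


@dataclass
class MarkovEnsemble:
    """Jump-process ensemble: chem codes 0..4 = D, W, S0, S1, S2."""

    chem: np.ndarray
    x0: np.ndarray
    xs: np.ndarray           # last sampled positions
    t_attach: np.ndarray
    scenario: Scenario
    z: float = 0.0
    t: float = 0.0
    counters: np.ndarray = field(
        default_factory=lambda: np.zeros(K.N_COUNTERS, dtype=np.int64))
    pm_attach: np.ndarray | None = None
    pm_back: np.ndarray | None = None
    _seed_seq: np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        n = self.chem.shape[0]
        if self.pm_attach is None:
            self.pm_attach = np.zeros(n, dtype=np.int64)
        if self.pm_back is None:
            self.pm_back = np.zeros(n, dtype=np.int64)

    @property
    def n_motors(self) -> int:
        return self.chem.shape[0]

    @property
    def n_attached(self) -> int:
        return int(np.sum(self.chem >= 2))

    def next_seed(self) -> int:
        if self._seed_seq is None:
            self._seed_seq = np.random.SeedSequence(0)
        (child,) = self._seed_seq.spawn(1)
        return int(child.generate_state(1, dtype=np.uint32)[0])


def initial_markov_ensemble(n: int, scenario: Scenario, p: EnergyParams,
                            seed: int) -> MarkovEnsemble:
    """All motors detached, positions from the bare-elastic Boltzmann law."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sp = np.sqrt(p.kBT / p.k_plus) if p.k_plus > 0 else 0.0
    sm = np.sqrt(p.kBT / p.k_minus) if p.k_minus > 0 else 0.0
    side = rng.random(n) < (sp / (sp + sm) if sp + sm > 0 else 1.0)
    xs = np.where(side, np.abs(rng.standard_normal(n)) * sp,
                  -np.abs(rng.standard_normal(n)) * sm)
    return MarkovEnsemble(
        chem=np.zeros(n, dtype=np.int64),
        x0=np.zeros(n),
        xs=xs.astype(float),
        t_attach=np.zeros(n),
        scenario=Scenario(scenario),
        _seed_seq=ss,
    )


# -- within-well position sampling -------------------------------------------

def sample_well_position(well: int, x0: float, p: EnergyParams,
                         rng: np.random.Generator,
                         scenario: Scenario = Scenario.SL) -> float:
    """Draw the head position inside attached well ``well`` (0, 1, 2).

    SL: normal approximation to the local Boltzmann density — mean at
    the elastically shifted minimum, standard deviation
    ``sqrt(kBT/(k_c + k))``.  Sharp scenarios: degenerate at the
    unshifted minimum ``x0 + n d``.
    """
    if well not in (0, 1, 2):
        raise ParameterError("well must be 0, 1 or 2")
    m0 = x0 + well * p.d
    if Scenario(scenario) is not Scenario.SL:
        return m0
    k = p.k_plus if m0 >= 0 else p.k_minus
    mean = shifted_minimum(m0, k, p.k_c)
    return float(mean + rng.standard_normal() * math.sqrt(p.kBT / (p.k_c + k)))


def sample_boltzmann_attached(x0: float, p: EnergyParams,
                              rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Exact draws from the full attached-state Boltzmann density
    ``N exp(-beta E_t(., x0))`` over all three basins: wells are chosen
    by their quadrature weights, positions by per-well rejection."""
    from scipy.integrate import quad

    ex = locate_extrema(x0, p)
    e_ref = float(ex.energies_minima.min())
    bounds = [(ex.minima[0] - 0.5 * p.d, ex.maxima[0]),
              (ex.maxima[0], ex.maxima[1]),
              (ex.maxima[1], ex.minima[2] + 0.5 * p.d)]
    w = np.array([quad(lambda xx: math.exp(-p.beta * (total_energy(xx, x0, p) - e_ref)),
                       a, b, points=[ex.minima[i]], limit=200)[0]
                  for i, (a, b) in enumerate(bounds)])
    wells = rng.choice(3, size=size, p=w / w.sum())
    out = np.empty(size)
    for i in range(3):
        m = wells == i
        if m.any():
            out[m] = rejection_sample_well(i, x0, p, rng, size=int(m.sum()))
    return out


def rejection_sample_well(well: int, x0: float, p: EnergyParams,
                          rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Exact draws from ``exp(-beta E_t)`` restricted to one attached
    basin of the SL landscape (test oracle for the Gaussian shortcut).

    Rejection from a uniform proposal over the basin between the
    flanking maxima (outer wells: one period around the minimum).
    """
    ex = locate_extrema(x0, p)
    lo = ex.maxima[well - 1] if well > 0 else ex.minima[0] - 0.5 * p.d
    hi = ex.maxima[well] if well < 2 else ex.minima[2] + 0.5 * p.d
    e_min = ex.energies_minima[well]
    beta = p.beta
    out = np.empty(size)
    got = 0
    while got < size:
        cand = rng.uniform(lo, hi, size=4 * (size - got))
        acc = rng.random(cand.size) < np.exp(
            -beta * (total_energy(cand, x0, p) - e_min))
        take = cand[acc][: size - got]
        out[got: got + take.size] = take
        got += take.size
    return out


# -- stepping -----------------------------------------------------------------

def _table_args(rt: RateTable):
    g = rt.x0_grid
    return (float(g[0]), float(g[1] - g[0]), rt.k01, rt.k10, rt.k12, rt.k21)


_NO_EVENTS = (0, np.empty(0), np.empty(0, dtype=np.int64),
              np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
              np.empty(0, dtype=np.int64), np.zeros(1, dtype=np.int64))


def advance_markov(e: MarkovEnsemble, t_end: float, rt: RateTable,
                   ap: AttachDetachParams, p: EnergyParams,
                   dt_max: float = DT_MAX_DEFAULT,
                   z_mode: int = 0, F_ext: float = 0.0,
                   sample=None, events=None) -> None:
    """Advance the ensemble to absolute time ``t_end`` (ns) with adaptive
    fixed steps capped by the 0.1 exit-probability rule."""
    if rt.scenario is not e.scenario:
        raise ParameterError("rate table scenario does not match the ensemble")
    sharp = 0 if e.scenario is Scenario.SL else 1
    zt = np.array([e.z, e.t])
    K.markov_run(
        e.next_seed(),
        e.chem, e.x0, e.xs, e.t_attach, zt,
        t_end, dt_max, P_STEP_CAP,
        p.d, p.k_plus, p.k_minus, p.kBT, p.k_c, sharp,
        *_table_args(rt),
        *effective_chem_rates(ap, p.T),
        z_mode, F_ext, DZ_CAP,
        *(sample if sample is not None else
          (0.0, np.empty(0), np.empty(0), np.empty(0),
           np.empty((0, 5), dtype=np.int64), np.zeros(1, dtype=np.int64))),
        e.counters, e.pm_attach, e.pm_back,
        *(events if events is not None else _NO_EVENTS),
    )
    e.z, e.t = float(zt[0]), float(zt[1])


def make_event_buffers(capacity: int):
    """Allocate a capacity-bounded event log for :func:`advance_markov`."""
    return (1, np.empty(capacity), np.empty(capacity, dtype=np.int64),
            np.empty(capacity, dtype=np.int64), np.empty(capacity, dtype=np.int64),
            np.empty(capacity, dtype=np.int64), np.zeros(1, dtype=np.int64))


def events_from_buffers(buf) -> EventLog:
    m = int(buf[6][0])
    return EventLog(t=buf[1][:m].copy(), motor_id=buf[2][:m].copy(),
                    from_state=buf[3][:m].copy(), to_state=buf[4][:m].copy(),
                    direction=buf[5][:m].copy(),
                    truncated=m >= buf[1].shape[0])


def markov_step(e: MarkovEnsemble, dt: float, rt: RateTable,
                ap: AttachDetachParams, p: EnergyParams,
                z_mode: int = 0, F_ext: float = 0.0,
                events=None) -> MarkovEnsemble:
    """Advance exactly one step of at most ``dt`` (shorter if the
    exit-probability cap demands it).  Mutates and returns ``e``."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    advance_markov(e, e.t + dt, rt, ap, p, dt_max=dt, z_mode=z_mode,
                   F_ext=F_ext, events=events)
    return e


# -- engine cross-validation --------------------------------------------------

def compare_engines(duration: float, n_motors: int, seeds, p: EnergyParams,
                    ap: AttachDetachParams, window_frac: float = 0.5,
                    langevin_seeds=None, dt: float = 0.5,
                    n_blocks: int = 8):
    """Run the Langevin and Markov engines on the same SL isometric
    protocol and report occupancy discrepancies.

    Occupancies are averaged over the final ``window_frac`` of each run;
    Monte-Carlo standard errors come from time-block binning pooled over
    seeds (blocks are long against the slowest chemistry correlation
    time).  ``langevin_seeds`` defaults to ``seeds`` but may be a
    smaller list, the Langevin engine being far costlier per run.
    """
    from .sarcomere import SarcomereGeometry, run_isometric

    geom = SarcomereGeometry(N_Fil=1, N_XB=n_motors)
    if langevin_seeds is None:
        langevin_seeds = seeds
    out = {"states": STATE_NAMES}
    for engine, eng_seeds in (("langevin", langevin_seeds), ("markov", seeds)):
        blocks = []
        tens = []
        for seed in eng_seeds:
            res = run_isometric(Scenario.SL, engine, duration, int(seed), geom,
                                p=p, ap=ap, dt=dt)
            pop = res.populations
            n = pop.shape[0]
            win = pop[int(n * (1.0 - window_frac)):]
            for chunk in np.array_split(win, n_blocks):
                blocks.append(chunk.mean(axis=0))
            tens.append(res.T0)
        blocks = np.asarray(blocks)
        out[f"occ_{engine}"] = blocks.mean(axis=0)
        out[f"se_{engine}"] = blocks.std(axis=0, ddof=1) / math.sqrt(blocks.shape[0])
        out[f"T0_{engine}"] = float(np.mean(tens))
    se = np.hypot(out["se_langevin"], out["se_markov"])
    diff = out["occ_langevin"] - out["occ_markov"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["discrepancy_se_units"] = np.where(se > 0, np.abs(diff) / se, 0.0)
    out["max_discrepancy_se_units"] = float(np.nanmax(out["discrepancy_se_units"]))
    return out
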