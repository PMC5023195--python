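"""Half-sarcomere ensemble mechanics and experimental protocols.

A half-sarcomere is ``N_Fil`` rigid thick filaments of ``N_XB`` myosin
heads each, all sharing one Z-line coordinate z (nm, 0 = optimal
length).  Total tension is the sum of the elastic forces of the
attached heads.  Three protocols are provided:

* **isometric** — z clamped; tension rises to a plateau T0;
* **isotonic**  — after the isometric plateau a constant force F is
  applied and z follows from mechanical equilibrium at every step,
  yielding the shortening velocity and the four-phase transient;
* **length step** — an instantaneous length change delta is applied to
  the isometric plateau; the tension drops to T1 and recovers to T2 (the
  tension at the S2-population peak) at rate r (inverse time to reach
  2/3 T2).

Fiber protocols default to 4 degC; Q10 scaling of the attachment and
detachment constants carries the temperature dependence, while the
power-stroke rates feel temperature through the thermal energy itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels as K
from .energy_landscape import EnergyParams, ParameterError, Scenario
from .langevin_engine import (
    DT_DEFAULT,
    EnsembleState,
    initial_ensemble,
    _advance,
)
from .markov_engine import (
    MarkovEnsemble,
    advance_markov,
    initial_markov_ensemble,
)
from .rate_theory import AttachDetachParams, RateTable, tabulate_rates

__all__ = [
    "FIBER_T",
    "HEART_T",
    "SarcomereGeometry",
    "ProtocolResult",
    "UnloadedSarcomereError",
    "total_tension",
    "solve_equilibrium_z",
    "run_isometric",
    "run_isotonic",
    "run_length_step",
    "hill_fit",
    "detect_isotonic_phases",
]

FIBER_T = 277.15  # K (4 degC, single-molecule and single-fiber protocols)
HEART_T = 310.15  # K (37 degC, heart-like runs)

#: Plateau statistics are averaged over this final fraction of a run.
PLATEAU_FRACTION = 1.0 / 3.0


class UnloadedSarcomereError(RuntimeError):
    """Mechanical equilibrium is undefined with no attached motors."""


@dataclass(frozen=True)
class SarcomereGeometry:
    """Half-sarcomere composition.  ``SL0`` (initial sarcomere length)
    is carried as metadata for organ-scale coupling and unused here."""

    N_Fil: int = 4
    N_XB: int = 38
    SL0: float = 2000.0  # nm

    def __post_init__(self) -> None:
        if self.N_Fil < 1 or self.N_XB < 1:
            raise ParameterError("N_Fil and N_XB must be >= 1")

    @property
    def n_motors(self) -> int:
        return self.N_Fil * self.N_XB


@dataclass
class ProtocolResult:
    """Traces and summary observables of one protocol run."""

    protocol: str
    scenario: Scenario
    engine: str
    t: np.ndarray                # ns
    tension: np.ndarray          # pN
    z: np.ndarray                # nm
    populations: np.ndarray      # (n_samples, 5) fractions of D, W, S0, S1, S2
    counters: np.ndarray         # attach, detach, dislodge, fwd, back, noatt
    n_motors: int
    pm_attach: np.ndarray | None = None
    pm_back: np.ndarray | None = None
    summaries: dict = field(default_factory=dict)

    @property
    def S_TOT(self) -> np.ndarray:
        """Attached fraction vs time."""
        return self.populations[:, 2:].sum(axis=1)

    def _plateau_slice(self) -> slice:
        n = self.t.size
        return slice(int(n * (1.0 - PLATEAU_FRACTION)), n)

    @property
    def T0(self) -> float:
        return self.summaries.get("T0", float(np.mean(self.tension[self._plateau_slice()])))

    @property
    def plateau_populations(self) -> np.ndarray:
        return self.populations[self._plateau_slice()].mean(axis=0)

    @property
    def s1_share(self) -> float:
        """Plateau S1 occupancy as a fraction of all attached heads."""
        pop = self.plateau_populations
        stot = pop[2:].sum()
        return float(pop[3] / stot) if stot > 0 else float("nan")

    @property
    def force_per_attached(self) -> float:
        pop = self.plateau_populations
        stot = pop[2:].sum() * self.n_motors
        return self.T0 / stot if stot > 0 else float("nan")


# -- mechanics ----------------------------------------------------------------

def total_tension(e, p: EnergyParams) -> float:
    """Sum of elastic forces over attached motors (pN), with the
    asymmetric stiffness; detached motors contribute nothing."""
    if isinstance(e, MarkovEnsemble):
        att, x = e.chem >= 2, e.xs
    else:
        att, x = e.chem == 2, e.x
    xa = x[att]
    k = np.where(xa >= 0.0, p.k_plus, p.k_minus)
    return float(np.sum(k * xa))


def solve_equilibrium_z(e, F: float, p: EnergyParams) -> float:
    """Z-line shift dz such that the total elastic tension equals F.

    Exact for the piecewise-linear elasticity (Newton on a convex
    piecewise-linear function).  Raises
    :class:`UnloadedSarcomereError` with no attached motors.
    """
    if isinstance(e, MarkovEnsemble):
        att_code, x, chem = 2, e.xs, e.chem
    else:
        att_code, x, chem = 2, e.x, e.chem
    if int(np.sum(chem >= att_code)) == 0:
        raise UnloadedSarcomereError("no attached motors: z is not determined")
    dz, ok = K._solve_dz(x, chem, att_code, F, p.k_plus, p.k_minus, x.shape[0])
    if not ok:  # pragma: no cover - guarded above
        raise UnloadedSarcomereError("equilibrium solve failed")
    return float(dz)


# -- engine-agnostic driver ---------------------------------------------------

def _alloc_samples(n: int):
    return (np.empty(n), np.empty(n), np.empty(n),
            np.empty((n, 5), dtype=np.int64), np.zeros(1, dtype=np.int64))


def _resolve(p, ap, T):
    if p is None:
        p = EnergyParams(T=T if T is not None else FIBER_T)
    elif T is not None:
        p = p.with_temperature(T)
    if ap is None:
        ap = AttachDetachParams()
    return p, ap


class _Driver:
    """Uniform advance/sample interface over the two engines."""

    def __init__(self, scenario, engine, seed, geom, p, ap, dt, dt_max):
        self.scenario = Scenario(scenario)
        self.engine = engine
        self.p, self.ap = p, ap
        n = geom.n_motors
        if engine == "langevin":
            if self.scenario is not Scenario.SL:
                raise ParameterError(
                    "the Langevin engine integrates a finite landscape; "
                    f"{self.scenario} has none (use the markov engine)")
            self.e = initial_ensemble(n, p, seed)
            self.dt = dt
            self.rt = None
        elif engine == "markov":
            self.e = initial_markov_ensemble(n, self.scenario, p, seed)
            self.rt = tabulate_rates(self.scenario, p)
            self.dt_max = dt_max
        else:
            raise ParameterError(f"unknown engine {engine!r}")

    def advance(self, duration, sample_dt, z_mode=0, F_ext=0.0):
        """Advance by ``duration`` ns, returning (t, T, z, pop-fractions)."""
        n_mot = self.e.n_motors
        if self.engine == "langevin":
            n_steps = int(round(duration / self.dt))
            sample_every = max(1, int(round(sample_dt / self.dt)))
            n_samp = n_steps // sample_every
            bufs = _alloc_samples(n_samp)
            _advance(self.e, n_steps, self.dt, self.p, self.ap,
                     do_diff=True, do_chem=True, z_mode=z_mode, F_ext=F_ext,
                     sample=(sample_every, *bufs))
        else:
            n_samp = int(round(duration / sample_dt))
            bufs = _alloc_samples(n_samp + 4)
            advance_markov(self.e, self.e.t + duration, self.rt, self.ap,
                           self.p, dt_max=self.dt_max, z_mode=z_mode,
                           F_ext=F_ext, sample=(sample_dt, *bufs))
        m = int(bufs[4][0])
        return (bufs[0][:m], bufs[1][:m], bufs[2][:m],
                bufs[3][:m].astype(float) / n_mot)

    def apply_length_step(self, delta: float) -> None:
        """Instantaneous z jump by -delta (delta > 0 releases)."""
        e = self.e
        if self.engine == "langevin":
            att = e.chem == 2
            e.x[att] -= delta
        else:
            att = e.chem >= 2
        e.x0[att] -= delta
        if self.engine == "markov":
            e.xs[att] -= delta
        e.z -= delta

    def result(self, protocol, traces, summaries) -> ProtocolResult:
        t, T, z, pop = traces
        return ProtocolResult(
            protocol=protocol, scenario=self.scenario, engine=self.engine,
            t=t, tension=T, z=z, populations=pop,
            counters=self.e.counters.copy(), n_motors=self.e.n_motors,
            pm_attach=self.e.pm_attach.copy(), pm_back=self.e.pm_back.copy(),
            summaries=summaries,
        )


def _cat(*traces):
    return tuple(np.concatenate([tr[i] for tr in traces]) for i in range(4))


# -- protocols ----------------------------------------------------------------

def run_isometric(scenario, engine, duration, seed, geometry=None, *,
                  p=None, ap=None, T=None, dt=DT_DEFAULT, dt_max=2000.0,
                  sample_dt=None) -> ProtocolResult:
    """Isometric contraction: z clamped at 0 for ``duration`` ns.

    Plateau statistics (T0, populations, force per attached head) are
    averaged over the final third of the run.
    """
    geometry = geometry or SarcomereGeometry()
    p, ap = _resolve(p, ap, T)
    drv = _Driver(scenario, engine, seed, geometry, p, ap, dt, dt_max)
    sample_dt = sample_dt or duration / 600.0
    traces = drv.advance(duration, sample_dt)
    res = drv.result("isometric", traces, {})
    res.summaries.update(
        T0=float(np.mean(res.tension[res._plateau_slice()])),
        plateau_populations=res.plateau_populations,
        s1_share=res.s1_share,
        force_per_attached=res.force_per_attached,
    )
    return res


def run_isotonic(scenario, engine, duration, seed, geometry=None, *,
                 F=None, force_frac=None, rise_duration=None,
                 p=None, ap=None, T=None, dt=DT_DEFAULT, dt_max=2000.0,
                 sample_dt=None) -> ProtocolResult:
    """Force clamp: isometric rise to the plateau, then the external
    force F (or ``force_frac * T0``) is applied and z evolves by
    mechanical equilibrium.

    The steady shortening velocity (nm/ms, positive = shortening) is a
    linear fit of z(t) over the last half of the loaded window; the full
    transient is retained for phase analysis.
    """
    geometry = geometry or SarcomereGeometry()
    p, ap = _resolve(p, ap, T)
    if (F is None) == (force_frac is None):
        raise ParameterError("provide exactly one of F, force_frac")
    drv = _Driver(scenario, engine, seed, geometry, p, ap, dt, dt_max)
    rise_duration = rise_duration or duration
    sample_dt = sample_dt or min(duration / 2500.0, 5e4)
    rise = drv.advance(rise_duration, rise_duration / 600.0)
    n_pl = max(1, int(rise[0].size * PLATEAU_FRACTION))
    T0 = float(np.mean(rise[1][-n_pl:]))
    if force_frac is not None:
        F = force_frac * T0
    t_step = drv.e.t
    loaded = drv.advance(duration, sample_dt, z_mode=1, F_ext=F)
    traces = _cat(rise, loaded)
    tl, Tl, zl, popl = loaded
    # yield: the attached set collapsed under load (dislodge cascade)
    stot = popl[:, 2:].sum(axis=1)
    collapsed = np.flatnonzero(stot <= 0)
    i_end = int(collapsed[0]) if collapsed.size else tl.size
    yielded = collapsed.size > 0
    if i_end >= 10:
        half = i_end // 2
        slope = np.polyfit(tl[half:i_end], zl[half:i_end], 1)[0]  # nm/ns
        v = -slope * 1e6  # nm/ms, positive = shortening
    else:
        v = float("nan")
    phases = detect_isotonic_phases(tl[:i_end], zl[:i_end], t_step)
    res = drv.result("isotonic", traces, {})
    res.summaries.update(
        T0=T0, F=float(F), v=float(v), t_step=t_step, yielded=yielded,
        lengthening=bool(F > T0), phases=phases,
    )
    return res


def run_length_step(scenario, engine, delta, seed, geometry=None, *,
                    rise_duration, window, p=None, ap=None, T=None,
                    dt=DT_DEFAULT, dt_max=2000.0, sample_dt=None,
                    smooth_samples: int = 9) -> ProtocolResult:
    """Length-step protocol: after the isometric plateau, z jumps
    instantaneously by ``-delta`` (delta > 0 is a release).

    T1 is the tension at the first post-step sample; T2 the (smoothed)
    tension at the time of the S2-population maximum; r the inverse of
    the time from the step until the tension recovers to 2/3 T2.
    Summaries are flagged undefined when S2 never peaks inside the
    window.
    """
    geometry = geometry or SarcomereGeometry()
    p, ap = _resolve(p, ap, T)
    drv = _Driver(scenario, engine, seed, geometry, p, ap, dt, dt_max)
    sample_dt = sample_dt or window / 20000.0
    rise = drv.advance(rise_duration, rise_duration / 600.0)
    n_pl = max(1, int(rise[0].size * PLATEAU_FRACTION))
    T0 = float(np.mean(rise[1][-n_pl:]))
    t_step = drv.e.t
    drv.apply_length_step(delta)
    post = drv.advance(window, sample_dt)
    traces = _cat(rise, post)
    tp, Tp, popp = post[0], post[1], post[3]
    T1 = float(Tp[0])
    w = max(smooth_samples, tp.size // 200, 1)
    kern = np.ones(w) / w
    T_s = np.convolve(Tp, kern, mode="same")
    s2 = np.convolve(popp[:, 4], kern, mode="same")
    i_pk = int(np.argmax(s2))
    interior = 0 < i_pk < s2.size - 1
    # the S2 peak must stand out from counting noise to define T2
    floor = max(2.0 / drv.e.n_motors, 1.5 * float(np.median(s2)))
    summ = dict(T0=T0, T1=T1, delta=float(delta), t_step=t_step)
    if not interior or s2[i_pk] < floor:
        summ.update(T2=float("nan"), r=float("nan"), undefined=True)
    else:
        T2 = float(T_s[i_pk])
        thresh = 2.0 / 3.0 * T2
        above = np.flatnonzero(T_s >= thresh)
        if above.size == 0:
            summ.update(T2=T2, r=float("nan"), undefined=True)
        else:
            t_hit = tp[above[0]]
            dt_hit = max(t_hit - t_step, sample_dt)  # resolution floor
            summ.update(T2=T2, r=1e6 / dt_hit,  # 1/ms
                        r_resolution_limited=bool(t_hit - t_step < sample_dt),
                        undefined=False)
    res = drv.result("length_step", traces, summ)
    return res


def detect_isotonic_phases(t, z, t_step, steady_frac: float = 0.5):
    """Slope segmentation of the post-load shortening transient.

    Returns the four classical phases as booleans: (1) elastic drop at
    load application, (2) rapid early shortening faster than steady,
    (3) a transient pause/slowing below the early rate, (4) steady
    shortening.  Velocities are slopes of z(t) over log-spaced windows,
    so the millisecond-scale power-stroke phase and the much slower
    steady phase are both resolved.
    """
    t = np.asarray(t) - t_step
    z = np.asarray(z)
    n = t.size
    out = dict(elastic_drop=False, rapid_early=False, pause=False,
               steady=False, all_four=False, v_early=float("nan"),
               v_pause=float("nan"), v_steady=float("nan"))
    if n < 40:
        return out
    # the load switch itself produced the first (elastic) z displacement
    out["elastic_drop"] = z[0] < -1e-6
    i_st = int(n * steady_frac)
    v_steady = -np.polyfit(t[i_st:], z[i_st:], 1)[0]  # nm/ns, >0 shortening
    out["steady"] = v_steady > 0
    out["v_steady"] = v_steady * 1e6
    edges = np.unique(np.geomspace(3, i_st, 14).astype(int))
    vw = np.array([-np.polyfit(t[a:b + 1], z[a:b + 1], 1)[0]
                   for a, b in zip(np.r_[0, edges[:-1]], edges)
                   if b - a >= 2])
    if vw.size >= 4:
        i_pk = int(np.argmax(vw[: max(2, vw.size // 2)]))
        v_early = float(vw[i_pk])
        out["v_early"] = v_early * 1e6
        out["rapid_early"] = v_early > 1.5 * v_steady
        if i_pk + 1 < vw.size:
            v_pause = float(np.min(vw[i_pk + 1:]))
            out["v_pause"] = v_pause * 1e6
            out["pause"] = v_pause < 0.6 * v_early
    out["all_four"] = all(out[k] for k in
                          ("elastic_drop", "rapid_early", "pause", "steady"))
    return out


# -- force-velocity fitting ---------------------------------------------------

def hill_fit(points, T0: float):
    """Least-squares fit of the Hill hyperbola (F + a)(v + b) = (T0 + a) b.

    ``points`` is a sequence of (F, v) pairs with v >= 0 spanning from
    near F = 0 to near T0.  Returns (a, b, v_max) with
    ``v_max = v(F=0) = b T0 / a`` from the fitted curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ParameterError("need at least 4 (F, v) points")
    F, v = pts[:, 0], pts[:, 1]
    if np.any(v < -1e-12):
        raise ParameterError("velocities must be non-negative")

    def model(FF, a, b):
        return b * (T0 - FF) / (FF + a)

    v_scale = max(v.max(), 1e-12)
    try:
        (a, b), _ = curve_fit(model, F, v, p0=[0.25 * T0, v_scale],
                              bounds=([1e-9, 1e-12], [np.inf, np.inf]),
                              maxfev=20000)
    except RuntimeError as err:
        resid = None
        raise RuntimeError(f"Hill fit did not converge: {err}") from err
    return float(a), float(b), float(b * T0 / a)
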