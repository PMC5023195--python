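"""Event accounting, recovery-rate fitting, configuration and file I/O.

Configuration is a flat sectioned key=value text file (INI); every
parameter of every module is a named key with a default, unknown keys
are errors (typos would silently break ceteris-paribus comparisons).
Scenario sweeps share one config so that only the minima sharpness
differs between compared runs.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels as K
from .energy_landscape import KBT0, EnergyParams, ParameterError, Scenario
from .markov_engine import EventLog, JumpEvent
from .rate_theory import AttachDetachParams
from .sarcomere import ProtocolResult, SarcomereGeometry

__all__ = [
    "EventSummary",
    "count_events",
    "exp_recovery_rate",
    "RunConfig",
    "write_outputs",
    "read_traces",
]

log = logging.getLogger(__name__)


# -- event accounting ---------------------------------------------------------

@dataclass(frozen=True)
class EventSummary:
    """Attachment/detachment/jump counts normalized by the number of
    cross-bridges N_XB, plus backward jumps per attachment event."""

    attach: float
    detach: float
    dislodge: float
    forward_jumps: float
    backward_jumps: float
    backward_jumps_per_attachment: float

    @classmethod
    def from_counts(cls, attach, detach, dislodge, fwd, back, N_XB):
        if N_XB < 1:
            raise ParameterError("N_XB must be >= 1")
        bpa = back / attach if attach > 0 else 0.0
        return cls(attach / N_XB, detach / N_XB, dislodge / N_XB,
                   fwd / N_XB, back / N_XB, bpa)

    @classmethod
    def from_counters(cls, counters, N_XB):
        return cls.from_counts(counters[K.C_ATTACH], counters[K.C_DETACH],
                               counters[K.C_DISLODGE], counters[K.C_FWD],
                               counters[K.C_BACK], N_XB)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def count_events(events, N_XB: int) -> EventSummary:
    """Exact per-direction counts of a time-ordered jump-event log,
    normalized by N_XB.  Raises on an unordered log."""
    if isinstance(events, EventLog):
        times = events.t
        dirs = [int(d) for d in events.direction]
    else:
        events = list(events)
        times = np.array([ev.t for ev in events])
        name_to_code = {"attach": 0, "detach": 1, "dislodge": 2,
                        "forward": 3, "backward": 4}
        dirs = [name_to_code[ev.direction] for ev in events]
    if times.size and np.any(np.diff(times) < 0):
        raise ParameterError("event log is not time-ordered")
    c = np.zeros(5, dtype=np.int64)
    for d in dirs:
        c[d] += 1
    return EventSummary.from_counts(c[0], c[1], c[2], c[3], c[4], N_XB)


# -- tension-recovery rate ----------------------------------------------------

def exp_recovery_rate(t, tension, t_step: float, T2: float,
                      smooth_samples: int = 1) -> dict:
    """Tension recovery rate after a length step, two ways.

    Rule-based: ``r = 1 / (time from the step until T >= 2/3 T2)``
    (1/ms).  Diagnostic cross-check: an exponential fit
    ``T(t) = T2 - (T2 - T1) exp(-lam (t - t_step))`` reported on the
    same scale as ``lam / ln 3`` (for a pure exponential from zero the
    two coincide exactly).  Flags are set when the threshold is never
    crossed or only at the sampling-resolution floor.
    """
    t = np.asarray(t, float)
    T = np.asarray(tension, float)
    post = t >= t_step
    tp, Tp = t[post], T[post]
    if tp.size < 3:
        raise ParameterError("trace must span the step")
    if smooth_samples > 1:
        kern = np.ones(smooth_samples) / smooth_samples
        Tp = np.convolve(Tp, kern, mode="same")
    out = dict(r=float("nan"), r_fit=float("nan"), undefined=False,
               resolution_limited=False)
    thresh = 2.0 / 3.0 * T2
    above = np.flatnonzero(Tp >= thresh)
    dt_samp = float(np.median(np.diff(tp)))
    if above.size == 0:
        out["undefined"] = True
        return out
    t_hit = tp[above[0]] - t_step
    if t_hit < dt_samp:
        out["resolution_limited"] = True
        t_hit = max(t_hit, dt_samp)
    out["r"] = 1e6 / t_hit  # 1/ms

    T1 = Tp[0]
    try:
        (lam,), _ = curve_fit(
            lambda tt, lam: T2 - (T2 - T1) * np.exp(-lam * (tt - t_step)),
            tp, Tp, p0=[math.log(3.0) / max(t_hit, dt_samp)],
            bounds=([1e-12], [np.inf]), maxfev=10000)
        out["r_fit"] = lam / math.log(3.0) * 1e6  # 1/ms, rule-comparable
    except RuntimeError:  # diagnostic only; rule-based r stands
        pass
    return out


# -- configuration ------------------------------------------------------------

#: Keys whose shipped defaults are stated in the main-text model
#: description; everything else is a package working default.
_PAPER_DEFAULT_KEYS = {
    "energy.H", "energy.d", "energy.n_minima", "energy.F_ATP",
    "energy.k_plus", "energy.eta",
    "attach_detach.x_dislodge",
}

_ENERGY_FIELDS = ("H", "d", "n_minima", "F_ATP", "alpha_d", "k_plus",
                  "k_minus", "eta")
_AD_FIELDS = ("f_max", "x_lim", "g_slope", "g_neg", "x_dislodge", "k_DW",
              "k_WD", "activation", "Q10", "T_ref")
_GEOM_FIELDS = ("N_Fil", "N_XB", "SL0")


@dataclass
class RunConfig:
    """Fully resolved run configuration; round-trips losslessly through
    its INI text representation."""

    # [run]
    scenario: str = "SL"
    engine: str = "markov"
    protocol: str = "isometric"
    duration_ms: float = 100.0
    rise_ms: float = 50.0
    temperature_C: float = 4.0
    seed: int = 1
    reps: int = 1
    force_frac: float = 0.5
    delta_nm: float = 5.6
    dt_ns: float = 0.5
    dt_max_ns: float = 2000.0
    decimation: int = 1
    log_level: str = "INFO"
    # [energy]
    H: float = EnergyParams.H
    d: float = EnergyParams.d
    n_minima: int = 3
    F_ATP: float = EnergyParams.F_ATP
    alpha_d: float = float("nan")   # nan -> derived from stationarity
    k_plus: float = EnergyParams.k_plus
    k_minus: float = EnergyParams.k_minus
    eta: float = EnergyParams.eta
    # [attach_detach]
    f_max: float = AttachDetachParams.f_max
    x_lim: float = AttachDetachParams.x_lim
    g_slope: float = AttachDetachParams.g_slope
    g_neg: float = AttachDetachParams.g_neg
    x_dislodge: float = AttachDetachParams.x_dislodge
    k_DW: float = AttachDetachParams.k_DW
    k_WD: float = AttachDetachParams.k_WD
    activation: float = AttachDetachParams.activation
    Q10: float = AttachDetachParams.Q10
    T_ref: float = AttachDetachParams.T_ref
    # [geometry]
    N_Fil: int = 4
    N_XB: int = 38
    SL0: float = 2000.0
    # [output]
    out_dir: str = "."

    _overridden: set = field(default_factory=set, repr=False, compare=False)

    _SECTIONS = {
        "run": ("scenario", "engine", "protocol", "duration_ms", "rise_ms",
                "temperature_C", "seed", "reps", "force_frac", "delta_nm",
                "dt_ns", "dt_max_ns", "decimation", "log_level"),
        "energy": _ENERGY_FIELDS,
        "attach_detach": _AD_FIELDS,
        "geometry": _GEOM_FIELDS,
        "output": ("out_dir",),
    }

    # -- construction --------------------------------------------------------

    @classmethod
    def from_ini(cls, source) -> "RunConfig":
        """Parse from an INI path or string.  Unknown sections or keys
        are hard errors."""
        cp = configparser.ConfigParser()
        cp.optionxform = str  # keys are case-sensitive (N_Fil, F_ATP, ...)
        text = Path(source).read_text() if isinstance(source, Path) else str(source)
        if isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        cp.read_string(text)
        cfg = cls()
        types = {f.name: f.type for f in fields(cls)}
        for section in cp.sections():
            if section not in cls._SECTIONS:
                raise ParameterError(f"unknown config section [{section}]")
            for key, raw in cp.items(section):
                if key not in cls._SECTIONS[section]:
                    raise ParameterError(
                        f"unknown config key {key!r} in section [{section}]")
                cur = getattr(cfg, key)
                if isinstance(cur, bool):  # pragma: no cover - none yet
                    val = raw.lower() in ("1", "true", "yes")
                elif isinstance(cur, int):
                    val = int(raw)
                elif isinstance(cur, float):
                    val = float(raw)
                else:
                    val = raw
                setattr(cfg, key, val)
                cfg._overridden.add(f"{section}.{key}")
        return cfg

    def to_ini(self) -> str:
        lines = []
        for section, keys in self._SECTIONS.items():
            lines.append(f"[{section}]")
            for key in keys:
                val = getattr(self, key)
                if isinstance(val, float):
                    lines.append(f"{key} = {val!r}")
                else:
                    lines.append(f"{key} = {val}")
            lines.append("")
        return "\n".join(lines)

    # -- resolution ----------------------------------------------------------

    def provenance(self) -> dict:
        """Per-key origin of the resolved value: user override, main-text
        default, or package working default."""
        out = {}
        for section, keys in self._SECTIONS.items():
            for key in keys:
                dotted = f"{section}.{key}"
                if dotted in self._overridden:
                    out[dotted] = "override"
                elif dotted in _PAPER_DEFAULT_KEYS:
                    out[dotted] = "model-default"
                else:
                    out[dotted] = "package-default"
        return out

    def log_provenance(self) -> None:
        for key, src in self.provenance().items():
            log.info("config %-28s = %-24r (%s)", key, getattr(
                self, key.split(".", 1)[1]), src)

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15

    def energy_params(self) -> EnergyParams:
        alpha = None if math.isnan(self.alpha_d) else self.alpha_d
        return EnergyParams(H=self.H, d=self.d, n_minima=self.n_minima,
                            F_ATP=self.F_ATP, alpha_d=alpha,
                            k_plus=self.k_plus, k_minus=self.k_minus,
                            eta=self.eta, T=self.temperature_K)

    def attach_params(self) -> AttachDetachParams:
        return AttachDetachParams(
            f_max=self.f_max, x_lim=self.x_lim, g_slope=self.g_slope,
            g_neg=self.g_neg, x_dislodge=self.x_dislodge, k_DW=self.k_DW,
            k_WD=self.k_WD, activation=self.activation, Q10=self.Q10,
            T_ref=self.T_ref)

    def geometry(self) -> SarcomereGeometry:
        return SarcomereGeometry(N_Fil=self.N_Fil, N_XB=self.N_XB, SL0=self.SL0)


# -- output files -------------------------------------------------------------

_TRACE_COLUMNS = ("t_ns", "tension_pN", "z_nm", "D", "W", "S0", "S1", "S2")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, Scenario):
        return o.value
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_outputs(result: ProtocolResult, cfg: RunConfig, out_dir=None,
                  prefix: str = "run") -> dict:
    """Write trace CSV, summary JSON and the resolved config next to each
    other; everything written reloads to numerically identical values.

    Returns the mapping of artifact name to path.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out}: {err}") from err
    dec = max(1, int(cfg.decimation))
    sl = slice(None, None, dec)
    import pandas as pd

    frame = pd.DataFrame({
        "t_ns": result.t[sl], "tension_pN": result.tension[sl],
        "z_nm": result.z[sl],
        **{name: result.populations[sl, i]
           for i, name in enumerate(("D", "W", "S0", "S1", "S2"))},
    })
    paths = {
        "traces": out / f"{prefix}_traces.csv",
        "summary": out / f"{prefix}_summary.json",
        "config": out / f"{prefix}_config.ini",
    }
    frame.to_csv(paths["traces"], index=False, float_format="%.17g")
    summary = dict(result.summaries)
    summary["protocol"] = result.protocol
    summary["scenario"] = result.scenario.value
    summary["engine"] = result.engine
    summary["n_motors"] = result.n_motors
    summary["events"] = EventSummary.from_counters(
        result.counters, result.n_motors).as_dict()
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
        fh.write("\n")
    paths["config"].write_text(cfg.to_ini())
    return paths


def read_traces(path):
    """Reload a trace CSV written by :func:`write_outputs`."""
    import pandas as pd

    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"trace file {path} missing columns {sorted(missing)}")
    return frame
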