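# Methods

## Model

An attached myosin head is reduced to one mechanical coordinate, the
stretch *x* (nm) of its elastic element relative to the thick-filament
backbone.  Its energy is the sum of a biochemical part — the
actomyosin interaction along the reaction path — and a mechanical part,
the elastic deformation of the head:

* biochemical: `E_c(x, x0) = H sin(2π(x − x0)/d + α_d) + F_ATP (x − x0)`
  on the central region spanning three minima (the pre-power-stroke
  state S0 at `x0` and post-power-stroke states S1, S2 at `x0 + d`,
  `x0 + 2d`).  The phase constant α_d is not free: it is recomputed from
  the stationarity condition `E_c′(x0, x0) = 0`, `E_c″ > 0` whenever H,
  d or F_ATP change, which pins the first minimum exactly at x0.
* elastic: `E_e(x) = ½ k± x²`, tensile stiffness `k⁺ = 2 pN/nm` for
  x > 0 and compressive stiffness `k⁻` (default 0.2 pN/nm) for x < 0.
  The asymmetry enters every energy and rate identically in all three
  scenarios, so ceteris-paribus comparisons are unaffected by the
  (uncertain) compressive value.

Outside the central region the sinusoid is continued for half a period
beyond each outer minimum and then closed with C1-continuous harmonic
walls of stiffness `100 k_c`, so Langevin trajectories cannot leave the
modeled landscape.  Only the definition of the central region is part of
the science; the walls are bookkeeping.

Units are fixed project-wide: pN, nm, ns, K; energies in pN·nm;
`kB = 0.0138065 pN·nm/K`.

Key default values: `H = 6 kB T₀` (T₀ = 310.15 K), `d = 4.5 nm`,
`F_ATP = −8 kB T₀ / d ≈ −7.61 pN` (a 16 kB T₀ drop over the two steps —
essentially the full free energy of one ATP; the sign is forced by the
requirement that the minima energies decrease S0 → S1 → S2 at
increasing x), drag `η = 70 pN·ns/nm`.  The parabolic well stiffness is
`k_c = H (2π/d)² ≈ 50.1 pN/nm` with the exact kB above (≈ 48 pN/nm when
kB T₀ is rounded to 4.1 pN·nm, the conventionally printed figure).

## The three sharpness scenarios

The scenarios share every number above and differ only in the width of
the biochemical wells.

**SL (wide minima).**  The head is a material point in overdamped
dynamics on `E_t = E_c + E_e`.  Inter-well rates follow the
Kramers–Smoluchowski mean-first-passage form

```
k(i→j) = [ β η · ∫_basin(i) e^{−βE_t} dx · ∫_{min_i}^{min_j} e^{+βE_t} dx ]⁻¹
```

with the basin of well *i* bounded by its flanking maxima (outer wells:
truncated where E_t exceeds the well bottom by 25 kB T).  This
factorized form satisfies detailed balance against the quadrature
stationary probabilities exactly, because the same well integrals define
both.

**SRII (sharp minima, flat potential).**  The well integral collapses to
a calibrated constant times `e^{−βE_e}` at the unshifted minimum; the
barrier integral of `e^{+βE_e}` between the minima is kept (for a
parabolic E_e it has an error-function closed form; we evaluate it by
quadrature, which is equivalent to numerical precision and also handles
the piecewise stiffness).  Forward/backward ratios then satisfy the
sharp-minima detailed balance `k_f/k_b = e^{−β ΔE_t}` at the unshifted
minima exactly.

**SRI (Huxley–Simmons).**  Backward rates are strain-independent
constants; forward rates are `k_b · e^{−β ΔE_t}`.

Calibration: the free constants of SRI and SRII are set from the KS
rates of the *unloaded* (k = 0) SL landscape, so all three scenarios
have identical unloaded forward and backward rates.  SRII's unloaded
match is exact by construction.  SRI keeps its detailed balance exact
instead, which leaves its unloaded forward rates matched only to ~1e-4:
the calibrated unloaded ratio equals `e^{−β ΔE_c}` only up to the
(in)congruence of the truncated quadrature basins.  Both properties
cannot be exact simultaneously with quadrature-calibrated constants; we
chose exact detailed balance.

## Cycle chemistry

D ↔ W (detached/weakly bound) transitions have constant rates, with
`k_DW` multiplied by a scalar activation ∈ [0, 1] that stands in for the
calcium/cooperativity/overlap machinery of a full sarcomere model;
fully activated protocols use 1.  W → S0 attachment is strain-gated:
rate `f_max · x/x_lim` for 0 < x ≤ x_lim, zero when compressed;
attachment anchors the pre-power-stroke minimum at the current position
(`x0 := x`), so every attachment starts in S0.  Detachment S → D rises
linearly with x > 0 (slope `g_slope`) and is the large constant `g_neg`
for x < 0.  |x| > 15 nm triggers mechanical dislodging — a forced S → D
with the elastic element snapped back to x = 0, counted separately from
ATP-mediated detachment.  Temperature scales all attachment/detachment
and D↔W constants by `Q10^((T − T_ref)/10)`; power-stroke rates carry no
Q10 factor because temperature already enters them through β and the
calibration.

Working defaults (config keys, overridable): `f_max = 300/s`,
`x_lim = 5 nm`, `g_slope = 15/s·nm`, `g_neg = 2000/s`, `k_DW = 200/s`,
`k_WD = 100/s`, `Q10 = 2`, `T_ref = 277.15 K`.  Three of these choices
deserve justification:

* *per-second magnitudes*: strain-gated attachment at 65–300 s⁻¹ is the
  classical scale (Huxley's f₁ = 65 s⁻¹); per-millisecond magnitudes
  would imply ATP turnover of ~10⁴ s⁻¹ per head and would make the
  attachment cycle two orders of magnitude faster than the calibrated
  power-stroke rates, erasing the within-lifetime S0 ↔ S1 dynamics the
  model exists to study.
* *T_ref = 4 °C*: the constants are defined at the fiber experimental
  condition and Q10 speeds them up (×9.9) for 37 °C heart-like runs.
  With the opposite referencing, 4 °C chemistry falls an order of
  magnitude below the power-stroke timescale and the single-molecule
  phenomenology (several jumps per SL lifetime, about one for SRII,
  nearly none for SRI) disappears.
* *f_max = 300/s*: with the attachment ramp averaged over the thermal
  spread of the detached elastic element, this yields a tetanized
  attached fraction of ~0.15–0.3 across scenarios, the duty ratio
  reported for fiber-scale simulations of this kind; the 65/s value
  yields 4–9%, too low to be comparable.

## Engines

**Langevin (SL only).**  `η dx = −(ω E_c′ + E_e′) dt + √(2 η kB T) dW`,
integrated with the Leimkuhler–Matthews averaged-noise scheme
`x_{n+1} = x_n + dt F/η + σ (ξ_n + ξ_{n+1})/2`, which has *exact*
Gaussian stationary statistics at any stable step and second-order
accuracy for the stationary distribution generally.  Where
`dt·E_t″/η > 0.8` (the harmonic walls) the drift is applied through a
linearized implicit update instead, so the scheme cannot blow up.  The
default `dt = 0.5 ns` keeps `dt·k/η ≤ 0.37` inside the wells; at
`dt = 1 ns` a small but measurable bias in the relative well weights
appears (we measured S0 occupancy 0.055 vs the Boltzmann 0.021 at
dt = 1, converged at dt ≤ 0.5), hence 0.5 ns is the default and the
Boltzmann-stationarity test runs there.  Chemistry, well classification
and the mechanics solve are operator-split and run every 8 diffusion
steps (4 ns, still 10³–10⁶ times finer than any chemical timescale);
single-step public wrappers use every step.  Standard normals are
pre-drawn in blocks with numpy's ziggurat generator and streamed to the
numba kernel.  Attached motors are classified into S0/S1/S2 by the
positions of the two E_t maxima, interpolated from a table on an x0
grid (0.25 nm spacing; degenerate anchors fall back to midpoint
boundaries); a position exactly on a maximum belongs to the forward
well.

**Markov (all scenarios).**  The four power-stroke rates are tabulated
at 10² intervals of x0 ∈ [−20, 20] nm (101 nodes, linear interpolation
between nodes).  Nodes where the loaded landscape has lost a well
(x0 ≳ 13.6 nm under the default stretch — the elastic slope exceeds the
maximal biochemical force) are flagged and filled by log-linear
extrapolation from valid neighbours, with a warning.  Each step, every
non-D motor's position is redrawn from its local distribution: the
two-sided elastic Boltzmann law when detached/weak; a Gaussian at the
elastically shifted minimum `x̄/(1 + k/k_c)` with variance
`kB T/(k_c + k)` when attached in SL (exact for the parabolic
approximation, ~12% narrow relative to the true anharmonic well — an
exact rejection sampler is provided and used as the test oracle); a
point mass at the unshifted minimum for the sharp scenarios.
Strain-dependent detachment is evaluated at the sampled position, so it
sees thermal fluctuations of the stretch — the purpose of the draw.
Time stepping is fixed-step with an adaptive cap: no motor's total exit
probability may exceed 0.1 per step (`dt ≤ 0.1/max Σ rates`, bounded by
2 µs).  Fixed-step rather than event-driven because the rates move
continuously with the filament coordinate.

**RNG.**  Each ensemble carries a `SeedSequence`; every kernel call
consumes a freshly spawned 32-bit seed (numba kernels keep one global
stream per call, the noise blocks use independent numpy Generators).
Runs are bit-reproducible for a fixed master seed.  Changing the
ensemble size reshuffles individual trajectories (a single stream is
shared across motors); only whole-run reproducibility is guaranteed.

## Half-sarcomere mechanics and protocols

N_Fil × N_XB heads (default 4 × 38) act in parallel on rigid filaments
sharing the Z-line coordinate z (z = 0 optimal length).  Total tension
is the sum of `k± x` over attached heads.  While attached,
`x0(t) = x(t_a) + z(t) − z(t_a)`: filament sliding shifts x and x0 of
attached heads together and leaves detached heads alone.

* **Isometric**: z clamped; plateau statistics (T0, populations, force
  per attached head) averaged over the final third of the run.
* **Isotonic**: after the isometric rise, the external force F is held
  and z follows from exact mechanical equilibrium each step — Newton on
  the convex piecewise-linear total elastic force, solved to machine
  precision (so an interval of pure power strokes obeys the
  sliding-velocity identity Δz = mean per-head stroke displacement
  exactly).  A per-step slide cap of 5 nm is the one numerical guard: it
  binds only when the attached set collapses under high load and the
  exact solve would otherwise teleport a lone newly attached head beyond
  the dislodging threshold, ratcheting z unphysically.  Runs whose
  attached population hits zero under load are flagged `yielded` and
  the velocity is fitted to the pre-collapse window.  Steady velocity:
  linear fit of z(t) over the late loaded phase, in nm/ms (positive =
  shortening).  The four-phase transient (elastic drop, rapid early
  shortening, pause, steady shortening) is detected by slopes over
  log-spaced windows, so the millisecond power-stroke phase and the
  hundredfold-slower steady phase are both resolved.
* **Length step**: an instantaneous z jump −δ on the isometric plateau
  (release δ > 0).  T1 is the tension at the first post-step sample
  (0.01 ms sampling by default); T2 the smoothed tension at the time of
  the S2-population maximum — provided that maximum stands out from
  counting noise (at least 2 heads' worth and 1.5× the median),
  otherwise the summaries are flagged undefined; r = 1/(time from the
  step until the tension reaches ⅔ T2), in 1/ms, with an
  exponential-fit rate as a cross-check diagnostic (for a pure
  exponential the rule gives exactly λ/ln 3).
* Fiber protocols run at 4 °C, heart-like runs at 37 °C.

Hill fitting: least squares of `v = b (T0 − F)/(F + a)` with
`v_max = b T0 / a`.

## Validation

The acceptance suite (tests/test_acceptance.py) checks, at desk scale:
the parabolic stiffness against its printed value (5%, absorbing the
kB T rounding); Boltzmann stationarity of the integrator at anchors
−4/0/+4 nm (25 000 motors × 400 steps = 10⁷ steps per anchor,
initialized from the exact rejection-sampled Boltzmann law, χ² on 40
equiprobable quadrature bins, α = 0.01 — a single 10⁷-step trajectory
cannot resolve the inter-well weights, whose exchange time is ~0.3 ms);
detailed balance of the tabulated SL rates against independent
quadrature (5% at every non-degenerate node with barrier > 1 kB T);
the harmonic Kramers closed form at barriers ≥ 8 kB T (20%); the
analytic minimum-shift formula (5% of d at k/k_c ≤ 0.1);
Langevin/Markov agreement on a 40-motor, 50-ms isometric run (≤ 3
pooled time-block standard errors); isometric S1 shares, cross-scenario
orderings (tension, attached fraction, force per head, velocity at
relative loads 0.2/0.5/0.8, four-phase transient, recovery-rate
ordering at δ = 5.6 nm), and backward-jump statistics at 37 °C.
Isometric studies use 10 seeds × 0.5 s simulated (the plateau is reached
by ~0.15 s and the S1 share converges on the ~30 ms attachment-lifetime
timescale); the highest-load isotonic runs use a doubled ensemble
(8 × 38) because near T0 the 152-head fiber occasionally yields by
dislodging cascade.

Two checks fail under the shipped working constants and are reported as
such rather than tuned: the sharp-scenario S1 shares come out ~18%
(SRII) and ~5% (SRI) against the reference 29%/12% (the share is set by
the ratio of the strongly suppressed forward rate to detachment at the
attachment strain; no single constant moves both while keeping SL at
its matching 43%), and the 37 °C backward-jump count per SL attachment
is ~1.3 against the reference ≈5 (Q10 = 2 accelerates detachment ×9.9
from 4 °C while β accelerates the backward rates only ×4–7, so the
4 °C value of 3.4 falls to 1.3 at heart temperature).  Both magnitudes
depend on attachment/detachment constants this package had to choose
itself; every qualitative contrast between the scenarios holds.

## What the simulations do and do not show

The generator of all data is the model itself; there is no external
data.  Passing tests therefore demonstrate internal consistency (engine
against engine, rates against quadrature, dynamics against closed
forms) and the robustness of the wide-vs-sharp orderings under the
stated conditions — not agreement with any particular muscle.  Known
limitations: rigid filaments (no series compliance, so T1 here is
purely cross-bridge elastic), no rigor states, no explicit
Pi/ADP-release substates, a scalar activation in place of
calcium/cooperativity/overlap kinetics, uniform-sarcomere fibers, and
no organ-scale coupling.  The compressive stiffness k⁻ and all
attachment/detachment constants are working values, labeled as such in
the configuration provenance (`crossbridge params dump`).
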