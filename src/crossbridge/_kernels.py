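"""Numba-compiled inner loops for the Langevin and Markov engines.

Everything here operates on plain float64/int64 arrays; the public
engine modules own the dataclasses and translate to/from this layer.
State codes: chem 0 = D, 1 = W, 2 = S (Langevin) or 2/3/4 = S0/S1/S2
(Markov).  Event-direction codes: 0 attach, 1 detach, 2 dislodge,
3 forward jump, 4 backward jump.

Each kernel call seeds numba's global RNG stream; callers must pass a
fresh (deterministically derived) seed per call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# counter indices
C_ATTACH, C_DETACH, C_DISLODGE, C_FWD, C_BACK, C_NOATT = 0, 1, 2, 3, 4, 5
N_COUNTERS = 6

# direction codes for the event log
DIR_ATTACH, DIR_DETACH, DIR_DISLODGE, DIR_FWD, DIR_BACK = 0, 1, 2, 3, 4


@njit(cache=True, inline="always")
def _ec_force(u, H, d, alpha, Fatp, kwall, ulo, uhi):
    """-dE_c/du of the tilted sinusoid with C1 harmonic walls."""
    w = 2.0 * np.pi / d
    if u < ulo:
        return -(H * w * np.cos(w * ulo + alpha) + Fatp + kwall * (u - ulo))
    if u > uhi:
        return -(H * w * np.cos(w * uhi + alpha) + Fatp + kwall * (u - uhi))
    return -(H * w * np.cos(w * u + alpha) + Fatp)


@njit(cache=True, inline="always")
def _ec_stiff(u, H, d, kwall, alpha, ulo, uhi):
    w = 2.0 * np.pi / d
    if u < ulo or u > uhi:
        return kwall
    return -H * w * w * np.sin(w * u + alpha)


@njit(cache=True, inline="always")
def _interp_uniform(g0, dg, yg, x):
    """Linear interpolation on a uniform grid (clamped at the ends)."""
    s = (x - g0) / dg
    if s <= 0.0:
        return yg[0]
    n = yg.shape[0]
    if s >= n - 1:
        return yg[n - 1]
    i = int(s)
    f = s - i
    return yg[i] * (1.0 - f) + yg[i + 1] * f


@njit(cache=True, inline="always")
def _sample_detached_x(kBT, kp, km):
    """Draw from the two-sided Boltzmann density of the bare elastic
    element, exp(-beta k(x) x^2 / 2) with asymmetric stiffness."""
    sp = np.sqrt(kBT / kp) if kp > 0 else 0.0
    sm = np.sqrt(kBT / km) if km > 0 else 0.0
    if sp + sm <= 0.0:
        return 0.0
    if np.random.random() < sp / (sp + sm):
        return abs(np.random.normal()) * sp
    return -abs(np.random.normal()) * sm


@njit(cache=True, inline="always")
def _solve_dz(x, chem, att_code, F_ext, kp, km, n):
    """Newton solve for the filament shift dz restoring total elastic
    tension to F_ext; exact for the piecewise-linear force (the total
    tension is convex in dz because k+ >= k-)."""
    dz = 0.0
    for _ in range(200):
        T = 0.0
        K = 0.0
        for i in range(n):
            if chem[i] >= att_code:
                xi = x[i] + dz
                k = kp if xi >= 0.0 else km
                T += k * xi
                K += k
        if K <= 0.0:
            return 0.0, False
        err = F_ext - T
        if abs(err) < 1e-9 * (1.0 + abs(F_ext)):
            return dz, True
        dz += err / K
    return dz, True


@njit(cache=True, fastmath=True)
def langevin_run(
    seed,
    # state (in/out)
    x, chem, x0, ta, xi_prev, well,
    zt,                      # float64[2]: z, t
    noise,                   # (n_steps, n) pre-drawn standard normals
    step_offset,             # global step counter at entry (for cadences)
    n_steps, dt, do_diff, do_chem, chem_every,
    # landscape
    H, d, alpha, Fatp, kp, km, eta, kBT, kwall, ulo, uhi,
    # chemistry (already Q10/activation-scaled, 1/ns)
    kdw, kwd, fmax, xlim, gslope, gneg, xdis,
    # protocol: 0 isometric (z fixed), 1 isotonic (solve z for F_ext);
    # dz_cap bounds the per-step slide (only binds when the attached set
    # collapses and the exact solve would teleport a lone head)
    z_mode, F_ext, dz_cap,
    # well-boundary tables on a uniform x0 grid
    bg0, bdg, b1g, b2g,
    # sampling of ensemble observables every `sample_every` steps
    sample_every, out_t, out_T, out_z, out_pop, out_idx,
    # counters and per-motor tallies
    ctr, pm_attach, pm_back,
    # motor-0 trajectory recording every `rec_every` steps
    rec_every, rec_x, rec_chem, rec_well, rec_idx,
):
    np.random.seed(seed)
    n = x.shape[0]
    z = zt[0]
    t = zt[1]
    sig = np.sqrt(2.0 * kBT * dt / eta)
    inv_eta = 1.0 / eta
    # chemistry, well classification and the mechanics solve run every
    # chem_every steps (timescales ~us-ms vs the ns diffusion step)
    dt_chem = dt * chem_every

    for step in range(n_steps):
        gstep = step_offset + step
        if do_diff == 1:
            for i in range(n):
                xi = x[i]
                if chem[i] == 2:
                    u = xi - x0[i]
                    F = _ec_force(u, H, d, alpha, Fatp, kwall, ulo, uhi)
                    kloc = _ec_stiff(u, H, d, kwall, alpha, ulo, uhi)
                else:
                    F = 0.0
                    kloc = 0.0
                if xi >= 0.0:
                    F -= kp * xi
                    kloc += kp
                else:
                    F -= km * xi
                    kloc += km
                xin = noise[step, i]
                nz = sig * 0.5 * (xi_prev[i] + xin)
                xi_prev[i] = xin
                c = dt * kloc * inv_eta
                if c > 0.8:
                    # linearized implicit update in stiff (wall) regions
                    x[i] = xi + (dt * F * inv_eta + nz) / (1.0 + c)
                else:
                    x[i] = xi + dt * F * inv_eta + nz

        if (gstep + 1) % chem_every == 0:
            if do_chem == 1:
                for i in range(n):
                    ci = chem[i]
                    xi = x[i]
                    if ci == 0:
                        if np.random.random() < kdw * dt_chem:
                            chem[i] = 1
                    elif ci == 1:
                        r = np.random.random()
                        p_wd = kwd * dt_chem
                        p_ws = 0.0
                        if 0.0 < xi:
                            f = fmax * (xi / xlim)
                            if f > fmax:
                                f = fmax
                            p_ws = f * dt_chem
                        if r < p_wd:
                            chem[i] = 0
                        elif r < p_wd + p_ws:
                            chem[i] = 2
                            x0[i] = xi
                            ta[i] = t
                            well[i] = 0
                            ctr[C_ATTACH] += 1
                            pm_attach[i] += 1
                    else:  # attached
                        if abs(xi) > xdis:
                            chem[i] = 0
                            well[i] = -1
                            x[i] = 0.0  # elastic element snaps back on dislodging
                            ctr[C_DISLODGE] += 1
                            continue
                        g = gslope * xi if xi > 0.0 else (gneg if xi < 0.0 else 0.0)
                        if g > 0.0 and np.random.random() < g * dt_chem:
                            chem[i] = 0
                            well[i] = -1
                            ctr[C_DETACH] += 1

            # well classification and jump bookkeeping for attached motors
            for i in range(n):
                if chem[i] == 2:
                    b1 = x0[i] + _interp_uniform(bg0, bdg, b1g, x0[i])
                    b2 = x0[i] + _interp_uniform(bg0, bdg, b2g, x0[i])
                    w_new = 0 if x[i] < b1 else (1 if x[i] < b2 else 2)
                    w_old = well[i]
                    if w_old >= 0 and w_new != w_old:
                        if w_new > w_old:
                            ctr[C_FWD] += w_new - w_old
                        else:
                            ctr[C_BACK] += w_old - w_new
                            pm_back[i] += w_old - w_new
                    well[i] = w_new

        if z_mode == 1 and (gstep + 1) % chem_every == 0:
            dz, ok = _solve_dz(x, chem, 2, F_ext, kp, km, n)
            if ok:
                if dz > dz_cap:
                    dz = dz_cap
                elif dz < -dz_cap:
                    dz = -dz_cap
                z += dz
                for i in range(n):
                    if chem[i] == 2:
                        x[i] += dz
                        x0[i] += dz
            else:
                ctr[C_NOATT] += 1

        t += dt

        if sample_every > 0 and (gstep + 1) % sample_every == 0:
            j = out_idx[0]
            if j < out_t.shape[0]:
                T = 0.0
                nD = 0
                nW = 0
                nS = np.zeros(3, dtype=np.int64)
                for i in range(n):
                    if chem[i] == 2:
                        k = kp if x[i] >= 0.0 else km
                        T += k * x[i]
                        nS[well[i]] += 1
                    elif chem[i] == 0:
                        nD += 1
                    else:
                        nW += 1
                out_t[j] = t
                out_T[j] = T
                out_z[j] = z
                out_pop[j, 0] = nD
                out_pop[j, 1] = nW
                out_pop[j, 2] = nS[0]
                out_pop[j, 3] = nS[1]
                out_pop[j, 4] = nS[2]
                out_idx[0] = j + 1

        if rec_every > 0 and (gstep + 1) % rec_every == 0:
            j = rec_idx[0]
            if j < rec_x.shape[0]:
                rec_x[j] = x[0]
                rec_chem[j] = chem[0]
                rec_well[j] = well[0]
                rec_idx[0] = j + 1

    zt[0] = z
    zt[1] = t


@njit(cache=True, fastmath=True)
def markov_run(
    seed,
    # state (in/out): chem 0=D,1=W,2/3/4=S0/S1/S2; xs = sampled position
    chem, x0, xs, ta,
    zt,                      # float64[2]: z, t
    t_end, dt_max, p_cap,
    # within-well sampling
    d, kp, km, kBT, kc, sharp,
    # power-stroke rate tables on a uniform x0 grid (1/ns)
    g0, dg, k01g, k10g, k12g, k21g,
    # chemistry (already Q10/activation-scaled, 1/ns)
    kdw, kwd, fmax, xlim, gslope, gneg, xdis,
    z_mode, F_ext, dz_cap,
    # uniform-time sampling
    sample_dt, out_t, out_T, out_z, out_pop, out_idx,
    ctr, pm_attach, pm_back,
    # optional event log (capacity-bounded; ev_cap = ev_t.shape[0])
    log_events, ev_t, ev_motor, ev_from, ev_to, ev_dir, ev_idx,
):
    np.random.seed(seed)
    n = chem.shape[0]
    z = zt[0]
    t = zt[1]
    next_sample = t + sample_dt if sample_dt > 0 else 1e300

    rates = np.zeros((n, 4), dtype=np.float64)  # exit channels per motor
    # hoisted sampling constants
    sp = np.sqrt(kBT / kp) if kp > 0 else 0.0
    sm = np.sqrt(kBT / km) if km > 0 else 0.0
    p_side = sp / (sp + sm) if sp + sm > 0 else 1.0
    shift_p = kc / (kc + kp)
    shift_m = kc / (kc + km)
    sw_p = np.sqrt(kBT / (kc + kp))
    sw_m = np.sqrt(kBT / (kc + km))

    while t < t_end - 1e-9:
        # 1. sample positions (D motors keep a stale xs; nothing reads it)
        for i in range(n):
            ci = chem[i]
            if ci == 0:
                continue
            if ci == 1:
                if np.random.random() < p_side:
                    xs[i] = abs(np.random.normal()) * sp
                else:
                    xs[i] = -abs(np.random.normal()) * sm
            else:
                m0 = x0[i] + (ci - 2) * d
                if sharp == 1:
                    xs[i] = m0
                elif m0 >= 0.0:
                    xs[i] = m0 * shift_p + np.random.normal() * sw_p
                else:
                    xs[i] = m0 * shift_m + np.random.normal() * sw_m

        # 2. rates and the step size from the exit-probability cap
        rmax = 1e-30
        for i in range(n):
            ci = chem[i]
            xi = xs[i]
            r0 = 0.0
            r1 = 0.0
            r2 = 0.0
            r3 = 0.0
            if ci == 0:
                r0 = kdw
            elif ci == 1:
                r0 = kwd
                if xi > 0.0:
                    f = fmax * (xi / xlim)
                    r1 = f if f < fmax else fmax
            else:
                if xi > 0.0:
                    r0 = gslope * xi
                elif xi < 0.0:
                    r0 = gneg
                if ci == 2:
                    r1 = _interp_uniform(g0, dg, k01g, x0[i])
                elif ci == 3:
                    r1 = _interp_uniform(g0, dg, k12g, x0[i])
                    r2 = _interp_uniform(g0, dg, k10g, x0[i])
                else:
                    r2 = _interp_uniform(g0, dg, k21g, x0[i])
            rates[i, 0] = r0
            rates[i, 1] = r1
            rates[i, 2] = r2
            rates[i, 3] = r3
            rtot = r0 + r1 + r2 + r3
            if rtot > rmax:
                rmax = rtot
        dt = dt_max
        if p_cap / rmax < dt:
            dt = p_cap / rmax
        if t + dt > t_end:
            dt = t_end - t
        if t + dt > next_sample:
            dt = next_sample - t

        # 3. transitions
        for i in range(n):
            ci = chem[i]
            xi = xs[i]
            # mechanical dislodging is checked before stochastic exits
            if ci >= 2 and abs(xi) > xdis:
                if log_events == 1 and ev_idx[0] < ev_t.shape[0]:
                    j = ev_idx[0]
                    ev_t[j] = t
                    ev_motor[j] = i
                    ev_from[j] = ci
                    ev_to[j] = 0
                    ev_dir[j] = DIR_DISLODGE
                    ev_idx[0] = j + 1
                chem[i] = 0
                ctr[C_DISLODGE] += 1
                continue
            r = np.random.random()
            p0 = rates[i, 0] * dt
            p1 = p0 + rates[i, 1] * dt
            p2 = p1 + rates[i, 2] * dt
            new = -1
            direction = -1
            if ci == 0:
                if r < p0:
                    new = 1
            elif ci == 1:
                if r < p0:
                    new = 0
                elif r < p1:
                    new = 2
                    direction = DIR_ATTACH
            else:
                if r < p0:
                    new = 0
                    direction = DIR_DETACH
                elif r < p1:
                    new = ci + 1  # forward power stroke
                    direction = DIR_FWD
                elif r < p2:
                    new = ci - 1  # backward jump
                    direction = DIR_BACK
            if new >= 0:
                if direction == DIR_ATTACH:
                    x0[i] = xi
                    ta[i] = t
                    ctr[C_ATTACH] += 1
                    pm_attach[i] += 1
                elif direction == DIR_DETACH:
                    ctr[C_DETACH] += 1
                elif direction == DIR_FWD:
                    ctr[C_FWD] += 1
                elif direction == DIR_BACK:
                    ctr[C_BACK] += 1
                    pm_back[i] += 1
                if direction >= 0 and log_events == 1 and ev_idx[0] < ev_t.shape[0]:
                    j = ev_idx[0]
                    ev_t[j] = t
                    ev_motor[j] = i
                    ev_from[j] = ci
                    ev_to[j] = new
                    ev_dir[j] = direction
                    ev_idx[0] = j + 1
                chem[i] = new

        # 4. mechanics
        if z_mode == 1:
            dz, ok = _solve_dz(xs, chem, 2, F_ext, kp, km, n)
            if ok:
                if dz > dz_cap:
                    dz = dz_cap
                elif dz < -dz_cap:
                    dz = -dz_cap
                z += dz
                for i in range(n):
                    if chem[i] >= 2:
                        xs[i] += dz
                        x0[i] += dz
            else:
                ctr[C_NOATT] += 1

        t += dt

        if sample_dt > 0 and t >= next_sample - 1e-9:
            j = out_idx[0]
            if j < out_t.shape[0]:
                T = 0.0
                nD = 0
                nW = 0
                nS = np.zeros(3, dtype=np.int64)
                for i in range(n):
                    ci = chem[i]
                    if ci >= 2:
                        k = kp if xs[i] >= 0.0 else km
                        T += k * xs[i]
                        nS[ci - 2] += 1
                    elif ci == 0:
                        nD += 1
                    else:
                        nW += 1
                out_t[j] = t
                out_T[j] = T
                out_z[j] = z
                out_pop[j, 0] = nD
                out_pop[j, 1] = nW
                out_pop[j, 2] = nS[0]
                out_pop[j, 3] = nS[1]
                out_pop[j, 4] = nS[2]
                out_idx[0] = j + 1
            next_sample += sample_dt

    zt[0] = z
    zt[1] = t
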