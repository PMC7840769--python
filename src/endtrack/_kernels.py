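"""Compiled trajectory kernels (numba).

The enzyme's overdamped Langevin dynamics are integrated with a
Metropolis-adjusted Langevin (MALA) step: the Euler–Maruyama proposal

    x' = x + D f(x) dt + sqrt(2 D dt) eta

is accepted with probability min(1, e^{U(x)-U(x')} q(x|x')/q(x'|x)).
The Metropolis correction makes the Boltzmann distribution exactly
stationary at any step size, which matters here because well-escape
rates carry an Arrhenius factor: unadjusted Euler at a feasible step
inflates the in-well variance and with it the escape rate severalfold,
while an in-well-exact Ornstein–Uhlenbeck update suppresses edge
crossings and understates it.  MALA reproduces the continuum mean
escape time of the 10 k_BT well to within a few percent at the standard
step (checked against the closed-form double-quadrature value).
:func:`endtrack.ratchet.step_enzyme` keeps the plain Euler form as the
readable reference discretisation of the same equation.

Treadmilling is a deterministic countdown clock: every
``round(L0/(V_Z dt))`` steps the shrinking-end subunit (and its well)
disappears and a new subunit appears beyond the growing end.  Gaussian
and uniform variates are drawn in blocks; each kernel seeds numba's
MT19937 stream once per call, so a trajectory is reproducible from its
integer seed.

Nearest-subunit resolution uses ``rint`` on the lattice coordinate whose
half-way tie-break (round-half-even) differs from the reference
implementation's smaller-index rule only on a measure-zero set.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BLOCK = 16384


@njit(cache=True, fastmath=True, inline="always")
def _force_energy(x, xs, n_sub, L0, a, U0, inv_L0, k_well):
    """Force (k_BT/nm) and energy (k_BT) of the nearest-live-subunit well."""
    u = (x - xs) * inv_L0
    if u < 0.0:
        u = 0.0
    elif u > n_sub - 1.0:
        u = n_sub - 1.0
    dxw = x - xs - np.rint(u) * L0
    if -a <= dxw <= a:
        return -k_well * dxw, -U0 * (1.0 - (dxw * dxw) / (a * a))
    return 0.0, 0.0


@njit(cache=True, fastmath=True)
def trajectory_kernel(
    seed,
    x0,
    xs0,
    n_sub,
    L0,
    a,
    U0,
    D,
    vz,
    dt,
    n_steps,
    record_every,
    margin,
    persist_steps,
):
    """Integrate one enzyme on one treadmilling filament.

    Returns ``(rec_x, rec_xs, rec_bound, n_rec, first_out_step, end_step)``
    where ``first_out_step`` is the first step index at which the enzyme
    was more than ``margin`` nm beyond either filament end (-1 if never),
    and the run terminates early once it has been continuously outside
    for ``persist_steps`` steps.
    """
    np.random.seed(seed)
    n_rec_max = n_steps // record_every + 1
    rec_x = np.empty(n_rec_max)
    rec_xs = np.empty(n_rec_max)
    rec_bound = np.zeros(n_rec_max, dtype=np.uint8)

    x = x0
    xs = xs0
    span = (n_sub - 1) * L0
    sig2 = 2.0 * D * dt
    sig = np.sqrt(sig2)
    k_well = 2.0 * U0 / (a * a)
    spe = int(round(L0 / (vz * dt))) if vz > 0 else 0
    cd = spe
    inv_L0 = 1.0 / L0
    Ddt = D * dt

    fx, ux = _force_energy(x, xs, n_sub, L0, a, U0, inv_L0, k_well)
    rec_x[0] = x
    rec_xs[0] = xs
    rec_bound[0] = 1 if ux < 0.0 else 0
    n_rec = 1

    first_out = np.int64(-1)
    out_run = 0
    end_step = n_steps
    i = 0
    stop = False
    rec_cd = record_every
    lo_bound = xs - margin
    hi_bound = xs + span + margin
    while i < n_steps and not stop:
        m = n_steps - i
        if m > _BLOCK:
            m = _BLOCK
        buf = np.random.standard_normal(m)
        unif = np.random.random(m)
        for j in range(m):
            drift = Ddt * fx
            xp = x + drift + sig * buf[j]
            fp, up = _force_energy(xp, xs, n_sub, L0, a, U0, inv_L0, k_well)
            rev = x - xp - Ddt * fp
            fwd = sig * buf[j]
            loga = (ux - up) + (fwd * fwd - rev * rev) / (2.0 * sig2)
            if loga >= 0.0 or unif[j] < np.exp(loga):
                x = xp
                fx = fp
                ux = up
            if spe > 0:
                cd -= 1
                if cd == 0:
                    xs += L0
                    lo_bound += L0
                    hi_bound += L0
                    cd = spe
                    fx, ux = _force_energy(
                        x, xs, n_sub, L0, a, U0, inv_L0, k_well
                    )
            i += 1
            if x < lo_bound or x > hi_bound:
                if first_out < 0:
                    first_out = i
                out_run += 1
                if out_run >= persist_steps:
                    end_step = i
                    stop = True
            else:
                out_run = 0
            rec_cd -= 1
            if rec_cd == 0:
                rec_cd = record_every
                rec_x[n_rec] = x
                rec_xs[n_rec] = xs
                rec_bound[n_rec] = 1 if ux < 0.0 else 0
                n_rec += 1
            if stop:
                break
    return rec_x, rec_xs, rec_bound, n_rec, first_out, end_step


@njit(cache=True, fastmath=True)
def multi_enzyme_kernel(
    seed,
    x0,
    xs0,
    n_sub,
    L0,
    a,
    U0,
    D,
    vz,
    dt,
    n_steps,
    record_every,
    margin,
    persist_steps,
    exclusion,
):
    """Several enzymes on one filament with optional hard-core exclusion.

    Enzymes take MALA steps sequentially in index order; with
    ``exclusion`` nonzero a proposed move that would bring two enzymes
    closer than ``L0`` (one subunit diameter) is rejected outright, which
    realises the knock-off interaction as a hard-core constraint.
    Returns per-enzyme recorded positions and first-escape steps; the run
    ends when every enzyme has been continuously beyond ``margin`` of
    both filament ends for ``persist_steps`` steps.
    """
    np.random.seed(seed)
    n_e = x0.size
    n_rec_max = n_steps // record_every + 1
    rec_x = np.empty((n_e, n_rec_max))
    rec_xs = np.empty(n_rec_max)

    x = x0.copy()
    xs = xs0
    span = (n_sub - 1) * L0
    sig2 = 2.0 * D * dt
    sig = np.sqrt(sig2)
    k_well = 2.0 * U0 / (a * a)
    spe = int(round(L0 / (vz * dt))) if vz > 0 else 0
    cd = spe
    inv_L0 = 1.0 / L0
    Ddt = D * dt

    for e in range(n_e):
        rec_x[e, 0] = x[e]
    rec_xs[0] = xs
    n_rec = 1

    first_out = -np.ones(n_e, dtype=np.int64)
    out_run = np.zeros(n_e, dtype=np.int64)
    end_step = n_steps
    i = 0
    stop = False
    rec_cd = record_every
    while i < n_steps and not stop:
        m = n_steps - i
        if m > _BLOCK:
            m = _BLOCK
        buf = np.random.standard_normal(m * n_e)
        unif = np.random.random(m * n_e)
        for j in range(m):
            for e in range(n_e):
                xe = x[e]
                fx, ux = _force_energy(xe, xs, n_sub, L0, a, U0, inv_L0, k_well)
                xp = xe + Ddt * fx + sig * buf[j * n_e + e]
                blocked = False
                if exclusion != 0:
                    for g in range(n_e):
                        if g != e and abs(xp - x[g]) < L0:
                            blocked = True
                            break
                if blocked:
                    continue
                fp, up = _force_energy(xp, xs, n_sub, L0, a, U0, inv_L0, k_well)
                rev = xe - xp - Ddt * fp
                fwd = sig * buf[j * n_e + e]
                loga = (ux - up) + (fwd * fwd - rev * rev) / (2.0 * sig2)
                if loga >= 0.0 or unif[j * n_e + e] < np.exp(loga):
                    x[e] = xp
            if spe > 0:
                cd -= 1
                if cd == 0:
                    xs += L0
                    cd = spe
            i += 1
            all_out = True
            for e in range(n_e):
                if x[e] < xs - margin or x[e] > xs + span + margin:
                    if first_out[e] < 0:
                        first_out[e] = i
                    out_run[e] += 1
                    if out_run[e] < persist_steps:
                        all_out = False
                else:
                    out_run[e] = 0
                    all_out = False
            if all_out:
                end_step = i
                stop = True
            rec_cd -= 1
            if rec_cd == 0:
                rec_cd = record_every
                for e in range(n_e):
                    rec_x[e, n_rec] = x[e]
                rec_xs[n_rec] = xs
                n_rec += 1
            if stop:
                break
    return rec_x, rec_xs, n_rec, first_out, end_step


@njit(cache=True, fastmath=True)
def catchup_kernel(seed, D, dt, a, L0, fail_dist, max_steps):
    """One catch-up attempt after loss of the end subunit.

    The enzyme starts at the departed subunit's former center (x = 0) on a
    flat landscape; the next live well starts at ``L0 - a``.  Success is
    reaching the well edge; failure is falling ``fail_dist`` nm behind.
    Free diffusion needs no Metropolis correction.  Returns
    ``(n_steps_taken, success)``.
    """
    np.random.seed(seed)
    x = 0.0
    sig = np.sqrt(2.0 * D * dt)
    target = L0 - a
    i = 0
    while i < max_steps:
        m = max_steps - i
        if m > _BLOCK:
            m = _BLOCK
        buf = np.random.standard_normal(m)
        for j in range(m):
            x += sig * buf[j]
            i += 1
            if x >= target:
                return i, True
            if x <= -fail_dist:
                return i, False
    return i, False
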