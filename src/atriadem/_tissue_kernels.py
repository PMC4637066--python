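"""Numba kernels for tissue-scale simulation: vectorised DEM contact forces,
centred-difference clump motion, per-step area-conserving resizing, and the
full electromechanical cycle (coupling currents -> cell ODE step -> target
lengths -> resize -> DEM step).

Mechanics works in SI units (m, kg, s, N); the cell model side works in
mV/ms/pA/um.  Clump poses are (x, y, theta) with the clump axis
(cos theta, sin theta); the fibre direction corresponds to theta = pi/2.
"""

import math

import numpy as np
from numba import njit

from ._cell_kernels import (
    NVAR, NEXTRA, IV, ICA_I, ISL, cell_rhs, euler_step, active_force,
)

DENSITY = 1053.0      # kg/m^3

# Gauss-Legendre nodes for the lens polar-moment quadrature (compile-time
# constants inside the jitted functions).
_GL_X, _GL_W = np.polynomial.legendre.leggauss(32)


@njit(cache=True)
def lens_area_nb(r, d):
    return (2.0 * r * r * math.acos(d / (2.0 * r))
            - 0.5 * d * math.sqrt(4.0 * r * r - d * d))


@njit(cache=True)
def clump_area_nb(n, r, d):
    return n * math.pi * r * r - (n - 1) * lens_area_nb(r, d)


@njit(cache=True)
def lens_polar_moment_nb(r, d):
    """Second polar moment of the two-disc lens about its own centre, via
    Gauss-Legendre quadrature after u = r sin(phi)."""
    if d >= 2.0 * r:
        return 0.0
    phi0 = math.asin(d / (2.0 * r))
    half = 0.5 * (0.5 * math.pi - phi0)
    acc = 0.0
    for i in range(_GL_X.shape[0]):
        phi = half * (_GL_X[i] + 1.0) + phi0
        c = r * math.cos(phi)
        s = r * math.sin(phi) - 0.5 * d
        acc += _GL_W[i] * (2.0 * s * s * c + (2.0 / 3.0) * c ** 3) * c
    return 2.0 * half * acc


@njit(cache=True)
def union_polar_moment_nb(n, r, d):
    j = n * math.pi * r ** 4 / 2.0
    half = (n - 1) / 2.0
    for k in range(n):
        off = (k - half) * d
        j += math.pi * r * r * off * off
    if n >= 2:
        s = lens_area_nb(r, d)
        jl = lens_polar_moment_nb(r, d)
        for k in range(n - 1):
            mid = (k + 0.5 - half) * d
            j -= jl + s * mid * mid
    return j


@njit(cache=True)
def solve_resize(L, A, n, r_init):
    """Solve length/area relations for (r, d) at fixed particle count.

    Newton iteration on the scalar area residual in r (d eliminated via the
    length relation), warm-started from ``r_init`` and safeguarded by the
    feasibility bracket r in (L/2n, L/2).  Relative tolerance 1e-12 on A.
    """
    r_lo = L / (2.0 * n)
    r_hi = L / 2.0
    r = r_init
    if r <= r_lo or r >= r_hi:
        r = 0.5 * (r_lo + r_hi)
    nm1 = n - 1.0
    for _ in range(100):
        d = (L - 2.0 * r) / nm1
        f = clump_area_nb(n, r, d) - A
        if abs(f) <= 1e-12 * A:
            return r, d
        h = 1e-7 * r
        d1 = (L - 2.0 * (r + h)) / nm1
        d2 = (L - 2.0 * (r - h)) / nm1
        df = (clump_area_nb(n, r + h, d1) - clump_area_nb(n, r - h, d2)) / (2.0 * h)
        step = f / df
        r_new = r - step
        if r_new <= r_lo or r_new >= r_hi:
            # bisect toward the feasible side
            if f > 0.0:
                r_new = 0.5 * (r + r_lo)
            else:
                r_new = 0.5 * (r + r_hi)
        r = r_new
    return -1.0, -1.0    # no convergence (caller raises)


@njit(cache=True)
def dem_forces(pos, theta, vel, omega, rr, dd, npart, mass,
               ca, ka, cb, kb, fs, kn, ks, betan, betas, dt,
               fx, fy, mz):
    """One force pass over all contacts; accumulates into fx, fy, mz."""
    fx[:] = 0.0
    fy[:] = 0.0
    mz[:] = 0.0
    half = (npart - 1) / 2.0
    for i in range(ca.shape[0]):
        A = ca[i]
        B = cb[i]
        axA = math.cos(theta[A])
        ayA = math.sin(theta[A])
        axB = math.cos(theta[B])
        ayB = math.sin(theta[B])
        offa = (ka[i] - half) * dd[A]
        offb = (kb[i] - half) * dd[B]
        pax = pos[A, 0] + offa * axA
        pay = pos[A, 1] + offa * ayA
        pbx = pos[B, 0] + offb * axB
        pby = pos[B, 1] + offb * ayB
        dx = pax - pbx
        dy = pay - pby
        dist = math.sqrt(dx * dx + dy * dy)
        nx = dx / dist
        ny = dy / dist
        tx = -ny
        ty = nx
        gs = dist - (rr[A] + rr[B])
        # contact plane location: midpoint of the interaction region
        xcx = pbx + (rr[B] + 0.5 * gs) * nx
        xcy = pby + (rr[B] + 0.5 * gs) * ny
        # rigid-body surface velocities (clump centroid + rotation)
        vax = vel[A, 0] - omega[A] * (xcy - pos[A, 1])
        vay = vel[A, 1] + omega[A] * (xcx - pos[A, 0])
        vbx = vel[B, 0] - omega[B] * (xcy - pos[B, 1])
        vby = vel[B, 1] + omega[B] * (xcx - pos[B, 0])
        rvx = vax - vbx
        rvy = vay - vby
        dn = rvx * nx + rvy * ny
        ds = rvx * tx + rvy * ty
        fs[i] += -ks * ds * dt
        mc = mass[A] * mass[B] / (mass[A] + mass[B])
        fn = -(kn * gs + 2.0 * betan * math.sqrt(mc * kn) * dn)
        ft = fs[i] - 2.0 * betas * math.sqrt(mc * ks) * ds
        Fx = fn * nx + ft * tx
        Fy = fn * ny + ft * ty
        fx[A] += Fx
        fy[A] += Fy
        fx[B] -= Fx
        fy[B] -= Fy
        mz[A] += (xcx - pos[A, 0]) * Fy - (xcy - pos[A, 1]) * Fx
        mz[B] -= (xcx - pos[B, 0]) * Fy - (xcy - pos[B, 1]) * Fx


@njit(cache=True)
def _damp(f, v, alpha):
    # local non-viscous damping: oppose motion with alpha*|F|
    if v > 0.0:
        return f - alpha * abs(f)
    if v < 0.0:
        return f + alpha * abs(f)
    return f


@njit(cache=True)
def integrate_clumps(pos, theta, vel, omega, fx, fy, mz, mass, inertia,
                     fixed_x, fixed_y, rot_lock, dt, alpha=0.7):
    for c in range(pos.shape[0]):
        if fixed_x[c]:
            vel[c, 0] = 0.0
        else:
            vel[c, 0] += _damp(fx[c], vel[c, 0], alpha) / mass[c] * dt
        if fixed_y[c]:
            vel[c, 1] = 0.0
        else:
            vel[c, 1] += _damp(fy[c], vel[c, 1], alpha) / mass[c] * dt
        if rot_lock:
            omega[c] = 0.0
        else:
            omega[c] += _damp(mz[c], omega[c], alpha) / inertia[c] * dt
        pos[c, 0] += vel[c, 0] * dt
        pos[c, 1] += vel[c, 1] * dt
        theta[c] += omega[c] * dt


@njit(cache=True)
def unbalanced_ratio(pos, theta, vel, omega, rr, dd, npart, mass,
                     ca, ka, cb, kb, fs, kn, ks, betan, betas,
                     fx, fy, mz):
    """Mean resultant force on clumps / mean contact normal-force magnitude.

    Evaluated with dt = 0 (no shear increment), so it is a pure residual
    measurement.  Returns the ratio, or the mean resultant force itself
    (in N) when all contact forces vanish.
    """
    dem_forces(pos, theta, vel, omega, rr, dd, npart, mass,
               ca, ka, cb, kb, fs, kn, ks, betan, betas, 0.0, fx, fy, mz)
    mean_res = 0.0
    for c in range(pos.shape[0]):
        mean_res += math.sqrt(fx[c] ** 2 + fy[c] ** 2)
    mean_res /= pos.shape[0]
    mean_con = 0.0
    for i in range(ca.shape[0]):
        A = ca[i]
        B = cb[i]
        half = (npart - 1) / 2.0
        axA = math.cos(theta[A]); ayA = math.sin(theta[A])
        axB = math.cos(theta[B]); ayB = math.sin(theta[B])
        offa = (ka[i] - half) * dd[A]
        offb = (kb[i] - half) * dd[B]
        dx = pos[A, 0] + offa * axA - (pos[B, 0] + offb * axB)
        dy = pos[A, 1] + offa * ayA - (pos[B, 1] + offb * ayB)
        gs = math.sqrt(dx * dx + dy * dy) - (rr[A] + rr[B])
        mean_con += abs(kn * gs)
    if ca.shape[0] > 0:
        mean_con /= ca.shape[0]
    # force floor: a 1 nm mean overlap; below that the assembly is at rest
    # to within geometric noise and the ratio would be 0/0
    denom = max(mean_con, kn * 1e-9)
    return mean_res / denom


@njit(cache=True)
def equilibrate_kernel(pos, theta, vel, omega, rr, dd, npart, mass, inertia,
                       ca, ka, cb, kb, fs, kn, ks, betan, betas,
                       fixed_x, fixed_y, rot_lock, dt, tol, max_steps,
                       check_every, alpha=0.7):
    """DEM-only cycling until the unbalanced-force ratio drops below tol.

    Returns (steps_taken, final_ratio).
    """
    nc = pos.shape[0]
    fx = np.zeros(nc)
    fy = np.zeros(nc)
    mz = np.zeros(nc)
    ratio = unbalanced_ratio(pos, theta, vel, omega, rr, dd, npart, mass,
                             ca, ka, cb, kb, fs, kn, ks, betan, betas,
                             fx, fy, mz)
    if ratio < tol:
        return 0, ratio
    steps = 0
    while steps < max_steps:
        for _ in range(check_every):
            dem_forces(pos, theta, vel, omega, rr, dd, npart, mass,
                       ca, ka, cb, kb, fs, kn, ks, betan, betas, dt,
                       fx, fy, mz)
            integrate_clumps(pos, theta, vel, omega, fx, fy, mz, mass,
                             inertia, fixed_x, fixed_y, rot_lock, dt, alpha)
        steps += check_every
        ratio = unbalanced_ratio(pos, theta, vel, omega, rr, dd, npart,
                                 mass, ca, ka, cb, kb, fs, kn, ks, betan,
                                 betas, fx, fy, mz)
        if ratio < tol:
            break
    return steps, ratio


@njit(cache=True)
def coupling_currents(v, ea, eb, d_ns, ist):
    """Eq.-style neighbour currents: ist[H] += D * (V_i - V_H) per edge
    (nS * mV = pA).  The per-edge contributions are antisymmetric, so the
    coupling part sums to zero over the tissue."""
    ist[:] = 0.0
    for i in range(ea.shape[0]):
        a = ea[i]
        b = eb[i]
        dv = d_ns * (v[b] - v[a])
        ist[a] += dv
        ist[b] -= dv


@njit(cache=True)
def run_tissue_kernel(states, cm, sl0, tmpc, coupled,
                      ea, eb, d_ns,
                      stim_mask, stim_amp_pa, stim_start, stim_dur,
                      mech_on,
                      pos, theta, vel, omega, rr, dd, npart, area0,
                      mass, inertia,
                      ca, ka, cb, kb, fs,
                      kn, ks, betan, betas,
                      fixed_x, fixed_y, rot_lock,
                      l0_um, dt_ms, n_steps, trace_every, snap_every,
                      density=DENSITY, alpha=0.7):
    """The full electromechanical cycle at a shared fixed step.

    Per step: (1) neighbour coupling currents from the previous step's V
    (plus any protocol stimulus), (2) explicit-Euler update of every cell's
    32 ODE variables, (3) target cell lengths from sarcomere length,
    (4) area-conserving clump resize (rotational inertia recomputed),
    (5) DEM contact forces and centred-difference motion update.  With
    ``mech_on`` false, stages 3-5 are skipped (electrics-only mode).

    Returns trace and snapshot arrays plus (clip_count, error_code,
    error_step, error_cell); error codes: 0 ok, 1 non-finite cell state,
    2 resize failed.
    """
    nc = states.shape[0]
    dt_s = dt_ms * 1e-3
    dy = np.empty(NVAR)
    exs = np.empty(NEXTRA)
    ist = np.zeros(nc)
    fx = np.zeros(nc)
    fy = np.zeros(nc)
    mz = np.zeros(nc)

    nt = n_steps // trace_every + 1
    t_trace = np.empty(nt)
    v_tr = np.empty((nt, nc))
    ca_tr = np.empty((nt, nc))
    f_tr = np.empty((nt, nc))
    l_tr = np.empty((nt, nc))
    ns = n_steps // snap_every + 1
    t_snap = np.empty(ns)
    pos_snap = np.empty((ns, nc, 2))
    theta_snap = np.empty((ns, nc))
    r_snap = np.empty((ns, nc))
    d_snap = np.empty((ns, nc))

    t_trace[0] = 0.0
    for c in range(nc):
        v_tr[0, c] = states[c, IV]
        ca_tr[0, c] = states[c, ICA_I]
        f_tr[0, c] = active_force(states[c])
        l_tr[0, c] = l0_um * states[c, ISL] / sl0
    t_snap[0] = 0.0
    pos_snap[0] = pos
    theta_snap[0] = theta
    r_snap[0] = rr
    d_snap[0] = dd
    it = 1
    isn = 1
    clips = 0

    for step in range(n_steps):
        t = step * dt_ms
        # (1) coupling + protocol stimulus from previous-step potentials
        ist[:] = 0.0
        coupling_currents_from(states, ea, eb, d_ns, ist)
        if stim_start <= t < stim_start + stim_dur:
            for c in range(nc):
                if stim_mask[c]:
                    ist[c] += stim_amp_pa
        # (2) cell ODE step
        for c in range(nc):
            clips += euler_step(states[c], ist[c], dt_ms, cm, sl0, tmpc,
                                coupled, dy, exs)
            if not math.isfinite(states[c, IV]):
                return (t_trace[:it], v_tr[:it], ca_tr[:it], f_tr[:it],
                        l_tr[:it], t_snap[:isn], pos_snap[:isn],
                        theta_snap[:isn], r_snap[:isn], d_snap[:isn],
                        clips, 1, step, c)
        if mech_on:
            # (3)+(4) target length from SL; area-conserving resize
            for c in range(nc):
                l_m = l0_um * states[c, ISL] / sl0 * 1e-6
                r_new, d_new = solve_resize(l_m, area0[c], npart, rr[c])
                if r_new < 0.0:
                    return (t_trace[:it], v_tr[:it], ca_tr[:it], f_tr[:it],
                            l_tr[:it], t_snap[:isn], pos_snap[:isn],
                            theta_snap[:isn], r_snap[:isn], d_snap[:isn],
                            clips, 2, step, c)
                if r_new != rr[c]:
                    rr[c] = r_new
                    dd[c] = d_new
                    inertia[c] = density * union_polar_moment_nb(
                        npart, r_new, d_new)
            # (5) DEM forces + centred-difference motion
            dem_forces(pos, theta, vel, omega, rr, dd, npart, mass,
                       ca, ka, cb, kb, fs, kn, ks, betan, betas, dt_s,
                       fx, fy, mz)
            integrate_clumps(pos, theta, vel, omega, fx, fy, mz, mass,
                             inertia, fixed_x, fixed_y, rot_lock, dt_s,
                             alpha)
        if (step + 1) % trace_every == 0:
            t_trace[it] = (step + 1) * dt_ms
            for c in range(nc):
                v_tr[it, c] = states[c, IV]
                ca_tr[it, c] = states[c, ICA_I]
                f_tr[it, c] = active_force(states[c])
                l_tr[it, c] = l0_um * states[c, ISL] / sl0
            it += 1
        if (step + 1) % snap_every == 0:
            t_snap[isn] = (step + 1) * dt_ms
            pos_snap[isn] = pos
            theta_snap[isn] = theta
            r_snap[isn] = rr
            d_snap[isn] = dd
            isn += 1

    return (t_trace[:it], v_tr[:it], ca_tr[:it], f_tr[:it], l_tr[:it],
            t_snap[:isn], pos_snap[:isn], theta_snap[:isn], r_snap[:isn],
            d_snap[:isn], clips, 0, n_steps, -1)


@njit(cache=True)
def coupling_currents_from(states, ea, eb, d_ns, ist):
    """Accumulate neighbour coupling currents from the state array."""
    for i in range(ea.shape[0]):
        a = ea[i]
        b = eb[i]
        dv = d_ns * (states[b, IV] - states[a, IV])
        ist[a] += dv
        ist[b] -= dv
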