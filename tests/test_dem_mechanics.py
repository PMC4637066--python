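"""DEM core: contact kinematics and force law, rigid-clump integration,
Newton's third law, momentum conservation and the critical-timestep
estimate.  Physics-conservation checks run with local damping off (the
damping term is deliberately non-conservative)."""

import numpy as np
import pytest

from atriadem import dem_mechanics as dm
from atriadem import _tissue_kernels as tk
from atriadem.clump_geometry import ClumpGeometry

UM = dm.UM


def _pair(gap_um=0.0, theta=np.pi / 2):
    """Two 9-particle clumps end-to-end along +y with the given surface gap
    between the facing end particles."""
    geom = ClumpGeometry(9, 8.0, 10.5)
    a = dm.ClumpBody(geometry=geom, pos=np.array([0.0, 0.0]), theta=theta)
    b = dm.ClumpBody(geometry=geom,
                     pos=np.array([0.0, (100.0 + gap_um) * UM]), theta=theta)
    # facing particles: top of a (index 8), bottom of b (index 0)
    return a, b, dm.Contact(a=b, index_a=0, b=a, index_b=8)


def test_resting_contact_zero_force():
    a, b, contact = _pair(0.0)
    kin = dm.contact_kinematics(contact)
    assert kin["g_s"] == pytest.approx(0.0, abs=1e-18)
    f, _ = dm.contact_force_update(contact, kin, 4e-6, dm.ContactParams())
    assert np.allclose(f, 0.0)


def test_static_overlap_is_repulsive_with_spring_force():
    """1 um overlap at k_n = 10 N/m gives a 1e-5 N force pushing apart."""
    a, b, contact = _pair(-1.0)
    kin = dm.contact_kinematics(contact)
    assert kin["g_s"] == pytest.approx(-1.0 * UM)
    f_on_b, _ = dm.contact_force_update(contact, kin, 4e-6,
                                        dm.ContactParams())
    # contact's A side is the upper clump: repulsion pushes it up (+y)
    assert f_on_b[1] == pytest.approx(10.0 * 1.0 * UM, rel=1e-12)
    assert f_on_b[0] == pytest.approx(0.0, abs=1e-20)


def test_bonded_separation_is_attractive():
    a, b, contact = _pair(+2.0)
    kin = dm.contact_kinematics(contact)
    f_on_b, _ = dm.contact_force_update(contact, kin, 4e-6,
                                        dm.ContactParams())
    assert f_on_b[1] < 0.0          # upper clump pulled down


def test_rigid_translation_has_no_relative_velocity():
    a, b, contact = _pair(0.0)
    a.vel[:] = (1e-3, 2e-3)
    b.vel[:] = (1e-3, 2e-3)
    kin = dm.contact_kinematics(contact)
    assert kin["dn"] == pytest.approx(0.0, abs=1e-18)
    assert kin["ds"] == pytest.approx(0.0, abs=1e-18)


def test_rotation_velocity_matches_finite_difference():
    """The contact-point velocity of a rotating clump matches the numerical
    derivative of the particle position."""
    a, b, contact = _pair(0.0)
    omega = 3.0
    a.omega = omega                 # lower clump rotates about its centroid
    kin = dm.contact_kinematics(contact)
    # finite-difference oracle: rotate the lower clump by omega*h
    h = 1e-9
    p0 = a.particle_centres()[8]
    a.theta += omega * h
    p1 = a.particle_centres()[8]
    a.theta -= omega * h
    v_fd = (p1 - p0) / h
    rel = -np.array([kin["dn"] * kin["n"][0] + kin["ds"] * kin["t"][0],
                     kin["dn"] * kin["n"][1] + kin["ds"] * kin["t"][1]])
    # B side of the contact is the rotating clump; A side is at rest, and
    # the contact point is the midpoint, so compare against the rigid-body
    # velocity field evaluated there
    v_xc = a.velocity_at(kin["x_c"])
    assert np.allclose(rel, v_xc, rtol=1e-9, atol=1e-15)
    assert np.allclose(v_fd, a.velocity_at(p0), rtol=1e-6)


def test_integrate_motion_force_free_is_uniform():
    a, _, _ = _pair()
    a.vel[:] = (1e-3, -2e-3)
    pos0 = a.pos.copy()
    dm.integrate_motion(a, 1e-5)
    assert np.allclose(a.pos, pos0 + a.vel * 1e-5)


def test_integrate_motion_constant_force_quadratic():
    """Displacement under constant force matches (1/2)(F/m)t^2 to O(dt^2)."""
    a, _, _ = _pair()
    F = 1e-8
    n_steps, dt = 2000, 1e-6
    for _ in range(n_steps):
        a.force[1] = F
        dm.integrate_motion(a, dt)
    t = n_steps * dt
    exact = 0.5 * F / a.mass * t ** 2
    # leapfrog from rest carries an O(dt/t) startup offset
    assert a.pos[1] == pytest.approx(exact, rel=1e-3)


def test_fixed_direction_ignores_force():
    a, _, _ = _pair()
    a.fixed_y = True
    y0 = a.pos[1]
    for _ in range(1000):
        a.force[:] = (0.0, 1e-6)
        dm.integrate_motion(a, 1e-6)
    assert a.pos[1] == y0


def test_newtons_third_law_over_assembly():
    """Contact forces over a perturbed multi-clump assembly sum to zero to
    machine precision."""
    from atriadem.tissue_model import TissueSpec, build_tissue

    tissue = build_tissue(TissueSpec(cells_along_fibre=3, fibres_across=3))
    rng = np.random.default_rng(7)
    tissue.pos += rng.uniform(-0.3, 0.3, tissue.pos.shape) * UM
    tissue.vel += rng.uniform(-1e-4, 1e-4, tissue.vel.shape)
    nc = tissue.n_cells
    fx, fy, mz = np.zeros(nc), np.zeros(nc), np.zeros(nc)
    tk.dem_forces(tissue.pos, tissue.theta, tissue.vel, tissue.omega,
                  tissue.rr, tissue.dd, tissue.npart, tissue.mass,
                  tissue.ca, tissue.ka, tissue.cb, tissue.kb, tissue.fs,
                  10.0, 0.1, 0.1, 0.1, 4e-6, fx, fy, mz)
    scale = np.abs(fx).max() + np.abs(fy).max()
    assert abs(fx.sum()) < 1e-12 * scale
    assert abs(fy.sum()) < 1e-12 * scale


def test_two_clump_momentum_conservation():
    """A free bonded pair under arbitrary contact history conserves linear
    momentum to machine precision (local damping off)."""
    from atriadem.tissue_model import TissueSpec, build_tissue

    tissue = build_tissue(TissueSpec(cells_along_fibre=2, fibres_across=1))
    tissue.pos[1, 1] -= 2.0 * UM          # overlap the junction
    tissue.vel[0] = (2e-4, -1e-4)
    tissue.vel[1] = (-3e-4, 2e-4)
    p0 = (tissue.mass[:, None] * tissue.vel).sum(axis=0)
    nc = tissue.n_cells
    fx, fy, mz = np.zeros(nc), np.zeros(nc), np.zeros(nc)
    for _ in range(10_000):
        tk.dem_forces(tissue.pos, tissue.theta, tissue.vel, tissue.omega,
                      tissue.rr, tissue.dd, tissue.npart, tissue.mass,
                      tissue.ca, tissue.ka, tissue.cb, tissue.kb, tissue.fs,
                      10.0, 0.1, 0.1, 0.1, 4e-6, fx, fy, mz)
        tk.integrate_clumps(tissue.pos, tissue.theta, tissue.vel,
                            tissue.omega, fx, fy, mz, tissue.mass,
                            tissue.inertia, tissue.fixed_x, tissue.fixed_y,
                            False, 4e-6, 0.0)
    p1 = (tissue.mass[:, None] * tissue.vel).sum(axis=0)
    assert np.allclose(p1, p0, rtol=0, atol=1e-18 + 1e-9 * np.abs(p0).max())


def test_kinetic_energy_decays_with_dashpots():
    """A perturbed free pair loses kinetic energy (beta > 0, no resizing)."""
    from atriadem.tissue_model import TissueSpec, build_tissue

    tissue = build_tissue(TissueSpec(cells_along_fibre=2, fibres_across=1))
    tissue.pos[1, 1] -= 1.0 * UM
    nc = tissue.n_cells
    fx, fy, mz = np.zeros(nc), np.zeros(nc), np.zeros(nc)

    def ke():
        return float(0.5 * (tissue.mass * (tissue.vel ** 2).sum(axis=1)).sum())

    energies = []
    for step in range(20_000):
        tk.dem_forces(tissue.pos, tissue.theta, tissue.vel, tissue.omega,
                      tissue.rr, tissue.dd, tissue.npart, tissue.mass,
                      tissue.ca, tissue.ka, tissue.cb, tissue.kb, tissue.fs,
                      10.0, 0.1, 0.1, 0.1, 4e-6, fx, fy, mz)
        tk.integrate_clumps(tissue.pos, tissue.theta, tissue.vel,
                            tissue.omega, fx, fy, mz, tissue.mass,
                            tissue.inertia, tissue.fixed_x, tissue.fixed_y,
                            False, 4e-6, 0.0)
        if step % 1000 == 999:
            energies.append(ke())
    assert energies[-1] < 1e-3 * max(energies)


def test_rigid_clump_particle_distances_constant():
    """Intra-clump particle distances never change during DEM stepping."""
    from atriadem.tissue_model import TissueSpec, build_tissue
    from atriadem.simulation_engine import simulate

    tissue = build_tissue(TissueSpec(cells_along_fibre=2, fibres_across=2))
    tissue.pos += np.random.default_rng(3).uniform(-0.2, 0.2,
                                                   tissue.pos.shape) * UM
    d0 = tissue.dd.copy()
    simulate(tissue, 2.0, protocol=None, mechanics=True)
    # geometry (r, d) changed only through resize; with quiescent cells the
    # resize is sub-nm, and within DEM stepping d is untouched
    assert np.allclose(tissue.dd, d0, rtol=1e-6)


def test_critical_timestep_scalings():
    params = dm.ContactParams()
    geom = ClumpGeometry(9, 8.0, 10.5)
    body = dm.ClumpBody(geometry=geom, pos=np.zeros(2))
    est = dm.critical_timestep([body], params)
    # the default 0.004 ms step runs stably below the estimate
    assert est >= 0.004e-3
    stiff = dm.ContactParams(k_n=100 * params.k_n, k_s=params.k_s)
    est_stiff = dm.critical_timestep([body], stiff,
                                     contacts_per_body=20)
    est_base = dm.critical_timestep([body], params, contacts_per_body=20)
    assert est_stiff == pytest.approx(est_base / 10.0, rel=1e-6)
    heavy = dm.ClumpBody(geometry=geom, pos=np.zeros(2),
                         mass=4 * body.mass, inertia=4 * body.inertia)
    est_heavy = dm.critical_timestep([heavy], params, contacts_per_body=20)
    assert est_heavy == pytest.approx(2.0 * est_base, rel=1e-6)


def test_python_and_kernel_contact_paths_agree():
    """The object-level contact/motion operations and the array kernels
    produce the same two-clump trajectory."""
    geom = ClumpGeometry(9, 8.0, 10.5)
    params = dm.ContactParams()
    # python path
    a = dm.ClumpBody(geometry=geom, pos=np.array([0.0, 0.0]))
    b = dm.ClumpBody(geometry=geom, pos=np.array([0.3 * UM, 98.5 * UM]))
    contact = dm.Contact(a=a, index_a=0, b=b, index_b=8)
    # (contact normal from b's end particle to a's start particle)
    contact = dm.Contact(a=b, index_a=0, b=a, index_b=8)
    dt = 4e-6
    for _ in range(500):
        dm.apply_contact(contact, dt, params)
        dm.integrate_motion(a, dt)
        dm.integrate_motion(b, dt)
    # kernel path
    pos = np.array([[0.0, 0.0], [0.3 * UM, 98.5 * UM]])
    theta = np.full(2, np.pi / 2)
    vel = np.zeros((2, 2))
    omega = np.zeros(2)
    rr = np.full(2, 8.0 * UM)
    dd = np.full(2, 10.5 * UM)
    mass = np.full(2, a.mass)
    inertia = np.full(2, a.inertia)
    ca = np.array([1], np.int64)
    ka = np.array([0], np.int64)
    cb = np.array([0], np.int64)
    kb = np.array([8], np.int64)
    fs = np.zeros(1)
    fx, fy, mz = np.zeros(2), np.zeros(2), np.zeros(2)
    fixed = np.zeros(2, bool)
    for _ in range(500):
        tk.dem_forces(pos, theta, vel, omega, rr, dd, 9, mass,
                      ca, ka, cb, kb, fs, params.k_n, params.k_s,
                      params.beta_n, params.beta_s, dt, fx, fy, mz)
        tk.integrate_clumps(pos, theta, vel, omega, fx, fy, mz, mass,
                            inertia, fixed, fixed, False, dt, 0.0)
    assert np.allclose(pos[0], a.pos, rtol=1e-12, atol=1e-18)
    assert np.allclose(pos[1], b.pos, rtol=1e-12, atol=1e-18)
    assert theta[0] == pytest.approx(a.theta, rel=1e-12)
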