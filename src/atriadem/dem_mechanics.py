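"""Discrete-element mechanical core: rigid-clump dynamics, bonded linear
contact model with viscous dashpots, and the explicit centred-difference
integrator.

Conventions
-----------
* Units are SI internally (m, kg, s, N) with unit out-of-plane thickness;
  the cell-scale um/ms quantities are converted at the module boundary.
* A contact joins one particle of clump A to one particle of clump B.  The
  contact normal points from the B particle centre to the A particle
  centre; the surface gap ``g_s = |centre distance| - (r_A + r_B)`` is
  negative in overlap.
* The bond force on A is ``-(k_n g_s) n - (2 beta_n sqrt(m_c k_n)
  d_n) n + F_s t - (2 beta_s sqrt(m_c k_s) d_s) t``: overlap repels,
  bonded separation attracts, and both dashpots oppose the relative
  surface velocity.  The accumulated shear spring force is stored as a
  scalar in the current tangent frame (magnitude preserved under frame
  rotation) and incremented by ``-k_s d_s dt`` each step.
* Bonds never break: the tensile/shear strengths are effectively infinite.
* Clumps are rigid during DEM stepping; gravity is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clump_geometry import ClumpGeometry, union_polar_moment

__all__ = [
    "DENSITY", "ContactParams", "ClumpBody", "Contact",
    "contact_kinematics", "contact_force_update", "apply_contact",
    "integrate_motion", "critical_timestep",
]

DENSITY = 1053.0     # kg/m^3 (1.053 g/mL), particle material density
UM = 1e-6            # metres per micrometre


@dataclass(frozen=True)
class ContactParams:
    """Linear contact-bond parameters.

    k_n, k_s : normal/shear spring stiffness (N/m).
    beta_n, beta_s : critical damping ratios of the dashpots.
    tensile_strength, shear_strength : bond strengths (N); the defaults are
        effectively unbreakable and the code never breaks bonds.
    detection_threshold_um : surface-gap threshold for the single initial
        contact detection pass (um).
    """

    k_n: float = 10.0
    k_s: float = 0.1
    beta_n: float = 0.1
    beta_s: float = 0.1
    tensile_strength: float = 1e200
    shear_strength: float = 1e200
    detection_threshold_um: float = 1.0

    def __post_init__(self):
        if self.k_n <= 0 or self.k_s <= 0:
            raise ValueError("spring stiffnesses must be positive")
        if self.beta_n < 0 or self.beta_s < 0:
            raise ValueError("damping ratios must be non-negative")


@dataclass
class ClumpBody:
    """One rigid clump: pose, kinematics and mass properties (SI units)."""

    geometry: ClumpGeometry
    pos: np.ndarray                     # centroid (m)
    theta: float = np.pi / 2.0          # axis angle; pi/2 = fibre along +y
    vel: np.ndarray = field(default_factory=lambda: np.zeros(2))
    omega: float = 0.0                  # rad/s about z
    mass: float = 0.0                   # kg (unit thickness)
    inertia: float = 0.0                # kg m^2
    force: np.ndarray = field(default_factory=lambda: np.zeros(2))
    moment: float = 0.0
    fixed_x: bool = False
    fixed_y: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, float)
        self.vel = np.asarray(self.vel, float)
        if self.mass <= 0.0:
            self.mass = DENSITY * self.geometry.area * UM ** 2
        if self.inertia <= 0.0:
            self.inertia = DENSITY * union_polar_moment(
                self.geometry.n, self.geometry.r, self.geometry.d) * UM ** 4

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    def particle_centres(self) -> np.ndarray:
        """Particle centres (m), symmetric about the centroid."""
        g = self.geometry
        k = np.arange(g.n) - (g.n - 1) / 2.0
        return self.pos + np.outer(k * g.d * UM, self.axis)

    @property
    def radius_m(self) -> float:
        return self.geometry.r * UM

    def set_geometry(self, geom: ClumpGeometry) -> None:
        """Replace the clump geometry (area-conserving resize), keeping pose
        and kinematics; rotational inertia is recomputed."""
        self.geometry = geom
        self.inertia = DENSITY * union_polar_moment(
            geom.n, geom.r, geom.d) * UM ** 4

    def velocity_at(self, point: np.ndarray) -> np.ndarray:
        """Rigid-body velocity field of the clump at a point (m)."""
        rx, ry = point[0] - self.pos[0], point[1] - self.pos[1]
        return np.array([self.vel[0] - self.omega * ry,
                         self.vel[1] + self.omega * rx])


@dataclass
class Contact:
    """A bonded interface between particle ``index_a`` of clump ``a`` and
    particle ``index_b`` of clump ``b`` (two different clumps)."""

    a: ClumpBody
    index_a: int
    b: ClumpBody
    index_b: int
    shear_force: float = 0.0   # accumulated spring force in the tangent frame


def contact_kinematics(contact: Contact) -> dict:
    """Geometry and relative surface velocity of a contact.

    Returns a dict with the surface gap ``g_s`` (m), contact-plane location
    ``x_c`` (midpoint of the interaction region on the line of centres),
    unit normal ``n`` (from the B particle to the A particle), tangent ``t``
    and the normal/shear relative velocity components ``dn``/``ds`` (A
    relative to B; positive dn = separating).  The rigid-body velocity
    field uses the clump centroid and angular velocity.
    """
    a, b = contact.a, contact.b
    if a is b:
        raise ValueError("contact must join two different clumps")
    pa = a.particle_centres()[contact.index_a]
    pb = b.particle_centres()[contact.index_b]
    dvec = pa - pb
    dist = float(np.hypot(*dvec))
    if dist < 1e-15:
        raise ValueError("degenerate contact: coincident particle centres")
    n = dvec / dist
    t = np.array([-n[1], n[0]])
    g_s = dist - (a.radius_m + b.radius_m)
    x_c = pb + (b.radius_m + 0.5 * g_s) * n
    rel = a.velocity_at(x_c) - b.velocity_at(x_c)
    return {"g_s": g_s, "x_c": x_c, "n": n, "t": t,
            "dn": float(rel @ n), "ds": float(rel @ t)}


def contact_force_update(contact: Contact, kin: dict, dt: float,
                         params: ContactParams):
    """Advance the contact force state one step; returns (force on A, x_c).

    The normal spring force is set from the current gap, the shear spring
    force is incremented by ``-k_s ds dt``, and both dashpots are
    recomputed from the current relative velocities.  The equal and
    opposite force acts on B at the same application point; accumulation
    onto the bodies is done by :func:`apply_contact`.
    """
    m_c = contact.a.mass * contact.b.mass / (contact.a.mass + contact.b.mass)
    contact.shear_force += -params.k_s * kin["ds"] * dt
    f_n = -(params.k_n * kin["g_s"]
            + 2.0 * params.beta_n * np.sqrt(m_c * params.k_n) * kin["dn"])
    f_t = (contact.shear_force
           - 2.0 * params.beta_s * np.sqrt(m_c * params.k_s) * kin["ds"])
    force_on_a = f_n * kin["n"] + f_t * kin["t"]
    if not np.isfinite(force_on_a).all():
        raise FloatingPointError(
            f"non-finite contact force at particles "
            f"({contact.index_a}, {contact.index_b})")
    return force_on_a, kin["x_c"]


def apply_contact(contact: Contact, dt: float, params: ContactParams) -> None:
    """Per-step contact update: kinematics, force law, then equal and
    opposite accumulation onto both clumps with moments about each
    centroid (the application point is x_c for both)."""
    kin = contact_kinematics(contact)
    f_a, x_c = contact_force_update(contact, kin, dt, params)
    a, b = contact.a, contact.b
    a.force += f_a
    b.force -= f_a
    ra = x_c - a.pos
    rb = x_c - b.pos
    a.moment += ra[0] * f_a[1] - ra[1] * f_a[0]
    b.moment -= rb[0] * f_a[1] - rb[1] * f_a[0]


def integrate_motion(body: ClumpBody, dt: float,
                     rotation: bool = True) -> ClumpBody:
    """Centred (leapfrog) update of one clump: half-step velocities advance
    by F/m and M/I, then positions advance by the full step; accumulators
    are cleared.  Fixed degrees of freedom keep zero velocity and ignore
    force."""
    if body.fixed_x:
        body.vel[0] = 0.0
    else:
        body.vel[0] += body.force[0] / body.mass * dt
    if body.fixed_y:
        body.vel[1] = 0.0
    else:
        body.vel[1] += body.force[1] / body.mass * dt
    if rotation:
        body.omega += body.moment / body.inertia * dt
    else:
        body.omega = 0.0
    body.pos += body.vel * dt
    body.theta += body.omega * dt
    body.force[:] = 0.0
    body.moment = 0.0
    return body


def critical_timestep(bodies, params: ContactParams,
                      contacts_per_body: int | None = None,
                      safety: float = 0.1) -> float:
    """Safety-factored estimate of the stable mechanical time step (s).

    For each body the translational limit sqrt(m / k_eff) and the
    rotational limit sqrt(I / k_rot) are evaluated, with k_eff the summed
    normal stiffness over its contacts (estimated as 2n + 2 bonds when not
    given) and k_rot the stiffness-weighted squared lever arms of the
    particle offsets; the estimate is ``safety`` times the minimum over
    bodies.  Scales as sqrt(m/k) and sqrt(I/k_rot).
    """
    bodies = list(bodies)
    if not bodies:
        raise ValueError("need at least one body")
    est = np.inf
    for body in bodies:
        g = body.geometry
        ncon = contacts_per_body if contacts_per_body is not None else 2 * g.n + 2
        k_eff = ncon * params.k_n
        est = min(est, np.sqrt(body.mass / k_eff))
        offsets = (np.arange(g.n) - (g.n - 1) / 2.0) * g.d * UM
        k_rot = 2.0 * params.k_n * float(np.sum(offsets ** 2))
        if k_rot > 0:
            est = min(est, np.sqrt(body.inertia / k_rot))
    return float(safety * est)
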