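"""Tissue construction: fibre-aligned clump lattice with optional cavities,
one-off contact detection, DEM equilibration, boundary conditions, and the
deduplicated cell-neighbour conduction graph.

The lattice places each cell (clump of ``n`` discs, resting radius 8 um,
spacing 10.5 um, length 100 um, width 16 um) with its axis along the fibre
direction.  Cells in the same fibre are end-to-end with tangent end
particles (surface gap 0); adjacent fibres are side-by-side with tangent
particles, so a generous detection threshold bonds the whole patch.  Two
cells are electrically coupled whenever at least one DEM contact exists
between them; contact multiplicity does not affect the coupling strength,
so the conduction graph keeps one edge per cell pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _tissue_kernels as _tk
from .cell_dynamics import CellParams, CellState, initial_state
from .clump_geometry import ClumpGeometry
from .dem_mechanics import DENSITY, UM, ContactParams

__all__ = ["TissueSpec", "Tissue", "build_tissue", "detect_contacts",
           "equilibrate", "build_conduction_graph"]

#: resting clump geometry of one atrial cell
RESTING_GEOMETRY = ClumpGeometry(n=9, r=8.0, d=10.5)


@dataclass(frozen=True)
class TissueSpec:
    """Geometry of a rectangular fibre-aligned patch.

    cells_along_fibre : cells per fibre (each 100 um long at rest).
    fibres_across : parallel fibres (each 16 um wide at rest).
    fibre_direction : unit vector, (0, 1) or (1, 0) (axis-aligned only).
    cavities : rectangles (x0, y0, x1, y1) in um to leave empty.
    fixed_regions : rectangles (x0, y0, x1, y1, fix_x, fix_y); cells whose
        centroid falls inside get the corresponding velocity components
        pinned to zero.
    stagger : axially offset adjacent fibres by d/2 (off by default).
    """

    cells_along_fibre: int = 1
    fibres_across: int = 1
    fibre_direction: tuple[float, float] = (0.0, 1.0)
    cavities: tuple = ()
    fixed_regions: tuple = ()
    stagger: bool = False

    def __post_init__(self):
        if self.cells_along_fibre < 1 or self.fibres_across < 1:
            raise ValueError("cell counts must be >= 1")
        if tuple(self.fibre_direction) not in ((0.0, 1.0), (1.0, 0.0)):
            raise ValueError("fibre_direction must be (0,1) or (1,0)")

    @property
    def n_cells_max(self) -> int:
        return self.cells_along_fibre * self.fibres_across


@dataclass
class Tissue:
    """The assembled tissue: flat per-clump arrays (SI units), the frozen
    contact list, and the deduplicated conduction graph."""

    spec: TissueSpec
    cell_params: CellParams
    contact_params: ContactParams
    npart: int
    states: np.ndarray          # (nc, 32)
    pos: np.ndarray             # (nc, 2) m
    theta: np.ndarray           # (nc,)
    vel: np.ndarray             # (nc, 2) m/s
    omega: np.ndarray           # (nc,)
    rr: np.ndarray              # (nc,) particle radius, m
    dd: np.ndarray              # (nc,) particle spacing, m
    area0: np.ndarray           # (nc,) resting clump area, m^2
    mass: np.ndarray            # (nc,) kg
    inertia: np.ndarray         # (nc,) kg m^2
    fixed_x: np.ndarray         # (nc,) bool
    fixed_y: np.ndarray         # (nc,) bool
    grid: np.ndarray            # (nc, 2) lattice indices (fibre, along)
    # contact arrays (filled by detect_contacts)
    ca: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ka: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    cb: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    kb: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    fs: np.ndarray = field(default_factory=lambda: np.empty(0))
    # conduction graph edges (filled by build_conduction_graph)
    ea: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    eb: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    conductance_nS: float = 1000.0

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    @property
    def n_particles(self) -> int:
        return self.n_cells * self.npart

    def cell_lengths_um(self) -> np.ndarray:
        """Current clump lengths (um) from the per-clump (r, d)."""
        return ((self.npart - 1) * self.dd + 2.0 * self.rr) / UM

    def particle_table(self) -> np.ndarray:
        """(N, 5) array: particle id, clump id, x(um), y(um), r(um)."""
        nc, n = self.n_cells, self.npart
        k = np.arange(n) - (n - 1) / 2.0
        ax = np.stack([np.cos(self.theta), np.sin(self.theta)], axis=1)
        centres = (self.pos[:, None, :]
                   + k[None, :, None] * self.dd[:, None, None] * ax[:, None, :])
        out = np.empty((nc * n, 5))
        out[:, 0] = np.arange(nc * n)
        out[:, 1] = np.repeat(np.arange(nc), n)
        out[:, 2:4] = centres.reshape(-1, 2) / UM
        out[:, 4] = np.repeat(self.rr / UM, n)
        return out

    def cell_state(self, index: int) -> CellState:
        return CellState(self.states[index].copy())

    def region_mask(self, rect_um) -> np.ndarray:
        """Boolean mask of cells whose centroid lies in (x0, y0, x1, y1) um."""
        x0, y0, x1, y1 = rect_um
        x = self.pos[:, 0] / UM
        y = self.pos[:, 1] / UM
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)

    def extent_um(self) -> tuple[float, float, float, float]:
        """Bounding box (x0, y0, x1, y1) of particle material, um."""
        p = self.particle_table()
        return (float((p[:, 2] - p[:, 4]).min()),
                float((p[:, 3] - p[:, 4]).min()),
                float((p[:, 2] + p[:, 4]).max()),
                float((p[:, 3] + p[:, 4]).max()))


def build_tissue(spec: TissueSpec,
                 cell_params: CellParams | None = None,
                 contact_params: ContactParams | None = None,
                 cell_state: CellState | None = None,
                 detect: bool = True) -> Tissue:
    """Place clumps at resting geometry on the fibre-aligned lattice, apply
    cavities and boundary conditions, initialise per-cell states, and (by
    default) detect contacts and derive the conduction graph.

    ``cell_state`` seeds every cell (e.g. a paced steady state); the
    published resting initial conditions are used when omitted.
    """
    cell_params = cell_params or CellParams()
    contact_params = contact_params or ContactParams()
    geom = RESTING_GEOMETRY
    L = geom.length            # 100 um
    W = 2.0 * geom.r           # 16 um
    along, across = spec.cells_along_fibre, spec.fibres_across

    centroids = []
    grididx = []
    for fi in range(across):
        x = (fi + 0.5) * W
        y_off = 0.5 * geom.d if (spec.stagger and fi % 2 == 1) else 0.0
        for j in range(along):
            y = (j + 0.5) * L + y_off
            in_cavity = False
            for (cx0, cy0, cx1, cy1) in spec.cavities:
                if cx0 <= x <= cx1 and cy0 <= y <= cy1:
                    in_cavity = True
                    break
            if not in_cavity:
                centroids.append((x, y))
                grididx.append((fi, j))
    if not centroids:
        raise ValueError("tissue spec leaves no cells (cavities cover all)")
    nc = len(centroids)

    xy = np.asarray(centroids) * UM
    if tuple(spec.fibre_direction) == (1.0, 0.0):
        xy = xy[:, ::-1].copy()          # fibre along +x: swap coordinates
        theta0 = 0.0
    else:
        theta0 = np.pi / 2.0

    state0 = (cell_state or initial_state()).y
    tissue = Tissue(
        spec=spec,
        cell_params=cell_params,
        contact_params=contact_params,
        npart=geom.n,
        states=np.tile(state0, (nc, 1)),
        pos=xy,
        theta=np.full(nc, theta0),
        vel=np.zeros((nc, 2)),
        omega=np.zeros(nc),
        rr=np.full(nc, geom.r * UM),
        dd=np.full(nc, geom.d * UM),
        area0=np.full(nc, geom.area * UM ** 2),
        mass=np.full(nc, DENSITY * geom.area * UM ** 2),
        inertia=np.full(nc, DENSITY * _tk.union_polar_moment_nb(
            geom.n, geom.r * UM, geom.d * UM)),
        fixed_x=np.zeros(nc, bool),
        fixed_y=np.zeros(nc, bool),
        grid=np.asarray(grididx, np.int64),
    )

    for (x0, y0, x1, y1, fix_x, fix_y) in spec.fixed_regions:
        mask = tissue.region_mask((x0, y0, x1, y1))
        if fix_x:
            tissue.fixed_x |= mask
        if fix_y:
            tissue.fixed_y |= mask

    if detect:
        detect_contacts(tissue)
        build_conduction_graph(tissue)
    return tissue


def detect_contacts(tissue: Tissue, threshold_um: float | None = None) -> int:
    """One-off contact detection: one Contact per particle pair from
    different clumps with surface gap <= threshold.  Intra-clump pairs are
    skipped; the list is frozen afterwards (contact detection is disabled
    during cycling).  Returns the number of contacts."""
    if threshold_um is None:
        threshold_um = tissue.contact_params.detection_threshold_um
    p = tissue.particle_table()
    xy = p[:, 2:4]
    clump = p[:, 1].astype(np.int64)
    r_um = p[:, 4]
    cutoff = 2.0 * r_um.max() + threshold_um + 1e-9
    pairs = cKDTree(xy).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        gap = (np.hypot(*(xy[i] - xy[j]).T) - (r_um[i] + r_um[j]))
        keep = (clump[i] != clump[j]) & (gap <= threshold_um + 1e-12)
        i, j = i[keep], j[keep]
    else:
        i = j = np.empty(0, np.int64)
    n = tissue.npart
    tissue.ca = clump[i]
    tissue.ka = (i % n).astype(np.int64)
    tissue.cb = clump[j]
    tissue.kb = (j % n).astype(np.int64)
    tissue.fs = np.zeros(len(i))
    isolated = np.setdiff1d(np.arange(tissue.n_cells),
                            np.union1d(tissue.ca, tissue.cb))
    if tissue.n_cells > 1 and len(isolated):
        warnings.warn(f"{len(isolated)} isolated cell(s) with no contacts",
                      RuntimeWarning, stacklevel=2)
    return len(i)


def equilibrate(tissue: Tissue, tolerance: float = 1e-5,
                max_steps: int = 200_000, dt_ms: float = 0.004) -> dict:
    """DEM-only cycling (no cell ODEs, no resizing) until the mean ratio of
    unbalanced force to mean contact force drops below ``tolerance``.

    Returns {'steps': ..., 'residual': ...}; raises if the step budget is
    exhausted first.  The conduction graph is frozen and unaffected.
    """
    cp = tissue.contact_params
    steps, ratio = _tk.equilibrate_kernel(
        tissue.pos, tissue.theta, tissue.vel, tissue.omega,
        tissue.rr, tissue.dd, tissue.npart, tissue.mass, tissue.inertia,
        tissue.ca, tissue.ka, tissue.cb, tissue.kb, tissue.fs,
        cp.k_n, cp.k_s, cp.beta_n, cp.beta_s,
        tissue.fixed_x, tissue.fixed_y, False, dt_ms * 1e-3,
        tolerance, max_steps, 50)
    if ratio >= tolerance:
        raise RuntimeError(
            f"equilibration did not converge in {max_steps} steps "
            f"(unbalanced ratio {ratio:.3e} >= {tolerance:.1e})")
    return {"steps": int(steps), "residual": float(ratio)}


def build_conduction_graph(tissue: Tissue,
                           conductance_nS: float = 1000.0) -> np.ndarray:
    """Deduplicated cell-neighbour edges from the contact list: one
    undirected edge per cell pair with at least one contact, uniform
    conductance.  Returns the (n_edges, 2) edge array."""
    if len(tissue.ca) == 0:
        edges = np.empty((0, 2), np.int64)
    else:
        lo = np.minimum(tissue.ca, tissue.cb)
        hi = np.maximum(tissue.ca, tissue.cb)
        edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    tissue.ea = edges[:, 0].copy() if len(edges) else np.empty(0, np.int64)
    tissue.eb = edges[:, 1].copy() if len(edges) else np.empty(0, np.int64)
    tissue.conductance_nS = conductance_nS
    return edges


def neighbour_graph(tissue: Tissue):
    """The conduction graph as a networkx Graph (cells as nodes)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(tissue.n_cells))
    g.add_edges_from(zip(tissue.ea.tolist(), tissue.eb.tolist()))
    return g
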