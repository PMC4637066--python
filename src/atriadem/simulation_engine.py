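"""The electromechanical cycle and its measurements.

Each shared time step executes five barrier-ordered stages on all cells:

1. neighbour coupling currents I_st = D * sum(V_i - V_H) from the previous
   step's potentials (Jacobi update, order-independent), plus any protocol
   stimulus;
2. explicit-Euler update of every cell's 32 ODE variables;
3. target cell lengths from sarcomere length (L = L0 SL / SL0);
4. area-conserving clump resize (r, d re-solved; inertia recomputed);
5. DEM contact forces and centred-difference motion update.

Electrics-only mode skips stages 3-5 (frozen geometry), which is how pure
conduction experiments are run.  Measurement utilities quantify the
results: per-cell activation times, conduction velocity along a direction,
and tissue-level polygon area and central-fibre length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tissue_kernels as _tk
from .cell_dynamics import STATE_NAMES  # noqa: F401
from .dem_mechanics import UM
from .tissue_model import Tissue

__all__ = [
    "StimulusProtocol", "SimulationRecord", "stimulus_currents",
    "step_tissue", "simulate", "activation_map", "conduction_velocity",
    "tissue_area", "tissue_length", "boundary_cells", "run_experiment",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """A square current pulse applied to a set of cells.

    region : cell selector — boolean mask, index array, or one of the named
        selectors resolved by :func:`resolve_region` ("first-cell",
        "top-row", "bottom-row", "corner-block:K", "all", "none").
    amplitude_nA : pulse amplitude per cell (2 nA default).
    start_ms / duration_ms : pulse window.
    """

    region: object = "first-cell"
    amplitude_nA: float = 2.0
    start_ms: float = 1.0
    duration_ms: float = 2.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")


def resolve_region(tissue: Tissue, region) -> np.ndarray:
    """Resolve a region selector to a boolean cell mask."""
    if isinstance(region, np.ndarray) and region.dtype == bool:
        return region
    if isinstance(region, (list, tuple, np.ndarray)):
        mask = np.zeros(tissue.n_cells, bool)
        mask[np.asarray(region, int)] = True
        return mask
    fibre, along = tissue.grid[:, 0], tissue.grid[:, 1]
    if region == "none":
        return np.zeros(tissue.n_cells, bool)
    if region == "all":
        return np.ones(tissue.n_cells, bool)
    if region == "first-cell":
        return (fibre == 0) & (along == 0)
    if isinstance(region, str) and region.startswith("first-cells:"):
        k = int(region.split(":")[1])
        return along < k
    if region == "bottom-row":
        return along == 0
    if region == "top-row":
        return along == along.max()
    if isinstance(region, str) and region.startswith("top-rows:"):
        k = int(region.split(":")[1])
        return along >= along.max() - (k - 1)
    if isinstance(region, str) and region.startswith("corner-block:"):
        k = int(region.split(":")[1])
        return (fibre < k) & (along >= along.max() - (k - 1))
    if isinstance(region, str) and region.startswith("rect:"):
        rect = tuple(float(v) for v in region.split(":")[1].split(","))
        return tissue.region_mask(rect)
    raise ValueError(f"unknown stimulus region {region!r}")


def stimulus_currents(tissue: Tissue, V_mV: np.ndarray,
                      protocol_pA: np.ndarray | None = None) -> np.ndarray:
    """Per-cell I_st (pA): D * sum over neighbours of (V_i - V_H), plus any
    protocol contribution.  The coupling part sums to zero over all cells
    (each edge contributes antisymmetrically)."""
    ist = np.zeros(tissue.n_cells)
    _tk.coupling_currents(np.asarray(V_mV, float), tissue.ea, tissue.eb,
                          tissue.conductance_nS, ist)
    if protocol_pA is not None:
        ist += protocol_pA
    return ist


@dataclass
class SimulationRecord:
    """Time series of a tissue run.

    Traces are sampled every ``trace_every`` steps: per-cell V (mV),
    [Ca2+]_i (mM), normalised active force, and cell length (um).
    Snapshots (clump poses and geometry, um) are sampled every
    ``snap_every`` steps.  ``tissue`` is the final state.
    """

    tissue: Tissue
    t_ms: np.ndarray
    V: np.ndarray
    Ca_i: np.ndarray
    F_active: np.ndarray
    L_um: np.ndarray
    t_snap_ms: np.ndarray
    pos_snap_um: np.ndarray
    theta_snap: np.ndarray
    r_snap_um: np.ndarray
    d_snap_um: np.ndarray
    clip_count: int = 0
    meta: dict = field(default_factory=dict)

    def activation_times(self, threshold_mV: float = -40.0) -> np.ndarray:
        return activation_map(self.t_ms, self.V, threshold_mV)

    def area_series_um2(self) -> np.ndarray:
        """Boundary-polygon area at every snapshot (um^2)."""
        order = boundary_cells(self.tissue)
        return np.array([_shoelace(self.pos_snap_um[i][order])
                         for i in range(len(self.t_snap_ms))])

    def length_series_um(self) -> np.ndarray:
        """Central-fibre tissue length at every snapshot (um)."""
        return np.array([
            _central_fibre_length(self.tissue, self.pos_snap_um[i],
                                  self.r_snap_um[i], self.d_snap_um[i])
            for i in range(len(self.t_snap_ms))])


def step_tissue(tissue: Tissue, dt_ms: float = 0.004,
                protocol: StimulusProtocol | None = None,
                t_now_ms: float = 0.0, mechanics: bool = True,
                rotation: bool = True) -> Tissue:
    """Advance the tissue by one full electromechanical cycle in place."""
    rec = simulate(tissue, dt_ms, protocol=protocol, dt_ms=dt_ms,
                   t0_ms=t_now_ms, mechanics=mechanics, rotation=rotation,
                   trace_every=1, snap_every=1)
    return rec.tissue


def simulate(tissue: Tissue, duration_ms: float,
             protocol: StimulusProtocol | None = None,
             dt_ms: float = 0.004, mechanics: bool = True,
             rotation: bool = True, local_damping: float = 0.7,
             trace_every: int = 20,
             snap_every: int = 250, t0_ms: float = 0.0) -> SimulationRecord:
    """Run the tissue for ``duration_ms``; mutates the tissue state and
    returns the record.  Deterministic: identical inputs give bit-identical
    records."""
    cp = tissue.contact_params
    pp = tissue.cell_params
    if protocol is None:
        mask = np.zeros(tissue.n_cells, bool)
        amp_pa, start, dur = 0.0, 0.0, 1.0
    else:
        mask = resolve_region(tissue, protocol.region)
        amp_pa = protocol.amplitude_nA * 1e3
        start, dur = protocol.start_ms - t0_ms, protocol.duration_ms
    n_steps = int(round(duration_ms / dt_ms))
    trace_every = max(1, min(trace_every, n_steps))
    snap_every = max(1, min(snap_every, n_steps))
    out = _tk.run_tissue_kernel(
        tissue.states, pp.Cm, pp.SL0, pp.temperature_C,
        1.0 if pp.coupled else 0.0,
        tissue.ea, tissue.eb, tissue.conductance_nS,
        mask, amp_pa, start, dur,
        mechanics,
        tissue.pos, tissue.theta, tissue.vel, tissue.omega,
        tissue.rr, tissue.dd, tissue.npart, tissue.area0,
        tissue.mass, tissue.inertia,
        tissue.ca, tissue.ka, tissue.cb, tissue.kb, tissue.fs,
        cp.k_n, cp.k_s, cp.beta_n, cp.beta_s,
        tissue.fixed_x, tissue.fixed_y, not rotation,
        pp.L0, dt_ms, n_steps, trace_every, snap_every,
        alpha=local_damping)
    (t_tr, v_tr, ca_tr, f_tr, l_tr, t_sn, pos_sn, th_sn, r_sn, d_sn,
     clips, err, err_step, err_cell) = out
    if err == 1:
        raise FloatingPointError(
            f"cell state diverged at step {err_step} (cell {err_cell})")
    if err == 2:
        raise RuntimeError(
            f"area-conserving resize failed at step {err_step} "
            f"(cell {err_cell}): target length outside feasible range")
    return SimulationRecord(
        tissue=tissue, t_ms=t_tr + t0_ms, V=v_tr, Ca_i=ca_tr,
        F_active=f_tr, L_um=l_tr, t_snap_ms=t_sn + t0_ms,
        pos_snap_um=pos_sn / UM, theta_snap=th_sn, r_snap_um=r_sn / UM,
        d_snap_um=d_sn / UM, clip_count=int(clips),
        meta={"dt_ms": dt_ms, "mechanics": mechanics,
              "duration_ms": duration_ms})


# ---------------------------------------------------------------------------
# measurements

def activation_map(t_ms: np.ndarray, V: np.ndarray,
                   threshold_mV: float = -40.0) -> np.ndarray:
    """Per-cell activation time: first upward crossing of the threshold,
    linearly interpolated between samples; NaN for unactivated cells.

    ``V`` has shape (n_samples, n_cells); sampling should be <= 0.5 ms.
    """
    t = np.asarray(t_ms, float)
    v = np.asarray(V, float)
    nt, nc = v.shape
    below = v[:-1] < threshold_mV
    above = v[1:] >= threshold_mV
    out = np.full(nc, np.nan)
    for c in range(nc):
        idx = np.nonzero(below[:, c] & above[:, c])[0]
        if len(idx):
            i = idx[0]
            out[c] = np.interp(threshold_mV, [v[i, c], v[i + 1, c]],
                               [t[i], t[i + 1]])
    return out


def conduction_velocity(activation_ms: np.ndarray, positions_um: np.ndarray,
                        direction, exclude_frac: float = 0.1,
                        min_cells: int = 10) -> float:
    """Wavefront speed (cm/s) from the least-squares slope of distance
    along ``direction`` versus activation time.

    Cells within ``exclude_frac`` of either end of the path (initiation and
    boundary transients) and unactivated cells are excluded.
    """
    act = np.asarray(activation_ms, float)
    pos = np.asarray(positions_um, float)
    direction = np.asarray(direction, float)
    direction = direction / np.hypot(*direction)
    s = pos @ direction
    ok = np.isfinite(act)
    if ok.sum() < min_cells:
        raise ValueError(
            f"only {int(ok.sum())} activated cells; need >= {min_cells} "
            "for a conduction-velocity fit (no propagation?)")
    lo, hi = s.min(), s.max()
    span = hi - lo
    core = ok & (s >= lo + exclude_frac * span) & (s <= hi - exclude_frac * span)
    if core.sum() < 2:
        raise ValueError("too few cells in the fit window")
    slope = np.polyfit(act[core], s[core], 1)[0]     # um/ms
    return float(slope * 0.1)                        # um/ms -> cm/s


def boundary_cells(tissue: Tissue) -> np.ndarray:
    """Indices of boundary cells in perimeter order (rectangular,
    cavity-free lattices)."""
    fibre, along = tissue.grid[:, 0], tissue.grid[:, 1]
    fmax, jmax = fibre.max(), along.max()
    expected = ((fmax + 1) * (jmax + 1))
    if expected != tissue.n_cells:
        raise ValueError("boundary trace requires a full rectangular patch")
    lookup = {(f, j): i for i, (f, j) in enumerate(map(tuple, tissue.grid))}
    order = []
    for f in range(fmax + 1):                  # bottom row, left -> right
        order.append(lookup[(f, 0)])
    for j in range(1, jmax + 1):               # right column, upward
        order.append(lookup[(fmax, j)])
    for f in range(fmax - 1, -1, -1):          # top row, right -> left
        order.append(lookup[(f, jmax)])
    for j in range(jmax - 1, 0, -1):           # left column, downward
        order.append(lookup[(0, j)])
    return np.asarray(order, np.int64)


def _shoelace(poly_um: np.ndarray) -> float:
    x, y = poly_um[:, 0], poly_um[:, 1]
    area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise ValueError("degenerate boundary polygon")
    return float(area)


def tissue_area(tissue: Tissue) -> float:
    """Tissue area (um^2): the shoelace area of the polygon through the
    boundary clump centroids in perimeter order."""
    order = boundary_cells(tissue)
    return _shoelace(tissue.pos[order] / UM)


def _central_fibre_length(tissue: Tissue, pos_um, r_um, d_um) -> float:
    fibre, along = tissue.grid[:, 0], tissue.grid[:, 1]
    f_mid = int(np.sort(np.unique(fibre))[len(np.unique(fibre)) // 2])
    sel = np.nonzero(fibre == f_mid)[0]
    sel = sel[np.argsort(along[sel])]
    bot, top = sel[0], sel[-1]
    axis_of = lambda i: np.array([np.cos(tissue.theta[i]),
                                  np.sin(tissue.theta[i])])
    half = (tissue.npart - 1) / 2.0
    # end-particle extremity of the bottom and top cells along the fibre
    p_top = pos_um[top] + (half * d_um[top] + r_um[top]) * axis_of(top)
    p_bot = pos_um[bot] - (half * d_um[bot] + r_um[bot]) * axis_of(bot)
    return float(np.hypot(*(p_top - p_bot)))


def tissue_length(tissue: Tissue) -> float:
    """Tissue length (um) through the central fibre: distance between the
    outer extremities (end-particle surfaces) of its end cells."""
    return _central_fibre_length(tissue, tissue.pos / UM, tissue.rr / UM,
                                 tissue.dd / UM)


def run_experiment(config) -> SimulationRecord:
    """Run a canned scenario described by a RunConfig (see
    :mod:`atriadem.config`).  Deterministic given the config."""
    from . import config as _cfg

    return _cfg.execute(config)
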