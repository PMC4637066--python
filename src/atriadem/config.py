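"""Run configuration: schema, text-file round-trip, canned scenarios and
their execution.

The config format is one ``key = value`` per line; ``#`` starts a comment.
Keys carry their units in the name (e.g. ``kn_N_per_m``); unknown keys are
rejected with the expected schema.  An empty file means all defaults —
the parameter set of the tissue model (k_n = 10 N/m, k_s = 0.1 N/m,
beta = 0.1, D = 1000 nS, rho = 1.053 g/mL, r = 8 um, L = 100 um, n = 9,
dt = 0.004 ms).

No default code path uses random numbers; an optional lattice jitter takes
an explicit seed and is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .cell_dynamics import CellParams, CellState, pace_to_steady_state
from .clump_geometry import ClumpGeometry
from .dem_mechanics import ClumpBody, ContactParams, critical_timestep
from .tissue_model import TissueSpec, build_tissue, equilibrate

__all__ = ["RunConfig", "load_config", "save_config", "make_scenario",
           "execute", "SCENARIOS"]

_JITTER_NONE = -1


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one simulation run (all defaults are the
    tissue model's parameter table)."""

    scenario: str = "single-cell"
    cells_along_fibre: int = 1
    fibres_across: int = 1
    fibre_axis: str = "y"                  # fibre direction: "y" or "x"
    cavities_um: tuple = ()                # rectangles (x0, y0, x1, y1)
    fix_bottom_row_y: bool = False
    # electrics
    D_nS: float = 1000.0
    stim_region: str = "first-cell"
    stim_amplitude_nA: float = 2.0
    stim_start_ms: float = 1.0
    stim_duration_ms: float = 2.0
    paced_beats: int = 20
    pacing_Hz: float = 1.0
    # mechanics (contact bond parameters)
    kn_N_per_m: float = 10.0
    ks_N_per_m: float = 0.1
    beta_n: float = 0.1
    beta_s: float = 0.1
    density_g_per_mL: float = 1.053
    detection_threshold_um: float = 1.0
    mechanics: bool = True
    rotation: bool = True
    local_damping: float = 0.7
    stagger: bool = False
    # numerics / output
    dt_ms: float = 0.004
    duration_ms: float = 600.0
    trace_every_steps: int = 20
    snap_every_steps: int = 250
    equilibration_tolerance: float = 1e-5
    lattice_jitter_um: float = 0.0
    jitter_seed: int = _JITTER_NONE
    threads: int = 1

    def __post_init__(self):
        if self.dt_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("dt_ms and duration_ms must be positive")
        if self.fibre_axis not in ("x", "y"):
            raise ValueError("fibre_axis must be 'x' or 'y'")

    def contact_params(self) -> ContactParams:
        return ContactParams(
            k_n=self.kn_N_per_m, k_s=self.ks_N_per_m,
            beta_n=self.beta_n, beta_s=self.beta_s,
            detection_threshold_um=self.detection_threshold_um)

    def cell_params(self) -> CellParams:
        return CellParams(dt_ms=self.dt_ms,
                          stim_amplitude_nA=self.stim_amplitude_nA,
                          stim_duration_ms=self.stim_duration_ms)

    def tissue_spec(self) -> TissueSpec:
        fixed = ()
        if self.fix_bottom_row_y:
            width = 16.0 * self.fibres_across
            fixed = ((-1.0, -1.0, width + 1.0, 100.0 + 1.0, False, True),)
        return TissueSpec(
            cells_along_fibre=self.cells_along_fibre,
            fibres_across=self.fibres_across,
            fibre_direction=(0.0, 1.0) if self.fibre_axis == "y" else (1.0, 0.0),
            cavities=tuple(tuple(c) for c in self.cavities_um),
            fixed_regions=fixed,
            stagger=self.stagger)

    def validate(self) -> None:
        """Consistency checks, including dt against the critical mechanical
        time step estimate for the configured stiffness."""
        if self.mechanics:
            body = ClumpBody(geometry=ClumpGeometry(),
                             pos=np.zeros(2))
            est = critical_timestep([body], self.contact_params())
            if self.dt_ms * 1e-3 > est:
                raise ValueError(
                    f"dt_ms = {self.dt_ms} exceeds the critical mechanical "
                    f"time step estimate {est * 1e3:.4g} ms for "
                    f"kn = {self.kn_N_per_m} N/m")
        if self.lattice_jitter_um > 0 and self.jitter_seed == _JITTER_NONE:
            raise ValueError("lattice jitter requires an explicit jitter_seed")


_FIELDS = {f: t for f, t in RunConfig.__annotations__.items()}


def save_config(config: RunConfig, path) -> None:
    """Write every key (sorted) as ``key = value``; lists as JSON."""
    d = asdict(config)
    with open(path, "w") as fh:
        fh.write("# atriadem run configuration (units in key names)\n")
        for k in sorted(d):
            v = d[k]
            if isinstance(v, tuple):
                v = json.dumps([list(x) if isinstance(x, (tuple, list))
                                else x for x in v])
            fh.write(f"{k} = {v}\n")


def _parse_value(key: str, raw: str):
    default = getattr(RunConfig(), key)
    if isinstance(default, bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"key {key}: expected a boolean, got {raw!r}")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    if isinstance(default, tuple):
        return tuple(tuple(x) if isinstance(x, list) else x
                     for x in json.loads(raw))
    return raw


def load_config(path) -> RunConfig:
    """Parse, default, and validate a config file; unknown keys rejected."""
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in _FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: unknown key {key!r}; known keys: "
                    f"{', '.join(sorted(_FIELDS))}")
            try:
                values[key] = _parse_value(key, raw)
            except (ValueError, json.JSONDecodeError) as err:
                raise ValueError(f"{path}:{lineno}: key {key}: {err}") from err
    config = RunConfig(**values)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# canned scenarios

SCENARIOS = ("single-cell", "strip-cv", "anisotropy-patch",
             "contraction-patch", "paper-tissue")


def make_scenario(name: str, **overrides) -> RunConfig:
    """The canned experiment set-ups, at configurable scale.

    * ``single-cell`` — one cell, 2 nA / 2 ms stimulus at t = 50 ms, 600 ms.
    * ``strip-cv`` — 60-cell single fibre, stimulus on the first 6 cells
      (a block deep enough to ignite the wave; it coincides with the 10 %
      fit-exclusion zone), electrics-only; for conduction-velocity
      measurement over the middle 80 % of the strip.
    * ``anisotropy-patch`` — 20 x 20 patch, corner-block stimulus,
      electrics-only; fibre vs transverse conduction velocity.
    * ``contraction-patch`` — 10 x 10 patch, stimulus on the top portion
      (top 8 rows, deep enough to ignite), bottom row fixed in y, 450 ms
      of full electromechanics (long enough for full relaxation).
    * ``paper-tissue`` — full scale: 50 cells along x 200 fibres across
      (10,000 cells / 90,000 particles, 5 mm x 3.2 mm), top-left corner
      stimulus, 600 ms; for optional long runs.
    """
    base = dict(
        scenario=name)
    if name == "single-cell":
        base.update(cells_along_fibre=1, fibres_across=1, mechanics=False,
                    stim_region="all", stim_start_ms=50.0,
                    duration_ms=600.0)
    elif name == "strip-cv":
        base.update(cells_along_fibre=60, fibres_across=1, mechanics=False,
                    stim_region="first-cells:6", stim_start_ms=1.0,
                    duration_ms=20.0)
    elif name == "anisotropy-patch":
        base.update(cells_along_fibre=20, fibres_across=20, mechanics=False,
                    stim_region="corner-block:8", stim_start_ms=1.0,
                    duration_ms=15.0)
    elif name == "contraction-patch":
        base.update(cells_along_fibre=10, fibres_across=10, mechanics=True,
                    stim_region="top-rows:8", stim_start_ms=1.0,
                    fix_bottom_row_y=True, duration_ms=450.0,
                    snap_every_steps=250)
    elif name == "paper-tissue":
        base.update(cells_along_fibre=50, fibres_across=200, mechanics=True,
                    stim_region="corner-block:5", stim_start_ms=1.0,
                    fix_bottom_row_y=True, duration_ms=600.0)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base.update(overrides)
    return RunConfig(**base)


# ---------------------------------------------------------------------------
# execution

_paced_cache: dict = {}


def paced_state(params: CellParams, beats: int,
                frequency_Hz: float = 1.0) -> CellState:
    """End-diastolic state after pacing (memoised per parameter set)."""
    key = (params, beats, frequency_Hz)
    if key not in _paced_cache:
        state, _ = pace_to_steady_state(params, frequency_Hz, beats)
        _paced_cache[key] = state
    return _paced_cache[key].copy()


def execute(config: RunConfig):
    """Build the scenario's tissue, equilibrate, and run; returns the
    SimulationRecord.  Deterministic given the config."""
    from .simulation_engine import StimulusProtocol, simulate

    config.validate()
    cell_params = config.cell_params()
    state0 = paced_state(cell_params, config.paced_beats, config.pacing_Hz)
    tissue = build_tissue(config.tissue_spec(), cell_params,
                          config.contact_params(), cell_state=state0)
    tissue.conductance_nS = config.D_nS
    if config.lattice_jitter_um > 0:
        rng = np.random.default_rng(config.jitter_seed)
        tissue.pos += (rng.uniform(-1, 1, tissue.pos.shape)
                       * config.lattice_jitter_um * 1e-6)
    if config.mechanics and tissue.n_cells > 1:
        equilibrate(tissue, config.equilibration_tolerance)
    protocol = StimulusProtocol(
        region=config.stim_region, amplitude_nA=config.stim_amplitude_nA,
        start_ms=config.stim_start_ms, duration_ms=config.stim_duration_ms)
    record = simulate(
        tissue, config.duration_ms, protocol=protocol, dt_ms=config.dt_ms,
        mechanics=config.mechanics, rotation=config.rotation,
        local_damping=config.local_damping,
        trace_every=config.trace_every_steps,
        snap_every=config.snap_every_steps)
    record.meta["config"] = asdict(config)
    return record
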