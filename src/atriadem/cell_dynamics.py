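"""Coupled single-cell electromechanics: ionic model, myofilament model and
their two-way Ca2+ coupling, advanced by explicit Euler at a fixed step.

The cell state is a flat vector of 32 primary ODE variables (see
``STATE_NAMES``): 21 ionic variables of the human atrial action-potential
model and 11 myofilament variables (regulatory units, crossbridges, mean
distortions, sarcomere length SL and the force integral).  On top of the
states, a documented set of monitored quantities (currents, SR fluxes,
forces, the troponin-bound Ca flux) is exposed through ``monitored()``.

Cell length is a linear scaling of sarcomere length: L = L0 * SL / SL0,
with L0 = 100 um at SL0 = 2.2 um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _cell_kernels as _k
from ._cell_kernels import (  # noqa: F401  (re-exported)
    NVAR, NEXTRA, STATE_NAMES, EXTRA_NAMES, SL_MIN, SL_MAX,
)

__all__ = [
    "CellParams", "CellState", "initial_state", "ionic_derivatives",
    "myofilament_derivatives", "coupled_ca_derivative", "step_cell",
    "integrate_cell", "pace_to_steady_state", "cell_length_from_SL",
    "apd90", "STATE_NAMES", "EXTRA_NAMES", "NVAR",
]

#: published resting initial conditions of the two source models
_INITIAL = np.array([
    -81.18,        # V (mV)
    2.908e-3, 9.649e-1, 9.775e-1,          # m h j
    3.043e-2, 9.992e-1,                    # oa oi
    4.966e-3, 9.986e-1,                    # ua ui
    3.296e-5, 1.869e-2,                    # xr xs
    1.367e-4, 9.996e-1, 7.755e-1,          # d f f_Ca
    0.0, 1.0, 9.992e-1,                    # u v w
    1.117e1, 1.390e2, 1.013e-4,            # Na_i K_i Ca_i (mM)
    1.488, 1.488,                          # Ca_up Ca_rel (mM)
    0.99, 0.01,                            # N_NoXB P_NoXB
    1.4773e-2, 1.3066e-1,                  # TropCaL TropCaH
    0.97, 3.049e-7, 1.975e-7,              # N XBprer XBpostr
    2.2,                                   # SL (um)
    3.412e-8, 7.0e-3,                      # xXBprer xXBpostr
    0.0,                                   # Integral_force
])

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
_GATE_SLICE = slice(1, 1 + _k.N_GATES)


@dataclass(frozen=True)
class CellParams:
    """Tunable cell-level parameters; everything else is fixed model data.

    Cm : membrane capacitance (pF).
    SL0 : initial/reference sarcomere length (um).
    L0 : resting cell length (um) at SL = SL0.
    width : resting cell width (um), used by the tissue geometry.
    temperature_C : myofilament temperature (degC); rates are specified at 37.
    coupled : if True the troponin-bound Ca flux of the myofilament model
        replaces the instantaneous troponin buffer in the Ca2+ balance.
    stim_amplitude_nA / stim_duration_ms : default stimulus pulse.
    dt_ms : default integration step.
    """

    Cm: float = 100.0
    SL0: float = 2.2
    L0: float = 100.0
    width: float = 16.0
    temperature_C: float = 37.0
    coupled: bool = True
    stim_amplitude_nA: float = 2.0
    stim_duration_ms: float = 2.0
    dt_ms: float = 0.004

    def __post_init__(self):
        if self.Cm <= 0 or self.SL0 <= 0 or self.L0 <= 0 or self.dt_ms <= 0:
            raise ValueError("Cm, SL0, L0 and dt_ms must be positive")

    @property
    def _coupled_flag(self) -> float:
        return 1.0 if self.coupled else 0.0

    def uncoupled(self) -> "CellParams":
        """Copy of these parameters with the Ca feedback removed (the
        original, purely electrophysiological Ca2+ balance)."""
        return replace(self, coupled=False)


@dataclass
class CellState:
    """State of one coupled cell: a 32-vector with named access."""

    y: np.ndarray = field(default_factory=lambda: _INITIAL.copy())

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (NVAR,):
            raise ValueError(f"cell state must have {NVAR} entries")

    def __getitem__(self, name: str) -> float:
        return float(self.y[_IDX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.y[_IDX[name]] = value

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    @property
    def V(self) -> float:
        return float(self.y[_k.IV])

    @property
    def Ca_i(self) -> float:
        return float(self.y[_k.ICA_I])

    @property
    def SL(self) -> float:
        return float(self.y[_k.ISL])

    def validate(self) -> None:
        """Raise ValueError naming the first invalid state variable."""
        bad = ~np.isfinite(self.y)
        if bad.any():
            name = STATE_NAMES[int(np.argmax(bad))]
            raise ValueError(f"non-finite cell state variable: {name}")
        sl = self.y[_k.ISL]
        if not (SL_MIN <= sl <= SL_MAX):
            raise ValueError(
                f"sarcomere length SL={sl:.4f} um outside physical bounds "
                f"[{SL_MIN}, {SL_MAX}] um")


def initial_state() -> CellState:
    """Published resting initial conditions of the two source models."""
    return CellState(_INITIAL.copy())


def _rhs(state: CellState, i_st_pA: float, params: CellParams):
    state.validate()
    dy = np.empty(NVAR)
    ex = np.empty(NEXTRA)
    _k.cell_rhs(state.y, i_st_pA, params.Cm, params.SL0,
                params.temperature_C, params._coupled_flag, dy, ex)
    return dy, ex


def monitored(state: CellState, i_st_pA: float = 0.0,
              params: CellParams = CellParams()) -> dict:
    """All monitored quantities (states + derived) as an ordered mapping."""
    dy, ex = _rhs(state, i_st_pA, params)
    out = {name: float(v) for name, v in zip(STATE_NAMES, state.y)}
    out.update({name: float(v) for name, v in zip(EXTRA_NAMES, ex)})
    out["L_um"] = cell_length_from_SL(state.SL, params)
    return out


def ionic_derivatives(state: CellState, i_st_pA: float,
                      params: CellParams) -> dict:
    """Derivatives of the ionic variables (everything except Ca_i, whose
    derivative is owned by ``coupled_ca_derivative``) plus monitored
    currents.  Units: mV/ms, 1/ms, mM/ms; currents in pA."""
    dy, ex = _rhs(state, i_st_pA, params)
    out = {name: float(dy[_IDX[name]]) for name in STATE_NAMES[:21]
           if name != "Ca_i"}
    out["currents"] = {n: float(ex[i]) for i, n in enumerate(EXTRA_NAMES)
                       if n.startswith("I_")}
    return out


def myofilament_derivatives(state: CellState, params: CellParams) -> dict:
    """Derivatives of the myofilament variables, the force-integral
    integrand, dSL/dt and the troponin-bound Ca flux dTropACa/dt (uM/ms)."""
    dy, ex = _rhs(state, 0.0, params)
    out = {name: float(dy[_IDX[name]]) for name in STATE_NAMES[21:]}
    out["dTropACa_dt"] = float(ex[_k.XDTROP])
    out["F_active"] = float(ex[_k.XF_ACT])
    out["F_passive"] = float(ex[_k.XF_PAS])
    out["F_preload"] = float(ex[_k.XF_PRE])
    out["F_afterload"] = float(ex[_k.XF_AFT])
    return out


def coupled_ca_derivative(state: CellState, dTropACa_dt_mM: float,
                          params: CellParams) -> float:
    """d[Ca2+]_i/dt (mM/ms) from the modified Ca2+ balance: the flux terms of
    the ionic model with the explicit troponin flux ``-2 dTropACa/dt`` in B1
    (``dTropACa_dt_mM`` in mM/ms) and only the calmodulin buffer in B2."""
    dy, ex = _rhs(state, 0.0, params)
    ca_i = state.Ca_i
    b1 = ((2.0 * ex[_k.XI_NACA] - ex[_k.XI_PCA] - ex[_k.XI_CAL]
           - ex[_k.XI_BCA]) / (2.0 * _k.V_I * _k.FARADAY)
          + (_k.V_UP * (ex[_k.XI_UPLEAK] - ex[_k.XI_UP])
             + ex[_k.XI_REL] * _k.V_REL) / _k.V_I)
    b1 -= 2.0 * dTropACa_dt_mM
    b2 = 1.0 + _k.CMDN_MAX * _k.KM_CMDN / (ca_i + _k.KM_CMDN) ** 2
    if b2 <= 0.0:
        raise ValueError("buffering factor B2 must be positive")
    return float(b1 / b2)


def step_cell(state: CellState, i_st_pA: float, dt_ms: float,
              params: CellParams) -> CellState:
    """One explicit-Euler update of all 32 variables (ionic derivatives, Ca
    coupling and myofilament derivatives are all evaluated on the incoming
    state).  Gates are clipped to [0, 1] only on overshoot, with a warning."""
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    state.validate()
    new = state.copy()
    dy = np.empty(NVAR)
    ex = np.empty(NEXTRA)
    clips = _k.euler_step(new.y, i_st_pA, dt_ms, params.Cm, params.SL0,
                          params.temperature_C, params._coupled_flag, dy, ex)
    if clips:
        warnings.warn(f"clipped {clips} gating variable(s) to [0, 1]",
                      RuntimeWarning, stacklevel=2)
    if not np.isfinite(new.y).all():
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(new.y)))]
        raise FloatingPointError(
            f"explicit Euler step produced non-finite {bad} "
            f"(dt={dt_ms} ms is likely above the stiffness limit)")
    return new


def integrate_cell(state: CellState, params: CellParams, duration_ms: float,
                   stim_start_ms: float = 50.0, sample_every: int = 20,
                   dt_ms: float | None = None):
    """Run one cell for ``duration_ms`` with a single stimulus pulse.

    Returns (t_ms, Y, F_active) where Y has one row per sample and one
    column per state variable.
    """
    dt = params.dt_ms if dt_ms is None else dt_ms
    n_steps = int(round(duration_ms / dt))
    t, yy, fact, clips = _k.integrate_cell(
        state.y, dt, n_steps, params.stim_amplitude_nA * 1e3, stim_start_ms,
        params.stim_duration_ms, sample_every, params.Cm, params.SL0,
        params.temperature_C, params._coupled_flag)
    if clips:
        warnings.warn(f"clipped gating variables {clips} time(s)",
                      RuntimeWarning, stacklevel=2)
    if not np.isfinite(yy[-1]).all():
        raise FloatingPointError("single-cell integration diverged")
    return t, yy, fact


def pace_to_steady_state(params: CellParams, frequency_Hz: float = 1.0,
                         beats: int = 200,
                         state: CellState | None = None):
    """Pace at ``frequency_Hz`` (one stimulus pulse per cycle) for ``beats``
    beats and return (end-diastolic CellState, convergence record).

    The convergence record is a dict with per-beat pre-stimulus V and Ca_i;
    the beat-to-beat change in these is the convergence metric.
    """
    if frequency_Hz <= 0:
        raise ValueError("frequency must be positive")
    if beats < 0:
        raise ValueError("beats must be >= 0")
    y0 = (initial_state() if state is None else state).y
    if beats == 0:
        return CellState(y0.copy()), {"V_rest": np.array([]),
                                      "Ca_rest": np.array([])}
    period = 1e3 / frequency_Hz
    y, v_rest, ca_rest = _k.pace_cell(
        y0, params.dt_ms, period, beats, params.stim_amplitude_nA * 1e3,
        params.stim_duration_ms, params.Cm, params.SL0,
        params.temperature_C, params._coupled_flag)
    if not np.isfinite(y).all():
        bad = int(np.argmax(~np.isfinite(v_rest))) if (~np.isfinite(v_rest)).any() else beats
        raise FloatingPointError(f"pacing diverged at beat {bad}")
    return CellState(y), {"V_rest": v_rest, "Ca_rest": ca_rest}


def cell_length_from_SL(SL_um: float, params: CellParams = CellParams()) -> float:
    """Cell length (um) as a linear scaling of sarcomere length:
    L = L0 * SL / SL0 (100 um at SL = 2.2 um)."""
    if SL_um < 0:
        raise ValueError("SL must be non-negative")
    return params.L0 * SL_um / params.SL0


def apd90(t_ms: np.ndarray, v_mV: np.ndarray) -> float:
    """Action-potential duration at 90 % repolarisation of the largest AP
    in the trace (linear interpolation on both crossings)."""
    t = np.asarray(t_ms, float)
    v = np.asarray(v_mV, float)
    i_peak = int(np.argmax(v))
    v_rest = float(v[0])
    v_target = v[i_peak] - 0.9 * (v[i_peak] - v_rest)
    # activation time: last upward crossing of v_target before the peak
    pre = np.nonzero(v[:i_peak + 1] <= v_target)[0]
    if len(pre) == 0 or i_peak == len(v) - 1:
        raise ValueError("no action potential found in trace")
    i0 = pre[-1]
    t_up = np.interp(v_target, [v[i0], v[i0 + 1]], [t[i0], t[i0 + 1]])
    post = np.nonzero(v[i_peak:] <= v_target)[0]
    if len(post) == 0:
        raise ValueError("trace ends before 90 % repolarisation")
    i1 = i_peak + post[0]
    t_dn = np.interp(v_target, [v[i1], v[i1 - 1]], [t[i1], t[i1 - 1]])
    return float(t_dn - t_up)
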