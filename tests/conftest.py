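"""Shared fixtures: paced steady states and single-beat records are computed
once per session (the pacing protocol is deterministic, so every test sees
the same state)."""

import numpy as np
import pytest

from atriadem import cell_dynamics as cd


@pytest.fixture(scope="session")
def cell_params():
    return cd.CellParams()


@pytest.fixture(scope="session")
def paced(cell_params):
    """End-diastolic state after 20 beats of 1 Hz pacing, plus the
    convergence record."""
    state, conv = cd.pace_to_steady_state(cell_params, 1.0, beats=20)
    return state, conv


@pytest.fixture(scope="session")
def beat(cell_params, paced):
    """One recorded coupled beat from the paced state: stimulus 2 nA / 2 ms
    at t = 50 ms, 600 ms window."""
    state, _ = paced
    t, Y, F = cd.integrate_cell(state.copy(), cell_params, 600.0,
                                stim_start_ms=50.0)
    return t, Y, F


@pytest.fixture(scope="session")
def beat_uncoupled(cell_params):
    """The matching purely-electrophysiological beat (original Ca balance),
    paced and stimulated identically."""
    pu = cell_params.uncoupled()
    state, _ = cd.pace_to_steady_state(pu, 1.0, beats=20)
    t, Y, F = cd.integrate_cell(state, pu, 600.0, stim_start_ms=50.0)
    return t, Y, F
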