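# atriadem

A 2D multiscale electromechanical simulator of human atrial tissue built on
the discrete element method (DEM), for researchers studying cardiac
excitation–contraction coupling who want tissue models that keep the
discrete, cellular structure of the myocardium instead of homogenising it
into a continuum.

## The model

**Single cell.** Each atrial myocyte is an equipotential cell whose membrane
potential obeys

    dV/dt = (−I_ion + I_st) / Cm,

with `I_ion` the sum of the twelve ionic and pump currents of the
Courtemanche–Ramirez–Nattel human atrial action-potential model
(Hodgkin–Huxley gating, `dy/dt = (y∞ − y)/τ_y`) and `I_st` the external
stimulus. Contraction comes from the Rice et al. approximate myofilament
model (rat parameter set, 37 °C): Ca²⁺ binds troponin, regulatory units
switch on cooperatively, crossbridges cycle, and sarcomere length SL follows

    d(SL)/dt = (Integral_force + (SL₀ − SL)·viscosity) / mass,
    Integral_force = ∫ (−F_active − F_passive + F_preload + F_afterload) dt,

with SL₀ = 2.2 µm. The models are coupled two ways through intracellular
Ca²⁺: [Ca²⁺]ᵢ drives the myofilaments, and the troponin-bound Ca²⁺ flux
dTrop_A Ca/dt replaces the instantaneous troponin buffer in the ionic Ca²⁺
balance `d[Ca²⁺]ᵢ/dt = B₁/B₂` (B₂ keeps only the calmodulin term). Cell
length is a linear scaling of SL: L = L₀·SL/SL₀ with L₀ = 100 µm.

**Cell as a clump.** Mechanically, each cell is a rigid clump of n = 9
overlapping discs of radius r spaced d apart along the fibre axis:

    L = (n − 1)·d + 2r,      A = n·π·r² − (n − 1)·S(r, d),

where S is the two-disc lens area. At every time step the new cell length
from SL is imposed by re-solving (r, d) at **constant clump area A** — the
2D incompressibility condition — so cells shorten and fatten without
changing area.

**Tissue.** Clumps are placed on a fibre-aligned lattice (optionally with
cavities), bonded to their neighbours by linear contact bonds with normal
and shear springs (k_n = 10 N/m, k_s = 0.1 N/m) plus critical-damped-ratio
dashpots (β = 0.1); bonds never break. Clump motion integrates Newton's
equations by an explicit centred finite-difference scheme. Any two cells
sharing at least one DEM contact are electrical neighbours; cell H receives

    I_st = D · Σᵢ (Vᵢ − V_H),        D = 1000 nS,

independent of contact multiplicity. Excitation waves propagate over this
graph while contraction feeds back through the per-step clump resizing.
All cell ODEs and the DEM share one explicit time step, Δt = 0.004 ms.

## Worked example

```python
import numpy as np
from atriadem.cell_dynamics import (CellParams, pace_to_steady_state,
                                    integrate_cell, cell_length_from_SL)

params = CellParams()                       # Δt = 0.004 ms, coupled model
state, conv = pace_to_steady_state(params, frequency_Hz=1.0, beats=20)
t, Y, F_active = integrate_cell(state, params, duration_ms=600.0,
                                stim_start_ms=50.0)
V, Cai, SL = Y[:, 0], Y[:, 18], Y[:, 28]
L = 100.0 * SL / 2.2
print(f"resting V      {V[t < 50][-1]:8.2f} mV")
print(f"peak V         {V.max():8.2f} mV")
print(f"peak [Ca2+]i   {1e3 * Cai.max():8.3f} uM")
print(f"shortening     {100 * (1 - L.min() / 100):8.2f} %")
print(f"t to min L     {t[np.argmin(L)] - 50:8.1f} ms")
```

prints

```
resting V        -81.18 mV
peak V            24.46 mV
peak [Ca2+]i      1.124 uM
shortening        10.12 %
t to min L         53.7 ms
```

i.e. the cell rests near −81 mV, overshoots to about +24 mV when a 2 nA /
2 ms stimulus is applied, and the Ca²⁺ transient makes it shorten by ~10 %
of its length, reaching full contraction ~54 ms after the stimulus.

Tissue experiments run through the scenario layer or the CLI:

```python
from atriadem import config as cfg
from atriadem.simulation_engine import conduction_velocity

rec = cfg.execute(cfg.make_scenario("strip-cv"))      # 60-cell fibre
cv = conduction_velocity(rec.activation_times(), rec.tissue.pos * 1e6,
                         (0, 1), exclude_frac=0.1)
print(f"fibre conduction velocity {cv:.1f} cm/s")     # -> 50.1 cm/s
```

```
atriadem single-cell --out out/          # CSV traces + VTK snapshots
atriadem strip-cv    --out out/
atriadem tissue      --out out/          # 10x10 electromechanical patch
```

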