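# Methods

This note documents the models implemented in `atriadem`, the choices made
where the formulation was genuinely open, the numerics, and the limits of
what the packaged experiments demonstrate.

## Coupled single-cell model

The electrophysiology is the Courtemanche–Ramirez–Nattel human atrial
action-potential model: 21 states (membrane potential V, 15 gating
variables, Na⁺/K⁺/Ca²⁺ concentrations, SR uptake and release compartments),
with the full published right-hand sides and constants (Cm = 100 pF,
T = 310 K, published cell volumes and maximal conductances). The mechanics
is the Rice–Wang–Bers–de Tombe approximate myofilament model: 11 states
(troponin Ca fractions at low/high-affinity regulatory sites, permissive /
non-permissive regulatory units with and without crossbridges, pre- and
post-rotation crossbridge populations with mean distortions, sarcomere
length SL, and the running force integral). We use the rat parameter set;
the rate constants are specified at 37 °C and the Q10 machinery is retained
(all factors equal 1 at the default temperature).

Coupling is two-way through intracellular Ca²⁺:

* [Ca²⁺]ᵢ (converted mM → µM) drives troponin binding in the myofilament
  model;
* the apparent troponin-bound Ca²⁺ flux dTrop_A Ca/dt — the overlap- and
  crossbridge-weighted total over both regulatory site classes — enters the
  ionic Ca²⁺ balance as an explicit `−2·dTrop_A Ca/dt` flux term in B₁,
  replacing the instantaneous troponin buffer; the buffering factor B₂
  retains only the calmodulin term. With the flux zeroed and the original
  troponin buffer restored (`CellParams(coupled=False)`), the balance
  reduces exactly to the uncoupled electrophysiological model, which is the
  reference for all coupled-vs-uncoupled comparisons.

Two constants of the force integral deserve note. The integrand is
`−F_active − F_passive + F_preload + F_afterload`; we take the afterload
from the myofilament model's series elastic element, `F_afterload =
KSE·(SL₀ − SL)` with KSE = 1 (normalised force)/µm anchored at SL₀. This is
the only non-zero afterload that model defines, and it is what gives the
physiological ~10 % unloaded-cell shortening; with the afterload removed
the same Ca²⁺ transient drives ~26 % shortening. Second, the troponin flux
carries the prefactor 2 in B₁; together with the calmodulin-only B₂ this
reproduces the intended coupled behaviour (a sharper, ~50 % higher Ca²⁺
peak than the uncoupled model, ~10 % shortening, full contraction ~54 ms
after the stimulus).

Cell length is a linear scaling of sarcomere length, L = L₀·SL/SL₀ with
L₀ = 100 µm, SL₀ = 2.2 µm (so 10 % sarcomere shortening is 10 % cell
shortening). Resting cell width is 16 µm.

**Known behavioural caveat.** In this formulation the coupled action
potential is ~28 ms *longer* at APD₉₀ than the uncoupled one (sustained
inward Na⁺/Ca²⁺-exchange current from the elevated plateau Ca²⁺), while
the dome is less prominent (stronger Ca-induced L-type inactivation). The
direction of the APD shift is sensitive to how the troponin flux enters
the Ca²⁺ balance; no packaged experiment depends on it.

## Stimulus convention and pacing

A positive stimulus depolarises: dV/dt = (−I_ion + I_st)/Cm, with the
standard pulse 2 nA for 2 ms. Initial conditions come from pacing at 1 Hz;
the packaged experiments use 20 beats from the published resting state
rather than 200, after which the beat-to-beat drift of the pre-stimulus
potential is below 0.005 mV/beat and monotonically shrinking (the pacing
helper reports per-beat pre-stimulus V and Ca²⁺ as its convergence
record). The residual difference from a fully converged state is well
inside the tolerances quoted for every packaged measurement.

## Clump geometry and incompressibility

One cell is a rigid clump of n = 9 collinear discs, radius r, spacing d:
L = (n−1)d + 2r and A = nπr² − (n−1)S with S the equal-circle lens area
S = 2r²·arccos(d/2r) − (d/2)√(4r²−d²) (the standard formula; verified
against a Monte-Carlo intersection-area oracle in the tests). At rest
r = 8 µm, d = 10.5 µm, L = 100 µm, A ≈ 1441.3 µm².

A resize imposes a target length at constant area by eliminating
d = (L−2r)/(n−1) and solving the scalar area equation in r: at the API
level by bracketed Brent iteration to 10⁻¹² relative tolerance over the
feasibility bracket r ∈ (L/2n, L/2); inside the simulation kernel by a
warm-started, bracket-safeguarded Newton iteration to the same tolerance
(2–3 iterations per cell per step in practice). Because every solve
targets the stored resting area afresh, errors do not accumulate: 10⁵
consecutive resizes along an SL trajectory keep |A−A₀|/A₀ < 10⁻⁹.
Resizes keep the centroid, orientation and kinematics of the clump
unchanged and distribute particles symmetrically; mass is constant (area
is), and the rotational inertia is recomputed from the disc-union polar
moment (per-disc terms minus lens corrections, with the lens moment by a
32-node Gauss–Legendre quadrature after an arcsine substitution).

## DEM mechanics

Units are SI internally (m, kg, s, N; unit out-of-plane thickness);
µm/ms quantities convert at module boundaries. Particle density is
1.053 g/mL; a resting clump has mass 1.52·10⁻⁶ kg. Gravity is zero.

Contacts join particles of *different* clumps (intra-clump pairs are
skipped) whose surface gap is within a 1 µm detection threshold on the
as-built lattice; detection runs once and the bonded list is frozen (the
dense packing forms no new contacts during contraction). The contact
normal runs between particle centres; the contact plane sits at the
midpoint of the interaction region. The force on the A-side clump is

    F_A = −(k_n·g_s + 2β_n√(m_c k_n)·δ̇_n)·n̂ + (F_s − 2β_s√(m_c k_s)·δ̇_s)·t̂

with g_s the surface gap (negative in overlap, so overlap repels and
bonded separation attracts), δ̇ the relative surface velocity from the
rigid-body fields of the two clumps, F_s the accumulated shear spring
force (incremented by −k_s·δ̇_s·Δt; stored as a scalar in the current
tangent frame, so its magnitude is preserved when the contact plane
rotates), and m_c = m_A m_B/(m_A+m_B). Both dashpots oppose the relative
surface velocity. −F_A acts on B; both act at the contact plane and
contribute moments about each clump centroid. Bond strengths are
effectively infinite; there is no slip model and no bond breakage.

Motion integrates by the explicit centred (leapfrog) scheme: half-step
velocity update from F/m and M/I, full-step position update; fixed degrees
of freedom hold zero velocity and ignore force. Clump rotation is enabled
by default with a config switch to lock it.

**Damping.** The printed contact dashpots act on relative surface
velocities and therefore cannot damp long-wavelength collective modes of a
bonded chain (neighbouring clumps move almost together, so δ̇ ≈ 0 while
the mode rings). With dashpots alone, a 20-cell fibre overshoots its
contraction by a factor of two and buckles at the fixed boundary. We
therefore additionally apply local non-viscous damping in the integrator —
each degree of freedom sees F_eff = F − α·|F|·sign(v), default α = 0.7,
the convention of production bonded-particle DEM engines — which removes
the overshoot: the tissue length then tracks the single-cell length curve
(10×10 patch: minimum 0.8996 vs the cells' 0.8996). α is configurable
(`local_damping`), and the conservation property tests run with α = 0.

**Stability.** `critical_timestep` estimates the stable step as a 0.1
safety factor times min over bodies of √(m/k_eff) and √(I/k_rot), with
k_eff the summed normal stiffness over a body's contacts and k_rot the
stiffness-weighted squared lever arms. For the default parameters this
gives ≈ 8.7 µs, comfortably above the shared Δt = 4 µs; configuration
validation enforces Δt below the estimate.

## Tissue construction and conduction

Cells sit on an unstaggered rectangular lattice, fibre axis along +y by
default: centroids (fᵢ+½)·16 µm across, (j+½)·100 µm along, which makes
end particles of consecutive cells in a fibre exactly tangent and
side-by-side particles of adjacent fibres exactly tangent. Cavities are
axis-aligned rectangles that simply omit cells; boundary conditions pin
the x and/or y velocity of cells in given rectangles. Equilibration cycles
the DEM alone until the mean unbalanced force falls below 10⁻⁵ of the mean
contact force (with a k_n·1 nm force floor in the denominator so that a
pristine tangent lattice, whose forces are pure float noise, counts as
equilibrated).

The conduction graph has one undirected edge per cell pair with at least
one contact (multiplicity deduplicated — along-fibre pairs share 1
contact, transverse pairs 9, both carry the same conductance), uniform
D = 1000 nS. Each step, cell H receives I_st = D·Σ(Vᵢ−V_H) (nS·mV = pA)
computed from the *previous* step's potentials for every cell
(Jacobi-style), making the update order-independent; the coupling
currents sum to zero over the tissue by construction.

The electromechanical cycle per Δt: (1) coupling + protocol currents,
(2) explicit-Euler update of all 32 cell ODE variables per cell, (3)
target lengths from SL, (4) area-conserving resize, (5) DEM force and
motion update. Electrics-only mode (conduction experiments) skips (3)–(5).
Mechanical state does not feed back into conduction (no stretch-activated
currents; the conduction graph is frozen).

## Measurements

* **Activation time**: first upward crossing of −40 mV, linearly
  interpolated between samples (default sampling every 20 steps =
  0.08 ms). The −40 mV choice is mid-upstroke; moving it by ±20 mV
  changes the measured conduction velocity by < 0.1 %.
* **Conduction velocity**: least-squares slope of distance along the
  propagation direction versus activation time, excluding cells within
  10 % of either end of the path (initiation and boundary transients),
  converted to cm/s.
* **Tissue area**: shoelace area of the polygon through the boundary-cell
  centroids in perimeter order (requires a full rectangular patch).
* **Tissue length**: distance between the outer end-particle extremities
  of the central fibre's end cells.

## Packaged experiments and problem sizes

The scenario generator (`atriadem.config.make_scenario`) produces the
standard set-ups; all default paths are deterministic (re-runs are
bit-identical), and the optional lattice jitter requires an explicit seed.

* `single-cell` — one cell, stimulus at t = 50 ms, 600 ms.
* `strip-cv` — 60-cell single fibre, electrics-only, 20 ms. A stimulated
  region must exceed the electrotonic space constant (~11 cells at
  D = 1000 nS; a single stimulated cell plateaus near −72 mV because the
  gap-junctional drain of 1 nA/mV sinks the 2 nA pulse — the classic
  source–sink mismatch), so the first 6 cells are stimulated; they
  coincide with the 10 % fit-exclusion zone, and the velocity is fitted
  over the middle 80 % of the strip. Measured: 50.1 cm/s at D = 1000 nS,
  strictly increasing in D and ∝ √D to a good approximation.
* `anisotropy-patch` — 20×20 cells, electrics-only, 8×8-cell corner
  stimulus; fibre velocity measured down the first fibre, transverse
  velocity across the top row. The ratio is ~6.25, set by the spatial
  step per hop (100 µm along vs 16 µm across at equal per-edge
  conductance and near-equal per-hop delay).
* `contraction-patch` — 10×10 cells, full electromechanics, top 8 rows
  stimulated ("top portion"), bottom row fixed in y, 450 ms — long enough
  for complete relaxation given the ~330 ms action potential. Tissue
  length minimum 0.90 of rest at ~54 ms after the stimulus; final length
  within 0.02 % of rest.
* `paper-tissue` — the full-scale 50×200 layout (10,000 cells, 90,000
  particles, 5 mm × 3.2 mm) for optional long runs; none of the packaged
  measurements require it (the quantities above are insensitive to
  further enlargement within their stated tolerances).

**Area conservation, quantitatively.** Per-cell clump area is conserved to
10⁻⁹ by construction. The boundary-centroid polygon, however, effectively
measures (F−1)·2r × (J−1)·L, and while the disc-union area is invariant
under the resize, the bounding rectangle 2r·L is not: at 10 % shortening
the constant-area solution is r = 8.70 µm, giving 2r·L/(16·100) = 0.979.
A dense tangent lattice therefore shows an intrinsic ~2.1 % centroid-
polygon dip at full contraction — for any patch size — plus a few tenths
of a percent of dynamic transient (measured minimum ≈ 0.971). The polygon
area is thus "conserved" only up to this geometric floor; the property
suite asserts the honest < 3 % bound.

## What the scenarios do and do not show

The lattice is perfectly regular with a single fibre direction,
homogeneous electrophysiology, and tangent packing; real atrial tissue has
curved and branching fibres, cellular heterogeneity (crista terminalis vs
pectinate muscle etc.), connective-tissue filler, and irregular cell
shapes. Passing tests therefore demonstrate the correctness of the
numerical machinery and the emergent cell-level physiology (AP morphology,
Ca²⁺ transient, twitch), the conduction mechanism on the contact graph,
and the contraction mechanics of a uniform patch — not predictive accuracy
for any real atrium. The fibre velocity here (~50 cm/s) is ~9 % below the
commonly quoted experimental 55 cm/s; mechanical stretch does not feed
back into the electrics; and the myofilament parameters are rat-derived,
not human.

## Numerical summary

| quantity | value | notes |
| --- | --- | --- |
| shared time step Δt | 0.004 ms | explicit Euler (cells) + centred difference (DEM) |
| Euler self-convergence | O(Δt), < 1 mV at Δt vs Δt/4 | first order, measured over a beat |
| resize tolerance | 10⁻¹² relative on A | Brent (API) / safeguarded Newton (kernel) |
| equilibration tolerance | 10⁻⁵ unbalanced-force ratio | k_n·1 nm force floor |
| contact stiffness k_n, k_s | 10, 0.1 N/m | with β_n = β_s = 0.1 dashpots |
| local damping α | 0.7 | set to 0 for conservation tests |
| activation threshold | −40 mV | ±20 mV changes CV < 0.1 % |
| pacing | 20 beats at 1 Hz | drift < 0.005 mV/beat at the end |
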