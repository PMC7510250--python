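# Methods

## Model

`venapump` simulates the lower-limb circulation as a closed U-loop of rigid
vessel segments carrying incompressible Newtonian blood (density
ρ = 1060 kg/m³, viscosity η = 0.0035 Pa·s, laminar regime), reduced to a
quasi-1D transmission-line network. Each edge of the chain carries an
inertance `ρl/A` and a linear hydraulic resistance; three special elements
interrupt the chain:

* the **porous baffle** — a lumped linear (Darcy) resistance standing in for
  the arteriolar/capillary bed at foot level;
* two **ball check valves** bracketing the calf trunk, whose pressure drop
  depends on the ball position (see below).

The calf trunk (radius R = 0.25 cm, length L = 30 cm, between z₀ = 10 cm
and z₀+L = 40 cm above the foot) is the only non-rigid part: its wall moves
with the prescribed radial velocity

    v_r(z,t) = a·π·sin(π(z−z₀)/L) · sin(2πt/T₀)/T₀ ,

positive inward during the first half-cycle (muscle systole). The law
integrates to a half-sine displacement profile peaking at `a` mid-trunk at
the end of systole, returns the wall exactly to rest each cycle, and sweeps
`4RaL` of volume per systole (the thin-wall surface integral; the exact
finite-displacement correction is ≲1% at the default amplitude and is
neglected consistently in sources and oracle).

Boundary conditions: pulsatile inlet pressure `100 + 20·sin(2πt/T)` mmHg
(T = 1 s, i.e. 120/80 systole/diastole), outlet 0 mmHg (vena cava). Gravity
(9.81 m/s²) enters as a hydrostatic term `ρg·Δz` in every edge momentum
equation and is switched off for the supine scenario. Initial state:
p = 100 mmHg everywhere, uniform flow at the aortic initialization velocity
35 cm/s; the transient is discarded before metrics (below).

### Assumptions carried over from the idealization

Single unbranched vessel per arm (no perforating or superficial veins — the
deep system is treated as the sole drainage path); rigid walls everywhere
except the prescribed-motion trunk (no venous collapse, no wave
propagation); convective acceleration neglected on plain edges
(resistance-dominated, velocities ≤ 0.35 m/s) and represented only in the
valve orifice loss; balls are neutrally buoyant (with balanced pressures
the valves then float open during quiet standing, with no assumption about
ball material).

## Circuit sizing and hydraulic calibration

Diameters follow the continuity equation from the venous reference pair
(0.5 cm, 0.25 cm/s): artery 0.08 cm at 9.8 cm/s, aorta 0.04 cm at 35 cm/s.
These are *functional* diameters — they reproduce velocities, not anatomy —
and at the reference flow `Q_ref = π·0.25²·0.25 = 0.049 mL/s` their
laminar (Poiseuille) resistances would dissipate several times the
available 100 mmHg head. The canonical circuit therefore carries
**calibrated segment resistances** reproducing the textbook resting
pressure budget at `Q_ref`:

| element | drop (mmHg) | resistance (mmHg·s/mL) |
|---|---|---|
| aorta + artery (130 cm) | 5 | 101.9 (split ∝ Poiseuille share) |
| porous baffle | 80 | 1629.7 |
| foot veins (below the pump) | ≈14.9 | 303.5 |
| calf trunk + conduit veins | ≈0.1 | physical Poiseuille (0.51 + 1.54) |

The venous budget is lumped into the foot-most segment because that is
where venous resistance lives physiologically (small veins and venules);
the wide conduit veins above the pump are hydraulically near-transparent.
This placement leaves the pump's ejection path free and puts the standing
ankle venous pressure at ≈94 mmHg (blood column 93.6 mmHg plus a small
viscous excess). User-defined segments without a calibrated value default
to the Poiseuille closure. Inertances are always physical (`ρl/A`).

## Ball valve closure

Ball (0.52 cm) on a 0.50 cm seat, travel 0.5 cm. The closed stop leaves a
residual clearance `min_gap`: 0.016 cm for a competent valve, 0.2 cm for a
severely incompetent one (incompetence = restricted ball travel). Grades:
healthy (both competent), severe (both restricted), partial (distal
restricted, proximal competent).

* **Leak area.** The residual flow area at the closed stop scales linearly
  with the gap, anchored at 1% of the full opening for the competent
  0.016 cm gap and capped at 100% (severe ⇒ 12.5%). The effective orifice
  area interpolates linearly from leak area (seated) to the seat lumen
  (fully open).
* **Pressure drop.** Quadratic orifice loss `(ρ/2)(Q/A_eff)²·sign(Q)`, plus
  the (negligible) Poiseuille term of the seat lumen, plus a **seat-film
  viscous resistance** that dominates when the ball is seated. The
  closed-stop value follows creeping-orifice (Sampson) scaling with leak
  area, `R_seat ∝ A_leak^{-3/2}`, anchored by a single calibrated constant
  `R_ref = 1.3·10⁵ mmHg·s/mL` at the competent stop, and decays as
  `(A_leak/A_eff)³` on lift-off so an open valve is transparent. The
  anchor was calibrated once against the dysfunction grading (severe
  ≈ 0.125 mL/cycle, a ≈29% reduction of venous return; partial nearly
  healthy) and is recorded in the canonical configurations. A bare
  quadratic orifice would make a seated competent valve far too permeable
  at the suctions a rigid loop develops; a thin-annulus lubrication law
  (cubic in the gap) would make the severe valve essentially open. The
  3/2-power law is the intermediate closure consistent with both anchors.
* **Ball dynamics.** Forces on the ball: pressure difference over the ball
  cross-section (dynamic pressures — hydrostatics and buoyancy cancel for a
  neutrally buoyant ball), Stokes drag `3πηd·(v_fluid − v_ball)`, and net
  weight for non-neutral densities. Default motion is first-order
  relaxation toward the stop selected by the force sign with time constant
  5 ms (stable at the fast time step and converging to the same cycle
  metrics as the optional inertial mode, which integrates Newton's law with
  hard stops). As the relaxation time → 0 the valve tracks the sign-of-Δp
  open/closed solution.

## Numerics

Chain discretization at Δx = 1 cm (263 edges for the canonical loop; valve
and porous edges have zero arc length). The semi-implicit step treats
pressures, linear friction and the linearized orifice term implicitly and
forcing/valve state explicitly; the nodal system is tridiagonal and solved
directly, so nodal mass balance closes to solver precision at every step
(checked against a 10⁻⁹ mL tolerance). An explicit-friction mode exists for
cross-checks at small Δt. Two time steps: 10 ms for resting scenarios,
0.2 ms when the pump is active (snapped to an integer count per cycle); the
Courant number `v·Δt/Δx` is checked against 1 with a 0.35 m/s reference
velocity before a run starts, and a non-finite state raises a numerical
failure carrying the last valid time.

Degenerate inputs behave as limits: zero wall amplitude reproduces the
resting scenario bit-for-bit (and selects the slow step), zero gravity
removes all hydrostatic terms, and a zero-forcing zero-flow state is a
fixed point. Transient discard: at least 2 initial cycles, then everything
before the first cycle whose net volume changed < 1% from its predecessor;
reported metrics average all remaining cycles (the full post-transient set,
since no particular averaging window is canonical). Default run lengths —
10 cycles for walking, 15 for resting — put the discard point well past the
loop's hydraulic time constant (≈0.01–0.25 s); halving Δx and Δt together
moves the healthy walking net volume by well under 2%.

## What the scenarios do and do not show

The five canonical scenarios are *model experiments*, not data fits: their
defaults (geometry, forcing, gaps, time steps) are the study conditions
stated above, and passing tests demonstrate internal consistency of the
solver (mass conservation, analytic Poiseuille/hydrostatic/swept-volume
oracles, knee–ankle agreement, valve rectification and monotonicity in the
leak gap) plus reproduction of the calibrated operating points. They do not
demonstrate fidelity to real limbs: real venous return involves perforating
and superficial veins, collapsible walls, respiration-modulated outflow and
gait-specific muscle activation, none of which are modelled.

## Known limitations

* **Sub-additive pump + arterial contributions.** In this rigid,
  quasi-static loop the healthy walking net output converges to ≈0.176 mL
  per cycle: the swept 0.15 mL plus only ≈0.028 mL of systolic arterial
  passthrough, because the same capillary-bed resistance that sets the
  resting 0.049 mL/cycle also throttles the arterial feed while the calf is
  pressurized (and the diastolic refill can never exceed the swept volume).
  A simple sum of the walking pump output and the full resting flow
  (0.15 + 0.05 = 0.2 mL) is not achievable in this class of model without
  compliance; the corresponding ejection fraction is 3.0% rather than 3.3%,
  and the pump gain over standing is ≈3.6 rather than 4. All
  volume-conservation and reflux diagnostics hold at these values.
* **Non-physiological calf pressures during valve closure.** With no
  perforating veins, the prescribed wall motion drives the calf pressure to
  large positive values during systole against a seated valve and to large
  suctions (hundreds of mmHg below atmospheric) during diastolic refill.
  These are reported as computed, never clamped; they are a known artefact
  of prescribing wall motion in a rigid single-path network.
* **Standing arterial pressure at the foot** computes to ≈196 mmHg
  (100 mmHg mean drive + 101 mmHg column − viscous loss); textbook values
  near 185 mmHg imply a measurement station somewhat above the foot. Probe
  placement, not physics, dominates this comparison, so resting pressures
  are treated as ±10% calibration checks only.
* The seat-leak law and the severe-grade anchor are closures, not measured
  valve hydraulics; a parametric study of gap vs reflux would be needed to
  constrain them independently.
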