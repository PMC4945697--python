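# Methods

## Scope and modelling stance

`dissectflow` is a reduced-order (0D) model of the circulation around an
aortic dissection. Every vessel territory is a lumped compartment: the 3D
patient geometry that a finite-element CFD study would resolve is replaced by
a compartmental chain whose elements carry resistances, the septum by
discrete tear connections, and the distal vasculature by three-element
Windkessel models. This buys speed and testability at the cost of all field
information (velocity profiles, wall shear stress, jet impingement); the
package therefore reproduces *network-level* quantities — flow splits,
cycle-mean pressures, stroke work, directional responses to topology changes
— and makes no claim about local 3D haemodynamics.

All computation uses a g–mm–s unit system (pressure in g mm⁻¹ s⁻²,
1 mmHg = 133.32; flow in mm³ s⁻¹; energy in g mm² s⁻² = 10⁻⁹ J). The
conversion constant is defined once in `units.py`; it is consistent with the
packaged heart table's preload of 533.320 for 4 mmHg.

## Windkessel outlets

Each outlet is the standard RCR element

    P = R_p Q + P_c,      C dP_c/dt = Q − (P_c − P_d)/R_d,

with `P` the interface pressure seen by the network and `P_c` the single
state. `P_d` is a ground reference, zero by default and configurable per
outlet. The state update is backward Euler — unconditionally stable, which
matters inside the implicit network solve where valve switching can make
time constants change abruptly. Two analytic oracles guard the
implementation: free decay of `P_c` follows `exp(−t/(R_d C))` with
first-order step-size convergence, and the cycle-mean interface pressure of
a periodic inflow equals `Q̄ (R_p + R_d) + P_d` once cyclically converged.

The packaged registry holds the tuned parameters of the 18 aortic branch
outlets in canonical units. (The source study's text speaks of 17 outlets
while its parameter table prints 18 rows, including two right-renal and two
medial-sacral entries; the registry follows the table.)

## Heart model

The left ventricle is a time-varying elastance chamber,
`P_LV = E_LV(t)(V_LV − V_u)`, with a piecewise-cosine elastance: half-cosine
rise from `E_min` to `E_max` over `t_max` seconds, half-cosine fall over
`t_relax`, flat at `E_min` for the rest of the cycle. The exact trigonometric
form used by the original lumped heart literature is not printed in the
source material; the cosine surrogate is C⁰-continuous, attains the two
printed timing parameters exactly, and is documented as a surrogate rather
than claimed identical.

Filling comes from a constant atrial pressure `P_LA` through a mitral
resistance–inductance pair; ejection passes an aortic pair. Both valves are
ideal diodes: within each implicit step the open/closed state is frozen, the
step is solved, and a flow that crossed zero is clamped and the step
re-solved — so `Q ≥ 0` holds exactly at all times and early-diastolic
backflow is structurally impossible. The ventricular viscous loss
`ΔP = k_LV P_LV Q` (the only dimensionally consistent reading of the
`R_LV = k_LV P_LV Q_LV` construction, with `k_LV` in s/mm³) acts on whichever
valve flow is active. Notably, with the packaged parameters this term
supplies the dominant damping of the mitral L–elastance oscillation (damping
ratio ≈ 0.57); without it the E-wave would ring almost undamped. The
residual inertial overshoot still carries the end-diastolic volume to
≈ 147 mL against the nominal 130 mL equilibrium — a known feature of this
parameter set, reflected in the test envelope for the untuned reference run
(peak chamber pressure ≈ 195 mmHg untuned, 149 mmHg at the tuned operating
point).

Stroke work is the shoelace area of the (V, P) loop over one converged
cycle, reported in joules. An energy audit is tested to 2 %: loop area =
boundary work at the aortic interface − atrial filling work + valve and
viscous dissipation (the inductive terms integrate to ~0 over a period).

### Cardiac-output tuning

`tune_elastance` adjusts `(E_max, t_max)` in log space by damped secant
(Broyden) steps — damping 0.5, per-step clip 0.25, cap 30 evaluations — until
the coupled heart–afterload simulation matches its mean and peak aortic-flow
targets within 5 %, the stopping rule of the study workflow it mirrors.
Non-convergence raises, carrying the full iteration log. Against the packaged
afterload the loop terminates in ~5 evaluations with both errors ≈ 4 %.

The packaged single-Windkessel afterload (`R_p = 0.008`, `C = 11`,
`R_d = 0.176` canonical) gives ~92 mmHg mean pressure at 4.4 L/min, a
proximal share approximating the aortic characteristic impedance, and a
diastolic decay time of ~1.9 s.

## Dissection network

The surrogate topology is: ascending aorta and arch (upper-branch outlets),
then either a single descending chain (undissected) or parallel true/false
lumen chains of six nodes each. The entry tear (135 mm²) joins the chains
proximally, the exit tear (68 mm²) distally, and 15 secondary tears
(20 mm² each, an assumption — they are not reliably imaged) cluster at the
visceral stations. The maximal variant adds two thoracic tears; the minimal
variant keeps only entry and exit. Visceral branches perfused from the false
lumen (left renal, inferior mesenteric, both medial sacral) attach to FL
nodes, the rest to TL nodes; iliac outlets sit past the distal reunion.

Segment resistances are Poiseuille (`8 μ L/(π r⁴)`, blood viscosity
4×10⁻³ g mm⁻¹ s⁻¹, density 1.060×10⁻³ g mm⁻³); optional per-segment
inertance and compliance exist but default to zero, so the packaged network
is rigid and conserves mass exactly at every instant. Tear resistances use
the Poiseuille formula on the effective circular diameter with a 2 mm septum
channel (assumed thickness); a quadratic orifice loss is available behind a
config flag and off by default. Poiseuille resistances cannot reproduce the
jet-dominated losses of the real 3D field, which is why the TL/FL calibre
pair is *calibrated*: the false-lumen radius is fixed at 8.5 mm and the
true-lumen radius swept by `analysis/02`, freezing 6.2 mm where the
demonstration descending split lands at 24/76 — near the reference
simulation's 25/75. Consequences of this compromise: interluminal pressure
differences are small (≲ 0.3 mmHg) and the tear-sensitivity experiment
reproduces the *directions* of the reference findings (TL flow up, TL peak
pressure down without secondary tears; near-insensitivity to extra thoracic
tears; tears equalise interluminal pressure) but not their magnitudes.

### Solver

The monolithic system — nodal flow balances, Windkessel states, heart states
— is advanced by backward Euler with Newton iteration per step (the heart's
bilinear viscous term is the only nonlinearity; valve states are frozen per
solve as above). Newton is capped at 20 iterations (step error with time
stamp beyond that) with a 10⁻⁸ relative update tolerance, which sits safely
above the round-off plateau of the mixed-scale system matrix. For
prescribed-flow inlets the system is linear and a single LU factorisation
serves the whole run.

Cyclic convergence is declared when every outlet's cycle-mean pressure and
flow change by < 10⁻³ (relative) between consecutive cycles — the same order
as the residual control of the CFD workflow this mirrors. Because the
slowest Windkessel relaxation times exceed the cardiac period, plain cycling
from rest would need tens of cycles; two accelerations avoid that without
touching the declared criterion:

* **Linear runs** start from the exact periodic orbit of the backward-Euler
  cycle map: the map is affine in the state (capacitor pressures), so one
  matrix-valued cycle propagation identifies it and `(I − M)⁻¹ c` is the
  fixed point. Fixtures then converge in 2–3 cycles.
* **Heart-driven runs** start from the steady (DC) solution at an
  ejection-fraction-based mean-flow guess and apply Aitken extrapolation to
  the cycle map every other cycle.

Default step size is 1 ms (1300 steps per 1.3 s cycle); the solver refuses
coarser steps. Halving dt changes outlet cycle means by ≪ 0.5 %.

## Synthetic data

The inflow generator emulates a gated 2D PC-MRI flow curve just distal to
the aortic valve: 25 phases at 52 ms over a 1.3 s cycle, half-sine systolic
pulse over a 0.33 systolic fraction, renormalised so the sampled net volume
is exactly the 94 mL stroke volume. An optional negative early-diastolic
lobe (default off, 3 % of SV available) emulates the slight measured
backflow that the diode heart model cannot produce. What the generator does
*not* emulate: the patient's actual pulse shape (only stroke volume, rate
and qualitative shape are recoverable), VENC saturation, and gating noise —
so tests passing on synthetic inflow validate the machinery, not fidelity to
any individual's waveform.

A bookkeeping caveat: the source flow report pairs a 1.3 s period with a
rounded 47 beats/min and a 4.4 L/min output; 94 mL × 47 min⁻¹ gives the
printed 4.4, while 94 mL / 1.3 s gives 4.34. The package keeps the 1.3 s
period for all simulations and uses the printed rate only in the
flow-bookkeeping check.

The measurement generator reproduces the reference per-lumen means at three
descending stations (TL 15.1/11.1/7.9, FL 40.6/42.5/42.4 cm³/s) with
optional seeded multiplicative noise. Reported totals (55.6/53.8/50.3) carry
their own rounding and are therefore stored as data — consistent with TL+FL
to 1 %, enforced — because the published error arithmetic is computed
against the totals as printed.

## Comparison statistics

Relative errors are signed percents `100 (sim − meas)/meas`; lumen fractions
are reported both as ratio-of-means across stations (display convention,
rounded to integers) and mean-of-ratios. Unrounded values are always
retained. On the reference inputs the module reproduces every published
error to one decimal, and reports the simulated FL fraction as the computed
75.3 % (the source displays 76 %, a rounding the module deliberately does
not imitate).

## Numerical and design choices, in brief

* Backward Euler everywhere: robust with diode switching; first-order
  accuracy is ample at 1 ms steps (dt-refinement changes means by < 0.5 %).
* Trapezoid quadrature with wrap-around for all cycle means: exact for the
  piecewise-linear sampled waveforms.
* Valve frozen-state stepping with post-step re-evaluation (≤ 3 re-solves):
  mirrors instantaneous closure while keeping the step implicit.
* Segment compliance, when used, splits half to each end node.
* Self-intersecting/clockwise PV polygons return the absolute area with a
  warning rather than failing.
* Tuning damping 0.5: the coupled gain is afterload-dependent; undamped
  secant steps overshoot and oscillate.

## Problem sizes

The packaged analyses use 1 ms steps (1300 per cycle), networks of ~20 nodes
with 18 outlets, and converge within 3 cycles (prescribed flow) or ~7 cycles
(heart-driven); a full fixture simulation takes well under a second and the
tuning loop a few seconds, so the entire test suite and analysis pipeline
run on one CPU in minutes.

## Known limitations

* Rigid network: no wall or septum compliance, so simulated lumen waveform
  amplitudes would exceed gated-MRI ones, as in any rigid model.
* Poiseuille-only losses: tear and lumen resistances ignore inertial/orifice
  effects unless the orifice flag is enabled; magnitudes of tear-sensitivity
  responses are indicative only.
* No baroreflex or autoregulation: boundary conditions are identical across
  variants by construction.
* Single-patient parameterisation: the registry and heart table describe one
  subject; nothing here generalises across patients without re-tuning.
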