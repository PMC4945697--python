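# dissectflow

Reduced-order (0D) haemodynamics of aortic dissection.

In a Stanford type B dissection the aortic wall splits into a narrow **true
lumen** (TL) and a larger **false lumen** (FL), separated by an intimal flap
with a primary entry tear, an exit tear, and a variable number of small
secondary communicating tears. Two clinical questions drive this package: how
the split channel redistributes flow and pressure down the aorta, and how much
extra work the dissection imposes on the left ventricle. `dissectflow`
answers both at the lumped-parameter level: every vessel territory is a
compartment, so whole-aorta experiments (remove the septum, delete tears,
raise the afterload) run in seconds on a laptop.

The package is aimed at cardiovascular modellers who want a tested,
scriptable 0D counterpart to patient-specific CFD: for boundary-condition
design, for tuning outlet parameters before a 3D run, or for teaching the
coupled heart–afterload physiology.

## Models

**Three-element Windkessel outlets.** Each of the 18 branch outlets (carotid,
subclavian, visceral, renal, sacral, iliac) carries an RCR model

    P = R_p Q + P_c,        C dP_c/dt = Q − (P_c − P_d)/R_d,

with the tuned per-outlet parameter table shipped as packaged data. At cyclic
convergence the mean obeys `P̄ = Q̄ (R_p + R_d) + P_d`, which the solver is
tested against.

**Time-varying elastance heart.** The left ventricle satisfies
`P_LV(t) = E_LV(t) (V_LV − V_u)` with a piecewise-cosine elastance between
`E_min` and `E_max` (rise time `t_max`, relaxation `t_relax`), filled from a
constant-pressure atrium and ejecting through resistive–inductive valve
diodes that clamp reverse flow to zero the instant an adverse gradient
appears. A ventricular viscous loss `ΔP = k_LV P_LV Q` damps the valve
dynamics. The enclosed pressure–volume loop area is the stroke work. A
damped two-variable secant loop tunes `(E_max, t_max)` until mean and peak
aortic flow match their targets within 5 %.

**Dissection network.** The aorta is a compartmental chain: trunk and arch
segments, parallel TL/FL chains with Poiseuille resistances
`R = 8 μ L / (π r⁴)`, tear connections sized from their areas via the
effective diameter `d = 2 √(A/π)`, and Windkessel outlets. Four packaged
fixtures mirror the study designs: *undissected* (single channel, no tears),
*dissected baseline* (entry 135 mm², exit 68 mm², 15 secondary tears),
*maximal tears* (19) and *minimal tears* (2). The monolithic implicit solver
(backward Euler + Newton) advances all states together and stops when every
outlet's cycle-mean pressure and flow change by less than 0.1 % between
cycles.

## Worked example

```python
import dissectflow as df

inflow = df.generate_inflow(df.InflowSpec())        # SV 94 mL, 1.3 s period
topo   = df.build_network(df.fixture_configs()["dissected_baseline"])
sol    = df.simulate(topo, inflow)
print(sol.n_cycles, df.lumen_flow_split(sol, "proximal"))
```

prints

```
2 {'Q_TL': 13291.1..., 'Q_FL': 41589.7..., 'total': 54880.8...,
   'fraction_TL': 24.21..., 'fraction_FL': 75.78...}
```

— the network converges in 2 cycles; the true lumen carries 24 % of the
54.9 cm³/s descending flow and the false lumen 76 %, the calibrated
demonstration split. Tuning the heart against the packaged single-Windkessel
afterload:

```python
heart = df.load_heart_params("dissected")
tuned = df.tune_elastance(4.4e6/60, inflow.metrics()["peak"],
                          df.single_rcr_afterload(), heart)
print(f"{tuned.mean_error_pct:+.2f}% {tuned.peak_error_pct:+.2f}%")
```

prints `+4.00% +3.59%`: both cardiac-output errors are inside the 5 %
stopping rule after five evaluations.

The numbered drivers under `analysis/` run the full study pipeline
(input generation, lumen-geometry calibration, descending-flow comparison,
stroke work under raised afterload, tear-count sensitivity) and write their
tables under `results/`. The same functionality is available from the shell
via the `dissectflow` CLI (`simulate`, `tune`, `compare`, `generate`,
`fixtures`).

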