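# Methods

## Mechanical model of the injection cycle

The injector is modelled as two coupled piston–cylinder stages driven by a
compressed-gas reservoir through a control valve.

**Gas.** Both gas volumes (reservoir, and the lower half of the main fluid
cylinder) are isothermal ideal gas. Each is tracked as a pressure–volume
inventory `pv = P·V` (Pa·m³), which is invariant under isothermal expansion,
so Boyle's law is built in and conservation across the valve is exact by
construction: the valve only moves inventory between the two compartments.
No gas constant or temperature enters the equations. The valve is a linear
conductance: volumetric flow `C_v·(P_up − P_down)` metered at the upstream
pressure, i.e. `d(pv_lower)/dt = C_v·(P_res − P_low)·P_res` for forward
flow (sign-symmetric for backflow). No published valve law exists for the
device, so `C_v` is a free design parameter of the preset (below).

**Insertion phase.** The drug is incompressible, so fluid-piston motion is
rigidly geared to needle-piston motion by the area ratio
`r = A_f/A_n = (1.07/0.5)² ≈ 4.58`. The coupled assembly is lumped into a
single inertia (the 500 g chassis mass) in the fluid-piston coordinate:

```
m ẍ = A_f (P_low − P_atm) − r [k x_n + b ẋ_n + F_tissue(x_n, ẋ_n)]
```

with `x_n = r·(x − x₀)` the needle travel, `k` the 11 N/m spring and `b`
the 11 N·s/m dashpot anchoring the inner assembly to the chassis (the
published table prints the dashpot value in N/m, a stiffness unit; it is
interpreted here as N·s/m). Needle-side forces appear reflected through `r`
(virtual work). The assembly cannot retract below its stowed position
(one-sided stop). No drug flows through the needle in this phase — flow is
hard-gated on full insertion, since the reference behaviour shows flow
beginning exactly when the needle piston plateaus.

**Tissue force.** A piecewise model of piston travel `d`:
a membrane-puncture bump for `d` below the membrane standoff `s`, shaped as
a half-sine `F_p·sin(π d/s)` so the force is zero at first contact and
continuous at breakthrough (a discontinuous indicator would be equivalent
for the peak bound but hostile to the integrator), then tissue elasticity
plus drag: `k_t·(d − s)₊ + b_t·ẋ₊`. Defaults `F_p = 1 N`, `k_t = 150 N/m`,
`b_t = 10 N·s/m` are in the range of reported 30-gauge needle insertion
forces and make the elastic term alone `150 × 0.008 = 1.2 N` at full 8 mm
insertion, so the > 1 N peak-force design bound is met by the static tissue
load, not by an artefact of insertion speed.

**Infusion phase.** The stop ring fixes the needle assembly at full stroke;
the regime is viscous-dominated, so piston inertia is dropped and the piston
is slaved to the flow:

```
Q = max(0, P_low − P_atm − P_subq) / R,   R = 8 μ L / (π r⁴)
ẋ = Q / A_f,   v̇_inj = Q
```

with `μ = ν·ρ = 0.658 cSt × 992.562 kg/m³ ≈ 6.53·10⁻⁴ Pa·s` and the
30-gauge needle (0.6 mm bore, 8 mm long) giving `R ≈ 1.64·10⁹ Pa·s/m³`.
Tissue back-pressure defaults to 0 gauge (configurable). The cycle ends at
the dose-complete event (`v_inj` reaches 1 ml), at fluid-stroke exhaustion,
or at a 10 s integration cap; the latter two mark the trajectory *stalled*.

**Integration.** LSODA with `rtol 1e-8`, `atol 1e-10` and root-finding
terminal events; trajectories are exported on a 1 ms grid plus event
endpoints. The impact at the stop ring is treated as plastic (velocities
zeroed); between doses the device state is latched — the valve closes and
the piston is held, so residual lower-compartment pressure does not bleed
extra drug through the still-inserted needle. Repeat doses therefore resume
as pure infusion from the previous terminal state.

## Preset calibration and the gas budget

The published parameter table is shipped verbatim as the `table1` preset.
Its gas reservoir (5 atm × 0.254 cm³) is, however, insufficient: expanding
to 1 atm it can displace only ~1.02 cm³, while one dose requires the lower
compartment to grow to ~1.9 cm³ (insertion travel + 1 ml) and the three-dose
schedule to ~3.9 cm³. Validation therefore emits a warning (not an error)
when the budget is below `dose_volume × max_doses`, and simulating `table1`
reproduces the stall honestly (the cycle never completes; the trajectory is
flagged). The `default` preset keeps every published mechanical parameter
and raises only the gas charge to **20 atm**, the smallest round value whose
Boyle equilibrium over the full three-dose displacement stays usefully above
atmospheric (1.23 atm, leaving ~0.23 atm of driving pressure at the end of
dose 3). 16 atm, a natural first guess, still equilibrates below 1 atm
(0.98 atm) once insertion travel is counted, and so cannot finish dose 3.

The valve conductance is pinned at `C_v = 8·10⁻¹⁴ m³/(s·Pa)`, chosen so the
first cycle of the default preset completes in ≈ 1.0 s — matching the
~1.2 s design milestone with margin; later doses run slower (the reservoir
has depleted) but still finish within seconds, far inside the 5-minute
re-dose interval. The membrane standoff defaults to
`stroke − needle length = 3 mm` so that full piston travel yields exactly
8 mm of tissue insertion.

## Dose controller

A four-mode state machine (MONITORING → AWAITING_RECHECK → … → EXHAUSTED)
stepped once per SpO2 sample (default 1 Hz). Triggering is single-sample
(`spo2 ≤ 90 %`), faithful to the stated behaviour; an optional
`persistence_samples` config supports sensitivity studies. The alert is
emitted exactly once per episode, with the same timestamp as dose 1.
Re-checks evaluate the first sample at or after `last_dose + 300 s`;
continued desaturation earns the next dose (to a maximum of three),
recovery closes the episode. A recovered-then-relapsed wearer does not
re-trigger without an explicit device reset: a fresh episode needs a fresh
needle, reservoir and gas charge, so re-arming is a physical intervention,
not a software transition. Stalled injection cycles are logged as
DEVICE_FAULT events and monitoring continues.

Screening applies the wearing criteria: no cardiac/pulmonary history, no
heart/lung exam findings, resting SpO2 ≥ 93 % (the accepted lower limit of
normal); all failed criteria are reported by name.

## Synthetic physiology

The SpO2 signal is baseline + disturbance, not a mechanistic respiratory
model:

* **Baseline**: `mean (95 %) + diurnal sinusoid (±0.5 %, 24 h period) +
  Gaussian sensor noise (σ 0.5 %)`, clipped to [0, 100]. The defaults keep
  the signal inside the accepted normal band 93–97 %.
* **Overdose**: from a configurable onset, a deterministic ramp at
  `desaturation_rate` (preset 2 %/min — illustrative; no quantitative
  overdose desaturation rate is published) down to a floor (70 %).
* **Dissociation curve**: the Severinghaus closed form
  `S = 1/(23400/(P³+150P)+1)`; its numerical inverse (Brent root of the
  monotone cubic) gives PaO2 58.7 mmHg at 90 % saturation, within the ±3
  mmHg tolerance adopted for the conventional "≈ 60 mmHg" correspondence.
  SpO2 is equated with SaO2; oximeter error can be injected as extra noise
  but is off by default so milestone runs are deterministic.
* **Antidote response** (optional `pk_feedback`): each dose follows a
  one-compartment model with first-order subcutaneous absorption `ka`
  (default 6 h⁻¹; `inf` degenerates to a bolus) and first-order elimination
  at the 8 h plasma half-life; doses superpose. The receptor-level effect is
  the saturable fraction `f = C/(C + EC50)`; it scales the opioid's
  desaturation drive by `(1 − f)` and relaxes the accumulated deficit at
  `recovery_rate·f`. The deficit is stepped with the forward-Euler rule on
  the sample grid — exact for the piecewise-linear untreated ramp — which
  makes the offline generator, the post-hoc dose-response overlay and the
  sample-by-sample closed-loop simulator bit-identical for the same seed,
  parameters and dose times.

All randomness flows through one named, seeded NumPy generator; the seed is
recorded in trace file headers and run manifests.

What the generator does *not* emulate: motion artefact and probe dropout,
ventilatory CO₂ dynamics, opioid dose–response heterogeneity, and the
oximeter's optical path. Passing tests therefore demonstrate the *device
logic and mechanics* under clean, well-specified physiological conditions —
not detection performance on real-world oximetry.

## Problem sizes

The shipped scenarios run at 1 Hz for 600–900 s (normal / overdose
episodes); injection cycles integrate 1–10 s of device time on a 1 ms
output grid. These sizes exercise every phase transition, the full
three-dose schedule and both stall paths.

## Known limitations

* Isothermal gas: rapid expansion in a real device cools the gas and lowers
  driving pressure; the 20 atm budget carries no thermal margin analysis.
* The valve is a linear conductance; a real solenoid/orifice is choked-flow
  nonlinear. `C_v` is a calibration constant, not a hardware datum.
* Piston friction and seal stiction are absorbed into the dashpot constant.
* The programmable flow-profile hook (piston-position feedback control of
  the valve) is exposed in configuration but only the stop-at-1-ml rule is
  implemented, as no target profile is published.
* The tissue model is a lumped spring/damper with a membrane bump; needle
  bending, tissue deformation and depth-dependent heterogeneity are out of
  scope.
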