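# Methods

## Model

The upper urinary tract during ureteroscopic irrigation is treated as a pipe
network feeding a single compliant chamber. Three hydraulic resistances
describe the circuit:

* **Rin** — the scope's irrigation channel, a circular Poiseuille conduit
  (R = 128 μ ℓ / (π d⁴));
* **Rout** — the drainage path around the inserted scope: the short annular
  UPJ segment in series with either the annular sheath lumen or, without a
  sheath, the annular ureter. Annular conduits use the effective
  fourth-power diameter d̃⁴ = d_o⁴ − d_i⁴ − (d_o² − d_i²)²/ln(d_o/d_i);
* **Rw** — the same path with the scope removed: circular conduits at the
  nominal (relaxed) diameters.

The renal pelvis obeys a linear pressure–volume law ΔP = K ΔV with constant
stiffness K. Mass conservation then yields a first-order linear ODE per
phase, solved in closed form (exponential rise to
P_max = P_irr (1 + Rin/Rout)⁻¹ with τ_in = (Rin/K)(1 + Rin/Rout)⁻¹;
exponential decay to zero gauge with τ_out = Rw/K). Pressures are gauge
relative to the bladder/atmospheric baseline and never negative for
nonnegative initial pressure.

Assumptions: Newtonian, incompressible, laminar, quasi-static flow with
no-slip walls; rigid conduit geometry within a phase (the distension of the
soft UPJ/ureter by the scope is a fixed geometric factor, not
pressure-dependent); constant K over a run; irrigation fully off while the
scope is withdrawn; instantaneous reinsertion with continuous pressure and
discontinuous resistance switching. Bladder outlet resistance and filling,
peristalsis, viscoelastic or Neohookean tissue behaviour, and turbulent or
entrance corrections are out of scope.

## Parameters

Defaults (the representative device/anatomy set; all configurable):

| parameter | default | unit | notes |
|---|---|---|---|
| P_irr | 150 or 200 | cm H₂O | irrigation bag/pump pressure |
| d_sc | 7.5 | Fr | scope shaft, tip diameter taken for the whole shaft |
| d_irr | 3.6 | Fr | working-channel diameter |
| ℓ_sc | 67 | cm | working length |
| d_sh | 10, 11, 12, 14 | Fr | sheath inner lumen ("10/12" = 10 Fr lumen / 12 Fr outer) |
| ℓ_sh | 35 | cm | sheath length |
| d_upj | 1.3 | Fr | nominal UPJ diameter, from the Whitaker inversion below |
| ℓ_upj | 0.5 | cm | UPJ length |
| d_ur | 8.5 | Fr | nominal ureter diameter |
| ℓ_ur | 25 | cm | ureter length |
| K | 0.4 | cm H₂O/mL | renal pelvis stiffness; source literature also prints 0.41, and its spread (±0.3) makes K the dominant uncertainty |
| μ | 1 | cP | saline |
| ureter stretch | 1.14 | — | distended ureter diameter / scope diameter |
| UPJ stretch | 1.11 | — | distended UPJ diameter / scope diameter |

Unit conventions: 3 Fr = 1 mm, 1 cm H₂O = 98.1 Pa, so 1 cm H₂O/mL =
9.81×10⁷ Pa/m³. All internal math is SI; clinical units appear only at
boundaries (configs, CLI, CSV headers).

**Whitaker inversion.** The nominal UPJ diameter comes from inverting
Poiseuille's law at an unobstructed-ureter Whitaker operating point:
ΔP = 15 cm H₂O, Q = 15 mL/min, ℓ = 0.5 cm, μ = 1 cP gives
d = (128 μ ℓ Q / (π ΔP))^{1/4} ≈ 1.29 Fr. Note the flow-rate unit: reading
the operating point as 15 mL/s instead yields ≈3.6 Fr; only the mL/min
reading is consistent with a 1.3 Fr junction, so mL/min is the default and
both conversions are exposed (`ml_per_min_to_m3_per_s`,
`ml_per_s_to_m3_per_s`).

**Stretch factors.** While the scope is inserted, the soft ureter and UPJ
are distended to 1.14× and 1.11× the scope diameter. These are calibrated
values consistent with published ex-vivo pressure data; they are ordinary
config fields, not constants.

## Scenario sets and what they emulate

`fig2_scenarios()` crosses four drainage options (no sheath, 10/12, 12/14,
14/16 Fr) with 150 and 200 cm H₂O irrigation at zero baseline pressure —
eight curves whose plateau fractions are ≈84%, 41%, 22% and 19% of P_irr.
Normalized by P_irr and τ_in they form exactly four groups (one per drainage
geometry); normalized by the per-curve plateau they all coincide with
1 − e^(−t̂).

`rehman_shao_scenarios()` mirrors the structure of two earlier clinical
protocols: four flexible-scope sheath conditions at 200 cm H₂O, plus nine
semirigid-scope cases crossing three ureteral stone locations with three
irrigation pressures at a nonzero baseline pressure. The semirigid scope's
channel diameter, the three pressures (200/150/100 cm H₂O), the three stone
locations (5/12.5/20 cm from the ureteral orifice) and the 10 cm H₂O
baseline are *synthetic placeholder defaults* — the sources do not print
them — and are chosen to be clinically plausible; the 13-curve structure and
the near-collapse behaviour do not depend on their exact values. A stone in
the ureter truncates the annular outflow path at the stone's distance from
the orifice (measured increasing proximally; only the segment length enters
the math).

These scenario sets exercise the model, not real measurements: passing tests
show internal consistency and reproduction of the model's printed outputs,
not agreement with any clinical trace.

## Numerical choices

* Closed forms are exact; the numerical oracle (`integrate_ode`,
  scipy LSODA, rtol 1e-9 / atol 1e-6 Pa) exists to cross-check them and is
  held to 1e-6 relative agreement — far below any model-relevant pressure.
* Time-averaged pressure, peak pressure and time-above-threshold are
  computed from exact per-phase integrals and crossing times carried on the
  trace (`PhaseSegment`), so refining the sampling interval changes them by
  exactly zero. The averaging window defaults to the full procedure
  (insertion + withdrawal); insertion-only is exposed because the convention
  is genuinely ambiguous, and the two differ by under 2% of P_max for the
  headline schedule, so the choice is immaterial.
* A degenerate annulus (outer ≤ inner diameter) is a hard error rather than
  a clamped zero-gap: silent infinite resistance would mask configuration
  mistakes.
* The annular→circular limit converges only logarithmically
  (correction ∝ 1/ln(d_o/d_i)); tests assert the limit qualitatively rather
  than at a fixed small ratio.
* The running time average is implemented as the exact integral of the rise
  solution, P̄ = P_max − (τ_in/t)(P_max − P₀)(1 − e^(−t/τ_in)); the minus
  sign on the transient term is forced by the t → 0⁺ limit P̄ → P₀.
* Protocol sampling grids are half-open per phase with the global endpoint
  appended, so phase boundaries appear exactly once (pressure is continuous
  there by construction, jump < 1e-9 Pa).

## Problem sizes

The shipped simulations are desk-scale: single procedures of 20–29 min
simulated analytically, sweeps of 12 (sheath, schedule) pairs, collapse
checks on ≤ 13 curves over 201 grid points. The full test suite, including
the randomized ODE-oracle sweeps, runs in a few seconds.

## Known limitations

* K is the dominant uncertainty (reported spread ±0.3 cm H₂O/mL around
  0.4); it scales both time constants linearly but leaves P_max untouched.
* The plateau fractions are "set fractions" of P_irr only because every
  resistance is pressure-independent; compliant conduits would break this.
* No bladder outlet model: without a sheath, drainage ends at the ureter,
  which overstates how freely the no-sheath configuration drains.
* The withdrawal model assumes irrigation stops exactly at removal and the
  drainage path instantly reverts to nominal circular geometry; transition
  hydraulics during the (seconds-long) exchange are not modelled.
* Stone-location resistance treats the stone as repositioning the scope tip,
  not as an obstruction with its own gap geometry.
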