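# Methods

This note documents the model equations, the parameter choices and their
rationale, the calibration procedure behind the shipped defaults, the
numerical scheme, and what the simulator's results do and do not say about
real patients.

## Scope and design

The simulator is a deliberate reduction of a full physiology engine: it
keeps the subsystems that the naloxone-requirement analysis actually reads
out — drug transport, mu-receptor pharmacodynamics, chemoreceptor control
of breathing, oxygen saturation — and replaces everything else (circuit
haemodynamics, renal/GI fidelity, blood-gas diffusion chemistry) with the
smallest surrogate that preserves the feedback topology. Cardiac output is
a constant: fentanyl's cardiovascular effects are out of scope because the
analysis only reads respiratory outputs.

## Pharmacokinetics

### Compartments and flows

Eleven compartments: arterial (1.5 L) and venous (3.5 L) blood pools, lung
(perfused in series by the full 5.6 L/min cardiac output), and brain,
liver, kidney, gut, muscle, fat, skin and a remainder compartment in
parallel. The gut's venous outflow enters the liver (portal inflow), so
hepatic clearance sees splanchnic blood; this is the smallest compartment
set that preserves the portal-clearance topology and a brain effect site.
Organ flow fractions and tissue composition (water/lipid/phospholipid
fractions, acidic-phospholipid content) are standard literature PBPK
values shipped as editable fixtures. Muscle receives 1.3 L/min, toward the
upper end of resting values, which gives the fast redistribution phase
that fentanyl's arterial concentration profile shows after a bolus.

### Partition coefficients

`K_TB` per (drug, tissue) follows the tissue-composition family of models:
ionisation factors X (intracellular) and Y (plasma) from the
Henderson–Hasselbalch terms for the drug's class; a neutral-lipid /
neutral-phospholipid term `(P·f_NL + (0.3P − 0.7)f_NP)/Y`; acidic
phospholipid binding for strong bases; a tissue-binding `K_bind` term for
acids/neutrals/weak bases; and an `f_u/γ_BP` prefactor rescaling from
plasma to whole blood. Fentanyl is treated as a strong base (pKa 8.4);
its effective logP is set to 3.2 — between the octanol and vegetable-oil
scales — because using the raw octanol value in the neutral-lipid term
inflates the adipose coefficient and pushes the whole-body distribution
volume far beyond the literature range; with 3.2 the model's V_ss is
~356 L (literature ≈ 300–400 L). The zwitterion branch implements the
printed expression literally, including the subtracted acidic-moiety term,
and is isolated in one function (`zwitterion_phospholipid_term`) so an
alternative grouping can be swapped at a single point; for parameter sets
where that term drives the sum negative the function raises a diagnostic
domain error rather than returning a nonphysical coefficient.

### Clearance

Hepatic clearance uses the well-stirred model on the total liver inflow
(hepatic artery + portal), per kg body weight, applied to the liver
vasculature (outflow) concentration each step and clamped so compartment
mass never goes negative. Renal clearance is the analogous expression on
the kidney outflow scaled by `f_u` (zero by default for both drugs: both
are predominantly hepatically cleared; fecal clearance is omitted).
Fentanyl's intrinsic clearance (0.149 L/min/kg) reproduces a hepatic
plasma clearance of ~0.8 L/min; naloxone's (0.5 L/min/kg) makes its
extraction near flow-limited, giving the fast elimination that underlies
re-narcotization risk.

## Nasal absorption

Six states: carrier-bound drug in anterior/posterior/GI compartments
(A, P, G) and released drug in the same spaces (a, p, g), with first-order
transfers `A→{P,a}`, `P→{G,p}`, `G→{g, elim}`, `a→{p, systemic, elim}`,
`p→{g, systemic, elim}`, `g→{systemic, elim}` and systemic input
`R = k₄a + k₈p + k₁₀g`. This is the unique mass-conserving reading of the
compartment scheme consistent with the lumped outflow constants
α…ε. Kinetics depend on deposited mass only; the 0.1 mL spray volume of
the branded 2 mg formulation is carried as metadata. Rate-constant
defaults were fitted (see Calibration) so that a single 2 mg spray peaks
in venous plasma at ~15 min (clinical Tmax 15–30 min) with ~71 % of the
dose reaching circulation, and — important for rescue dynamics — with most
early absorption flowing through the released-chain `a→p→systemic` route,
whose convex onset makes cumulative absorption from rapid repeat sprays
accelerate sharply in the minutes after dosing begins.

## Pharmacodynamics

Three effect channels for fentanyl, each a sigmoid Emax model on its
effect-site concentration with competitive shift `(1 + Ci/k_i)` from
naloxone's effect-site concentration (the antagonist raises apparent EC50
without lowering the ceiling — surmountable antagonism; naloxone has no
intrinsic channels):

| channel | E_b | Emax | EC50 (µg/L) | η | role |
|---|---|---|---|---|---|
| respiration_rate | 16 /min | 0.875 | 4.0 | 2.6 | lowers the driver's target frequency |
| driver_pressure | 13 cmH₂O | 0.5 | 4.0 | 1.6 | lowers the driver's target pressure |
| cns (ν) | 1 | 1.0 | 8.0 | 3.0 | attenuates chemoreceptor feedback |

`Emax = 0.875` on the frequency channel makes full receptor saturation
leave the rate at `16·(1 − 0.875) = 2` breaths/min, the configured
physiologic floor. The inhibition constant `k_i = 0.85 µg/L` is of the
order of naloxone's receptor affinity (~1 nM ≈ 0.33 µg/L) and is the main
potency knob of the reversal. Effect-site rate constants:
fentanyl `k_e = 0.005 s⁻¹` (τ ≈ 3.3 min), naloxone `0.008 s⁻¹` — fast
central equilibration for both, consistent with their clinical onset
times. Ci is the antagonist's effect-compartment (not plasma)
concentration, matching the effect-site framing of the interaction model.

## Chemoreflex

Central branch: `dΔE_c/dt = (−ΔE_c + g_c·C_f)/τ_c` with
`C_f = (P_CO₂ − 40)·e^(−3.5ν)`. Peripheral branch: carotid firing `f`
relaxes (τ_f = 5 s) toward
`ψ = S(P_O₂)·[K ln(P_CO₂/40) + γ]`, where `S` is a sigmoid spanning
f_min = 0.835 to f_max = 12.3 spikes/s around P_O₂ = 45 mmHg; the
attenuated afferent `A_f = ψ e^(−3.5ν) + f_set(1 − e^(−3.5ν))` replaces
raw firing as the effector input `g_p·(A_f − f_set)`, so full depression
(ν → 1) sends the peripheral drive to zero exactly as it zeroes the
central error. γ is solved at patient load so that ψ equals the firing
set point at the baseline gas tensions, making the undrugged set points an
exact closed-loop equilibrium. The driver targets are
`f_t = f_base + Δf_c + Δf_p − ΔE_RR` and likewise for pressure: direct
pharmacodynamic depression lowers the baseline drive while the (attenuated)
feedback fights it. Without the direct term, attenuation alone could never
push ventilation below baseline, contradicting the observed collapse to
2 breaths/min. Gains (g_c_f = 0.55 min⁻¹/mmHg, g_p_f = 0.2,
g_c_P = 0.25 cmH₂O/mmHg, g_p_P = 2.0) and time constants (τ_c = 105 s,
τ_p = 20 s) are in the range of the hypoxic-chemoreflex modelling
literature, then tuned to the anchors below. The peripheral pressure gain
is what raises tidal volume under partial depression — the model
reproduces this mechanism (deep slow breaths) even though clinically tidal
volume usually falls under opioids; see Limitations.

## Gas exchange and death (surrogate physiology)

Alveolar ventilation `V̇_A = max(0, V_T − 0.15 L)·RR` with
`V_T = 0.05 L/cmH₂O · (P_target − 3 cmH₂O)` bounded by a 3 L
vital-capacity limit; rate and volume track their targets with τ = 8 s.
Driver pressure is reported in cmH₂O and convertible to mmHg by 0.735559.
Lumped stores integrate the gas balances

    dP_CO₂/dt = (863·V̇CO₂ − V̇_A (P_CO₂ − P_ICO₂)) / V_store,CO₂
    dP_O₂/dt  = (V̇_A (P_IO₂ − AaG − P_O₂) − 863·V̇O₂,eff) / V_store,O₂

with V_store,CO₂ = 40 L (slow body CO₂ stores), V_store,O₂ = 10 L (lung
gas plus haemoglobin-buffered blood), a fixed 10 mmHg alveolar–arterial
gradient, and O₂ consumption scaled down once SpO₂ falls below 0.5
(supply-limited extraction). V̇CO₂ is solved at load so the CO₂ set point
is the exact resting equilibrium of the baseline driver (0.258 L/min for
the default patient — a normal value). SpO₂ is a Hill curve (n = 2.7,
P50 = 26.8 mmHg). Apnoea is handled as pure accumulation/decay — no
division by ventilation anywhere. The death criterion — SpO₂ below 0.40
continuously for 872 s — is an explicitly crude, tunable calibration knob
(see below), not a clinical claim; death freezes the simulation outputs.

## Calibration

The pharmacodynamic parameters, nasal rate constants and the death window
are not observable directly; they were set by iterating
`scripts/calibrate.py`, which evaluates all anchors for the current
defaults, and are frozen in `naloxsim.fixtures`. Anchors, in the order
they constrain the model:

1. **Resting respiration 16/min, P_CO₂ 40 mmHg, SpO₂ ≥ 0.96** — enforced
   structurally (exact equilibrium by construction), not fitted.
2. **Respiration floor 2/min at receptor saturation** — Emax on the
   frequency channel plus the configured floor.
3. **Nasal 2 mg plasma peak between 15 and 40 min** — nasal rate set.
4. **Unrescued survival boundary at 1.5 mg** — the duration of sustained
   SpO₂ < 0.40 grows smoothly with dose (970 s at 1.5 mg, 1025 s at
   1.6 mg at the batch step); the 872 s death window is placed between
   the corresponding durations measured against the 0.40 threshold,
   making 1.5 mg the largest surviving dose on the grid.
5. **Rescue-sweep envelope** — with the protocol active every dose is
   rescued, the maximum total (14 mg) stays within 8× the standard dose,
   and totals plateau above 1.2 mg. The plateau arises because above
   receptor saturation the SpO₂ trajectory is dose-insensitive and the
   reversal time is governed by the steeply accelerating cumulative
   absorption of the stacked repeat sprays, which compresses the spread
   of recovery times across 1.2–1.9 mg to under one 50 s check interval.
6. **CO₂-response slopes decrease monotonically with fentanyl level**,
   and adjacent-bin Welch tests on the sweep totals reach p < 0.05.

Anchor 5's dose counts are discrete (2 mg quanta at 50 s cadence), so they
are razor-sensitive to the interplay of absorption and recovery timing;
they are exactly reproducible at the batch step size (0.1 s, verified
unchanged at 0.05 s) but a future change to any PK/PD default requires
re-running the calibration script.

## Numerics

Fixed-step integration: explicit Euler for transport and gas stores (the
stiffest transport time constant, kidney, is ~16 s, two orders above the
batch step), and exact-exponential relaxation updates for every linear
first-order state (effect sites, firing, effector deltas, driver
tracking) — exact for inputs frozen over a step and unconditionally
stable, which is why they replace the two-evaluation Heun scheme that a
general-purpose engine would need for these states (a Heun variant of the
effect-site update is kept for convergence testing). Default dt = 0.02 s;
batch experiments (sweeps, challenge, acceptance) use 0.1 s, where halving
the step changes the continuous outputs by < 0.5 %. Transport updates are
algebraically conservative: total administered mass equals circulating +
tissue + cleared + nasal-in-transit + nasal-eliminated to relative 1e−6
on random dosing schedules (float rounding only). Negative masses (possible
only with steps far above the default) are clamped with a logged warning
and folded into the elimination ledger so the balance stays closed.
The CO₂-challenge slope is estimated by least squares of total ventilation
on EtCO₂ with a linear time regressor absorbing the operating-point drift
while each infusion step equilibrates; a drug-free conditioning window is
run first so every measured window sees the same carry-over from the
previous CO₂ exposure. Windows with zero EtCO₂ variance return an
undefined (None) slope with a warning.

## The protocol automaton

One IV fentanyl bolus at t = 0; first nasal naloxone dose after the 120 s
transit delay; thereafter SpO₂ is evaluated every 50 s (clock starts at the
first dose) and each evaluation below the 0.85 threshold administers one
more 2 mg dose — one dose per failed check, the only reading consistent
with repeat administration at the stated cadence. The patient is rescued
after 600 s of sustained SpO₂ at/above threshold; the clock resets on
every dip. A configurable safety cap terminates the run with a `capped`
flag. The automaton works against any object exposing the small
physiology interface (`step`, `spo2`, `rr`, `alive`, dosing methods), which
is how the hand-traceable scripted-SpO₂ tests exercise it independently of
the physiology. Totals always equal `dose × (1 + failed checks)`.
The simulation horizon is 3 h per dose, long enough to expose
re-narcotization (naloxone clears faster than fentanyl) if it occurs.
Bin statistics use three bins of six doses and two-sided Welch t-tests
between adjacent bins (the variance structure is unequal by construction);
zero-variance pairs degrade to an exact mean comparison with a warning.

## What the synthetic patient does and does not show

Everything here is a single 70 kg virtual patient with textbook tissue
composition and a surrogate gas-exchange layer. Passing tests show the
coupled mechanism is implemented correctly and that the calibrated system
reproduces the anchor behaviours; they do not validate the model against
human pharmacokinetic or outcome data, which requires externally digitized
concentration profiles (the CSV trace contract supports such comparisons).
Known, deliberate departures from clinical reality:

* tidal volume *rises* under partial opioid depression (peripheral
  pressure drive), where patients usually show decreased volumes;
* the death criterion tolerates long deep-hypoxaemia episodes (tens of
  minutes below SpO₂ 0.4) before declaring death, and survivors recover
  fully with no hypoxic injury;
* no ventilation, bag-valve-mask or supplemental-oxygen co-interventions;
  no chest-wall rigidity; no multi-receptor binding; no inter-patient
  variability — the dose–requirement curve is one patient's, not a
  population's;
* plasma pH and body temperature are constant; partition coefficients are
  computed once at load.
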