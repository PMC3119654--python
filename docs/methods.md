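# Methods

## Scope and model

`coccohv` packages the quantitative chain behind the physiology of the
voltage-gated H⁺ conductance in calcifying coccolithophores
(*Coccolithus pelagicus* ssp. *braarudii*): closed-form electrochemistry,
whole-cell voltage-clamp analysis, a coupled membrane-potential /
cytosolic-pH cell model, and single-cell imaging quantification, with
ground-truth synthetic data standing in for recordings (none are publicly
deposited).

### Electrochemistry (`iontheory`)

Equilibrium potentials use the Nernst relation
E = (2.303·RT/zF)·log₁₀(c_out/c_in); the decade slope is 58.17 mV at the
20 °C recording temperature. For H⁺ the package follows the field
convention E_H = s·(pH_i − pH_o) with the slope an **explicit caller
choice**: the −48 mV value quoted for seawater pH 8.0 over cytosol pH 7.2
requires the rounded 60 mV/decade slope, which is inconsistent with the
stated 20 °C — rather than resolve this silently, both `slope_mv` and
`temperature_c` entry points exist and the cell model carries
`nernst_slope_mv = 60.0` as a documented config field. ΔpH means
pH_o − pH_i everywhere.

The GHK voltage equation is restricted to monovalent ions (H⁺, Na⁺, K⁺
in the cation sense, Cl⁻ with sides swapped); divalents raise an error
because the monovalent voltage form does not treat them consistently.
Concentrations are used as activities — a documented limitation.
`min_selectivity_ratio` inverts the GHK equation by bisection on
log₁₀(P_H/P_x): the deviation of the two-ion reversal from E_H is
monotone in the ratio, so the smallest ratio keeping the reversal within a
stated tolerance of E_H is well defined. With the standard pipette/bath
pair (200 mM K⁺, pH 7.5 inside; 8 mM K⁺, pH 8.0 outside) a 10 mV
tolerance demands P_H/P_K ≈ 10⁷, comfortably above 10⁶.

Acid-load arithmetic: rate (pH min⁻¹) = J_H / (β·V_cyt) · 60. The
inputs (calcification flux, cytosolic volume, buffer capacity) are explicit
arguments because the published estimate prints only the resulting
~0.3 pH min⁻¹.

### Voltage-clamp analysis (`ephys`)

* **Leak subtraction** is resistive, referenced to the holding potential:
  I_leak = (V_cmd − V_hold)/R_seal, so holding-level current is untouched.
  Double subtraction is an error.
* **Steady-state I–V**: mean current over a window (default 40 ms, the
  10–50 ms convention) anchored to the *end* of the depolarising step —
  the published wording is ambiguous about placement; end-of-step matches
  "steady state" for a slowly activating current.
* **Tail reversal**: per test level, the tail peak is the signed extremum
  between a blanking delay (default 2 ms, skipping capacitance transients)
  and a search bound (default 20 ms) after the test-step onset; peaks were
  measured manually in the source work, so both are explicit parameters.
  E_rev is the x-intercept of one global OLS line of peak vs test voltage;
  its standard error is the inverse-prediction error at zero current.
  A non-positive slope flags the estimate unreliable. Note that with a
  finite deactivation time constant the open probability decays slightly
  during the blanking delay and varies with the test level's steady-state
  open fraction, which biases the intercept by a few tenths of a mV at the
  default blanking; the noiseless round-trip tests therefore either freeze
  the gate (ohmic tails) or allow a 2 mV tolerance.
* **Activation kinetics**: least-squares fit of
  I(t) = offset + A·(1 − e^(−(t−t₀)/τ)); flat traces are flagged
  (amplitude ≈ 0 makes τ unidentifiable) rather than fitted.
* **QC**: recordings fail when series resistance varies by more than 15%
  ((max − min)/first reading).

Sign conventions: outward positive current, membrane potentials in mV,
t = 0 at sweep start, all windows half-open [start, end).

### Cell model (`model`, `scenarios`)

State: membrane potential V (clamped or free-running), gate p of the H⁺
channel, cytosolic pH, and cumulative per-pathway H⁺ tallies.

* Gated H⁺ channel: Boltzmann steady state
  p∞ = 1/(1 + e^(−(V − (E_H + δ))/k)) with midpoint tracking E_H
  (offset δ), first-order relaxation with τ_act/τ_deact (native 220 ms;
  heterologous presets 107 and 22.9 ms). Open-channel current is ohmic in
  (V − E_H); a GHK-flux variant is a config switch, default off, because no
  open-channel rectification is reported. Zn²⁺ block scales the gated
  branch by (1 − block); presets: 0.84 for the heterologous wild type,
  0.27/0.28 for the S1–S2 loop histidine mutants H197A/H203A, and 0.97
  (calibrated, near-complete) for the native conductance at 30 µM free
  Zn²⁺.
* Background H⁺ pathway: a small **GHK (constant-field) permeability**.
  This deviates deliberately from an ohmic background: a single default
  parameterisation must make low external pH depolarise the cell
  (−29.0 mV at pH_o 6.5) and acidify it at rest, while hyperpolarising
  pulses at pH_o 8.0 stay pH-neutral (|ΔpH| < 0.005 in 10 s). An ohmic
  background large enough for the first violates the second ~10-fold; the
  GHK form passes ~12× more inward current at pH_o 6.5 than at 8.0 for
  comparable driving forces (30× higher [H⁺]_o), and satisfies both.
* Inward Cl⁻ rectifier: s∞ = 1/(1 + e^((V − V_half)/k)) — activated by
  hyperpolarisation — times g·(V − E_Cl). It stabilises the resting
  potential and carries no acid.
* pH dynamics: d(pH_i)/dt = I_H/(F·β·V_cyt) − J_calc/(β·V_cyt)
  + k_sec·(pH_set − pH_i), outward current alkalinising. Secondary
  regulation (uncharacterised slower transporters) is first-order with
  k_sec = 0.02 s⁻¹, the minimal form consistent with the observed
  30–60 s exponential recovery after depolarising pulses.
* Events: set_pH_o, Zn²⁺ on/off (also scales the Cl⁻ conductance by its
  Zn sensitivity), Gd³⁺ (zeroes the gated channel), Ca²⁺-free (zeroes
  J_calc), NH₄Cl pulse (phenomenological square-pulse acid load; explicit
  NH₃/NH₄⁺ permeation is out of scope), and voltage steps.

**Integration** is fixed-step classical RK4 with step
min(τ_act, τ_deact, C_m/g_total)/20 (seconds), deterministic and
bit-stable; the budget tallies are integrated inside the same RK4 pass, so
β·V_cyt·ΔpH equals the summed pathway terms to round-off and
`proton_budget` audits the integrator (residual < 10⁻⁵ required,
~10⁻¹² observed). Non-finite state aborts with an integration error.
Free runs start from the coupled (V, pH) fixed point found by nested
root-finding (brentq on dpH/dt over the zero-current potential).
`resting_potential` brackets every sign change of the steady-state I(V) on
a grid over [−120, +80] mV, refines with brentq, and returns the most
negative stable root (positive local slope conductance), reporting all
roots.

### Parameter choices and calibration

Fixed by assumption (documented plausible protoplast values): C_m 3 pF,
V_cyt 10⁻¹³ L, β 10 mmol L⁻¹ pH⁻¹. The calcification flux
J_calc = 5×10⁻¹⁸ mol H⁺ s⁻¹ makes the unbuffered acid load
0.3 pH min⁻¹, matching the published estimate. The remaining free
parameters (g_max, δ, k, g_leak, the common resting reversal of leak and
Cl⁻ pathways, the background permeability, the Cl⁻ conductance, and the
calcifying set-point pH_set) were calibrated **once**, jointly, by damped
least squares (`scripts/calibrate_defaults.py`) against the measured
anchors: resting V_m −45.7 mV (pH_o 8.0) and −29.0 mV (pH_o 6.5);
clamp-step ΔpH_i +0.22 (+20 mV) and +0.36 (+70 mV) over 10 s;
Zn²⁺-induced acidification −0.13 pH in calcifying cells and ≈ −0.02 in
Ca²⁺-free cells; hyperpolarisation pH-neutrality. The frozen values live
in `coccohv.scenarios`.

Design notes on the calibrated solution:

* The anchor set pins the channel density near 0.04 nS: the clamp-step pH
  excursions, with β·V_cyt = 10⁻¹⁵ mol pH⁻¹, admit only a small open
  conductance. This is the *pH-coupled effective* conductance of the model
  cell, not the multi-nS whole-cell conductance seen in recordings — real
  cells buffer far more H⁺ (organelles, mobile buffers) than the single
  cytosolic compartment modelled here. The synthetic-trace generator
  (`synth`) therefore uses whole-cell-scale conductances (0.5–5 nS)
  independently of the cell model's calibrated density.
* `native_config()` represents the patch-clamp context (decalcified
  protoplast, dialysed cytosol): J_calc = 0, pH_set = pH_i = 7.2.
  `calcifying_config()` adds the acid load and a lower set-point
  (pH_set ≈ 7.09, calibrated to the Zn²⁺ response); under sustained load
  the model cell rests near pH_i 6.99, slightly acid of the nominal 7.2 —
  an accepted compromise forced by requiring the channel to carry most of
  the calcification load at rest (otherwise blocking it could not acidify
  the cell by 0.13 pH).
* Sensitivity: the calibration is stiff — perturbing g_max by 50% breaks
  the +70 mV clamp anchor and/or the resting potential (tested). δ and k
  trade off against g_max within roughly ±2 mV and ±1 mV respectively
  before the resting anchors fail.

### Imaging (`imaging`)

Two-point BCECF calibration is linear in ratio between pH 6.5 and 7.5
(the published in-vitro curve closely matched the two-point ΔpH over this
range); ratios beyond 20% of the anchor span are flagged extrapolated.
Background subtraction is off by default. Event ΔpH windows default to
60 s pre / 60 s post because the source means are reported without window
definitions; for ester-loaded cells only ΔpH is reported. Calcification
rates are per-window OLS slopes of cross-polarised intensity (windows
0–150 / 150–300 / 300–600 min), normalised to the first window; percent
inhibition is 100·(1 − normalised treatment-window rate), with the
treatment window defaulting to the second period.

### Synthetic data (`synth`)

Generators draw from a per-call `numpy.random.default_rng(seed)`; no
global state, and identical (seed, parameters) reproduce outputs
bit-for-bit (the truth manifest records both). Voltage-clamp traces use the
exact piecewise-exponential gate solution under a piecewise-constant
command with pipette-buffered (fixed) E_rev; leak is ohmic via R_seal;
capacitance transients are decaying exponentials at step edges (charge
C·ΔV, τ 0.5 ms, default on) so blanking is genuinely exercised. Noise:
additive Gaussian for currents and intensity, multiplicative Gaussian for
fluorescence — the simplest forms consistent with each signal. The
birefringence scenarios encode treatment-window slope ratios 0.31 (low
external pH) and 0.33 (NH₄Cl) with a 60 min restoration lag and partial
(0.8×) third-window recovery.

What the generators do **not** emulate: photobleaching, focus drift, cell
movement, series-resistance voltage errors, imperfect pipette pH buffering
(the sub-Nernstian −43 mV/pH native slope is kept as a fixture
expectation, not a generated mechanism), open-channel rectification, and
stochastic single-channel gating. Passing closed-loop tests therefore
demonstrates correctness of the analysis chain under these idealisations,
not robustness to every artefact of real recordings.

### Problem sizes

The shipped test and acceptance runs use: 10 s clamp steps at the default
RK4 step (~11 ms for native kinetics); free-running scenario runs of
180–900 s at a 2–5 ms step cap for the slower tests; closed-loop recovery
on a 3-point (g, E_rev, τ) grid with SNR 20; 100 seeded replicates for the
imaging bias check. These sizes keep the full suite in a few minutes while
leaving every tolerance comfortably resolved.

## Known limitations

* Single well-mixed cytosolic compartment; no coccolith-vacuole or
  chloroplast pH, no carbonate-system speciation, no Ca²⁺ handling.
* Activities = concentrations; liquid-junction corrections out of scope.
* The gating midpoint offset δ and slope k are calibrated, not measured —
  the source reports only that activation sits positive of E_H.
* Zn²⁺-induced acidification is attributed entirely to channel block plus
  ongoing calcification; contributions from other Zn²⁺-sensitive pathways
  are not modelled.
* The −43 mV/pH native reversal slope and the −0.13 Zn²⁺ ΔpH are treated
  as fixture expectations / calibration context, not independent
  reproductions.
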