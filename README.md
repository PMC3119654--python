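# coccohv

Voltage-gated H⁺ channel physiology in calcifying coccolithophores.

Coccolithophores such as *Coccolithus pelagicus* build their calcite scales
(coccoliths) inside the cell, and every mole of calcite precipitated from
bicarbonate releases a mole of H⁺ into the cytosol — enough, unbuffered and
unremoved, to acidify the cell by ~0.3 pH min⁻¹. A plasma-membrane
voltage-gated H⁺ conductance (an Hv1 homologue) provides the fast efflux
path: it is exquisitely H⁺-selective, opens at voltages positive of the H⁺
equilibrium potential E_H = s·(pH_i − pH_o), and therefore passes only
outward (alkalinising) current whose activation tracks the transmembrane pH
gradient.

`coccohv` is a Python toolkit for the quantitative work behind that
physiology, aimed at membrane biophysicists and phytoplankton
physiologists:

* **`iontheory`** — Nernst and Goldman–Hodgkin–Katz (GHK) arithmetic,
  inverse selectivity bounds (how big must P_H/P_K be for the observed
  reversal potential), and calcification acid-load estimates; packaged
  pipette/bath solution compositions.
* **`ephys`** — whole-cell voltage-clamp analysis: resistive leak
  subtraction, steady-state I–V extraction, tail-current reversal-potential
  regression, single-exponential activation fits
  I(t) = I₀ + A·(1 − e^(−t/τ)), E_rev-vs-ΔpH slope regression, and
  series-resistance QC.
* **`model`/`scenarios`** — a deterministic ODE model of the cell:
  Boltzmann-gated H⁺ channel with midpoint E_H + δ, hyperpolarisation-
  activated inward Cl⁻ rectifier, leak, a small constant-field background
  H⁺ permeability, buffered cytosolic pH with calcification acid load and
  first-order secondary regulation; voltage-clamp and free-running modes
  with named experiment scenarios (Zn²⁺/Gd³⁺ block, pH_o shifts, NH₄Cl
  pulse, Ca²⁺-free, heterologous and mutant presets) and a conservation
  audit of the proton budget.
* **`imaging`** — BCECF ratiometric pH quantification (two-point
  calibration at pH_i 7.5/6.5) and calcification rates from cross-polarised
  birefringence intensity (windowed regression, percent inhibition).
* **`synth`** — ground-truth generators for all four data kinds, with
  bit-reproducible truth manifests, so every analysis is testable without
  recorded data.

See `docs/methods.md` for the model equations, parameter provenance,
numerical choices and limitations.

## Worked example

```python
import coccohv as c

# 1. Electrochemistry: E_H at seawater pH over a resting cytosol
e_h = c.ph_equilibrium_potential(8.0, 7.2, slope_mv=60.0)
print(f"E_H = {e_h.value_mv:.1f} mV")

# 2. How H+-selective must the conductance be, given the recording solutions?
sols = c.load_solutions()
ratio = c.min_selectivity_ratio(sols["P1a"], sols["E1"], "K", tolerance_mv=10.0)
print(f"min P_H/P_K = {ratio:.2e}")

# 3. Closed loop: synthesize a tail-current family and recover its reversal
truth = c.native_channel_truth(g_max_ns=2.0)
family, manifest = c.gen_tail_family(truth, e_rev_mv=-29.1,
                                     noise_sigma_pa=2.0, seed=1, r_seal_gohm=2.0)
est = c.tail_reversal(c.leak_subtract(family), blank_ms=5.0)
print(f"E_rev = {est.e_rev_mv:.1f} mV (true {manifest.truth['e_rev_mv']})")

# 4. Cell model: a 10 s depolarisation to +70 mV alkalinises the cytosol
res, dph = c.clamp_step(c.native_config(), 70.0, duration_s=10.0)
print(f"clamp +70 mV: dpH_i = {dph:+.3f}")
print(f"resting V_m = {c.resting_potential(c.native_config()).v_rest_mv:.1f} mV")
```

prints

```
E_H = -48.0 mV
min P_H/P_K = 1.06e+07
E_rev = -29.4 mV (true -29.1)
clamp +70 mV: dpH_i = +0.374
resting V_m = -45.7 mV
```

— the H⁺ conductance sits just 2 mV below its reversal at rest, so any
depolarisation or cytosolic acid load immediately drives H⁺ out; a
selectivity ratio above 10⁷ is needed to keep the simulated reversal within
10 mV of E_H, matching the extreme selectivity reported for Hv1-family
channels.

There is also a CLI:

```bash
coccohv synth birefringence --scenario ph6.5 --out demo/
coccohv imaging calcification --in demo/birefringence.csv --out demo/rates.csv
coccohv simulate --scenario zn_block --out demo/zn.csv
```

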