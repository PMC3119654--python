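"""One-off joint calibration of the default cell-model parameters.

Tunes the free parameters of the native configuration (channel density,
gating offset/slope, leak and Cl-rectifier conductances, common reversal of
the resting pathways, background H+ permeability, calcifying set-point)
against the measured anchors:

* resting potential −45.7 mV at pH_o 8.0 and −29.0 mV at pH_o 6.5;
* clamp-step alkalinisation +0.36 / +0.22 pH for 10 s steps to +70 / +20 mV;
* Zn2+-induced acidification −0.13 pH in calcifying cells and ≈ −0.02 in
  Ca2+-free (non-calcifying) cells (secondary-regulation rate fixed at
  0.02 s⁻¹, i.e. ~50 s recovery, which widens the calcifying/Ca-free
  contrast);
* pH neutrality of hyperpolarisation to −110 mV (target 0, tight weight).

Run from the repository root: ``python scripts/calibrate_defaults.py``.
The resulting numbers are frozen by hand into `coccohv.scenarios`. Geometry
(c_m, V_cyt, beta), kinetics (tau 220 ms), the calcification flux
(0.3 pH min^-1 unbuffered) and k_sec (0.025 s^-1) stay fixed.
"""

from dataclasses import replace

import numpy as np
from scipy.optimize import least_squares

from coccohv.model import (CellConfig, ClChannelParams, Event, HvChannelParams,
                           Scenario, clamp_step, resting_potential,
                           simulate_free_running)
from coccohv.model import NATIVE_ZN_BLOCK

DT_COARSE = 5e-3  # s; calibration-only integrator cap (verified at default step afterwards)


def build_configs(x):
    g_max, delta, k, g_leak, e_rest, log_bg, ph_set_calc, g_cl = x
    hv = HvChannelParams(g_max_ns=g_max, v_half_offset_mv=delta, slope_k_mv=k,
                         background_permeability=10.0 ** log_bg)
    cl = ClChannelParams(g_max_ns=g_cl, e_cl_mv=e_rest, v_half_mv=-60.0, slope_k_mv=10.0)
    native = CellConfig(hv=hv, cl=cl, c_m_pf=3.0, v_cyt_l=1e-13, beta_mol_per_l_ph=0.010,
                        j_calc_mol_s=0.0, k_sec_per_s=0.020, ph_set=7.2,
                        g_leak_ns=g_leak, e_leak_mv=e_rest,
                        ph_o=8.0, ph_i=7.2, nernst_slope_mv=60.0)
    calcifying = replace(native, j_calc_mol_s=5e-18, ph_set=ph_set_calc)
    return native, calcifying


def zn_delta_ph(config):
    sc = Scenario("cal_zn", config,
                  events=(Event(30.0, "zn_on", {"block_fraction": NATIVE_ZN_BLOCK}),),
                  duration_s=180.0)
    res = simulate_free_running(config, sc, dt_max_s=DT_COARSE)
    return res.ph_at(180.0) - res.ph_at(30.0)


def residuals(x):
    native, calcifying = build_configs(x)
    v8 = resting_potential(native).v_rest_mv
    v65 = resting_potential(native, ph_o=6.5).v_rest_mv
    _, d70 = clamp_step(native, 70.0)
    _, d20 = clamp_step(native, 20.0)
    _, dhyp = clamp_step(native, -110.0)
    dzn = zn_delta_ph(calcifying)
    dznca = zn_delta_ph(replace(calcifying, j_calc_mol_s=0.0))
    r = [
        (v8 + 45.7) / 0.3,
        (v65 + 29.0) / 0.5,
        (d70 - 0.36) / 0.008,
        (d20 - 0.22) / 0.008,
        (dzn + 0.13) / 0.01,
        (dznca + 0.02) / 0.012,
        dhyp / 0.002,
    ]
    print("x=", np.round(x, 5), "anchors:", round(v8, 2), round(v65, 2), round(d70, 3),
          round(d20, 3), round(dzn, 3), round(dznca, 3), round(dhyp, 4))
    return r


def main():
    x0 = np.array([0.0377, 7.9, 3.8, 0.0112, -45.36, np.log10(2.66e4), 7.09, 0.214])
    lo = [0.005, 0.0, 3.0, 0.002, -55.0, 3.0, 6.9, 0.01]
    hi = [0.2, 20.0, 12.0, 0.1, -40.0, 5.5, 7.19, 0.5]
    fit = least_squares(residuals, x0, bounds=(lo, hi), diff_step=0.02,
                        ftol=1e-4, xtol=1e-8, max_nfev=150)
    print("\nfinal cost", fit.cost)
    names = ["g_max_ns", "v_half_offset_mv", "slope_k_mv", "g_leak_ns", "e_rest_mv",
             "log10_bg", "ph_set_calc", "g_cl_ns"]
    for n, v in zip(names, fit.x):
        print(f"{n:>18s} = {v:.6g}")
    print("background_permeability =", 10.0 ** fit.x[5])


if __name__ == "__main__":
    main()
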