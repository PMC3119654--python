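"""Default cell configurations and the registry of named experiment scenarios.

`native_config()` is the package's reference C. pelagicus protoplast under
seawater pH 8.0 with pipette-style cytosol at pH 7.2. Its free parameters
(channel density, gating offset and slope, rectifier and leak conductances,
background H+ permeability, regulation set-point) were calibrated jointly,
once, against four measured anchors — resting potential −45.7 mV at pH_o 8.0
and −29.0 mV at pH_o 6.5, and clamp-step alkalinisations of +0.22 / +0.36 pH
for 10 s steps to +20 / +70 mV — by damped least squares
(scripts/calibrate_defaults.py) and frozen here. `calcifying_config()` adds
the calcification acid load (0.3 pH min⁻¹ unbuffered equivalent) and the
set-point shift calibrated to the Zn2+-induced acidification of −0.13 pH.

The scenario registry encodes the manipulations of the source experiments
(Zn2+ and Gd3+ block, external acidification, NH4Cl pulse, Ca2+-free medium,
heterologous and mutant channel presets) as config deltas plus timed events.
"""

from __future__ import annotations

from dataclasses import replace

from .model import (CPHV1_TAU_ACT_MS, EHHV1_TAU_ACT_MS, NATIVE_TAU_ACT_MS,
                    NATIVE_ZN_BLOCK, ZN_BLOCK_PRESETS, CellConfig,
                    ClChannelParams, Event, HvChannelParams, Scenario)

# Calibrated defaults (see module docstring); geometry c_m 3 pF, V_cyt 1e-13 L,
# beta 10 mmol L^-1 pH^-1 are assumed plausible protoplast values.
_NATIVE_HV = dict(
    g_max_ns=0.0377,
    v_half_offset_mv=7.9,
    slope_k_mv=3.8,
    tau_act_ms=NATIVE_TAU_ACT_MS,
    tau_deact_ms=NATIVE_TAU_ACT_MS,
    background_permeability=2.66e4,
)
_NATIVE_CL = dict(g_max_ns=0.214, e_cl_mv=-45.36, v_half_mv=-60.0, slope_k_mv=10.0,
                  zn_sensitivity=0.0)
_NATIVE_CELL = dict(
    c_m_pf=3.0, v_cyt_l=1e-13, beta_mol_per_l_ph=0.010,
    j_calc_mol_s=0.0, k_sec_per_s=0.020, ph_set=7.2,
    g_leak_ns=0.0112, e_leak_mv=-45.36,
    ph_o=8.0, ph_i=7.2, temperature_c=20.0, nernst_slope_mv=60.0,
)

#: calcification H+ flux giving a 0.3 pH min^-1 unbuffered acid load for the default geometry
CALCIFICATION_FLUX_MOL_S = 5e-18
#: regulation set-point under sustained calcification load (calibrated to the Zn2+ response)
CALCIFYING_PH_SET = 7.09
#: square-pulse acid load standing in for a 10 mM NH4Cl washout-phase acidification
NH4CL_ACID_LOAD_MOL_S = 7.5e-18


def native_config(**overrides) -> CellConfig:
    """Reference non-calcifying protoplast (patch-clamp context)."""
    hv = HvChannelParams(**_NATIVE_HV)
    cl = ClChannelParams(**_NATIVE_CL)
    cfg = CellConfig(hv=hv, cl=cl, **_NATIVE_CELL)
    return replace(cfg, **overrides) if overrides else cfg


def calcifying_config(**overrides) -> CellConfig:
    """Actively calcifying cell: native parameters plus the calcification acid load."""
    cfg = native_config(j_calc_mol_s=CALCIFICATION_FLUX_MOL_S, ph_set=CALCIFYING_PH_SET)
    return replace(cfg, **overrides) if overrides else cfg


def hek_config(tau_act_ms: float = EHHV1_TAU_ACT_MS, **overrides) -> CellConfig:
    """Heterologous (HEK293) expression context: faster kinetics, NMDG solutions
    (pH_i 7.0 / pH_o 7.8), larger cell, no calcification or Cl- rectifier."""
    hv = HvChannelParams(g_max_ns=1.0, v_half_offset_mv=5.0, slope_k_mv=6.0,
                         tau_act_ms=tau_act_ms, tau_deact_ms=tau_act_ms,
                         background_permeability=0.0)
    cl = ClChannelParams(g_max_ns=0.0)
    cfg = CellConfig(hv=hv, cl=cl, c_m_pf=15.0, v_cyt_l=1.5e-12,
                     beta_mol_per_l_ph=0.02, j_calc_mol_s=0.0, k_sec_per_s=0.02,
                     ph_set=7.0, g_leak_ns=0.2, e_leak_mv=-20.0,
                     ph_o=7.8, ph_i=7.0, temperature_c=20.0, nernst_slope_mv=60.0)
    return replace(cfg, **overrides) if overrides else cfg


def _scenarios() -> dict:
    reg = {}

    reg["native_default"] = lambda: Scenario("native_default", native_config(),
                                             duration_s=120.0)
    reg["calcifying_default"] = lambda: Scenario("calcifying_default", calcifying_config(),
                                                 duration_s=240.0)
    reg["zn_block"] = lambda: Scenario(
        "zn_block", calcifying_config(),
        events=(Event(30.0, "zn_on", {"block_fraction": NATIVE_ZN_BLOCK}),
                Event(180.0, "zn_off")),
        duration_s=240.0)
    reg["zn_block_ca_free"] = lambda: Scenario(
        "zn_block_ca_free", calcifying_config(j_calc_mol_s=0.0),
        events=(Event(30.0, "zn_on", {"block_fraction": NATIVE_ZN_BLOCK}),
                Event(180.0, "zn_off")),
        duration_s=240.0)
    reg["gd_block"] = lambda: Scenario(
        "gd_block", calcifying_config(),
        events=(Event(30.0, "gd_on"),), duration_s=180.0)
    reg["ph_o_6.5"] = lambda: Scenario(
        "ph_o_6.5", native_config(),
        events=(Event(60.0, "set_ph_o", {"ph_o": 6.5}),
                Event(360.0, "set_ph_o", {"ph_o": 8.0})),
        duration_s=600.0)
    reg["nh4cl_pulse"] = lambda: Scenario(
        "nh4cl_pulse", calcifying_config(),
        events=(Event(60.0, "nh4cl_pulse",
                      {"duration_s": 600.0, "acid_load_mol_s": NH4CL_ACID_LOAD_MOL_S}),),
        duration_s=900.0)
    reg["ca_free"] = lambda: Scenario("ca_free", calcifying_config(j_calc_mol_s=0.0),
                                      duration_s=240.0)
    reg["hek_ehhv1"] = lambda: Scenario("hek_ehhv1", hek_config(EHHV1_TAU_ACT_MS),
                                        duration_s=60.0)
    reg["hek_cphv1"] = lambda: Scenario("hek_cphv1", hek_config(CPHV1_TAU_ACT_MS),
                                        duration_s=60.0)
    reg["mutant_H197A"] = lambda: Scenario(
        "mutant_H197A", hek_config(EHHV1_TAU_ACT_MS),
        events=(Event(30.0, "zn_on", {"block_fraction": ZN_BLOCK_PRESETS["H197A"]}),),
        duration_s=60.0)
    reg["mutant_H203A"] = lambda: Scenario(
        "mutant_H203A", hek_config(EHHV1_TAU_ACT_MS),
        events=(Event(30.0, "zn_on", {"block_fraction": ZN_BLOCK_PRESETS["H203A"]}),),
        duration_s=60.0)
    reg["wild_type_hek_zn"] = lambda: Scenario(
        "wild_type_hek_zn", hek_config(EHHV1_TAU_ACT_MS),
        events=(Event(30.0, "zn_on", {"block_fraction": ZN_BLOCK_PRESETS["wild_type_hek"]}),),
        duration_s=60.0)
    return reg


SCENARIO_NAMES = tuple(sorted(_scenarios().keys()))


def get_scenario(name: str) -> Scenario:
    reg = _scenarios()
    if name not in reg:
        raise KeyError(f"unknown scenario {name!r}; known: {', '.join(SCENARIO_NAMES)}")
    return reg[name]()
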