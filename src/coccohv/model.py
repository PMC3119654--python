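"""Coupled membrane-potential / cytosolic-pH model of a calcifying coccolithophore cell.

The model couples four elements on the plasma membrane of a C. pelagicus-like
cell:

* a voltage-gated H+ conductance whose activation midpoint tracks the H+
  equilibrium potential E_H (V_half = E_H + δ), opening at voltages positive
  of E_H and passing outward (alkalinising) H+ current;
* a hyperpolarisation-activated inward Cl- rectifier that stabilises the
  resting potential;
* an ohmic leak;
* a small background H+ permeability in the constant-field (GHK) form, which
  carries inward acid load when external pH is low and is negligible at
  seawater pH — this is what couples pH_o to pH_i when the gated channel is
  shut.

Cytosolic pH obeys a buffered proton budget: outward H+ current raises pH_i,
the calcification flux j_calc (1 mol H+ per mol calcite from bicarbonate)
lowers it, and slower uncharacterised transporters relax pH_i toward a
set-point with first-order rate k_sec. Membrane potential is either clamped
(ideal voltage clamp) or free-running with C_m dV/dt = −ΣI.

Integration is fixed-step classical Runge-Kutta; the per-pathway cumulative
H+ tallies are integrated alongside the state, so the proton budget closes
to round-off by construction and `proton_budget` audits the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .constants import MOL_PER_SECOND_PER_PA, thermal_voltage_mv

#: activation time constants (ms) measured at +50 mV for the three channel contexts
NATIVE_TAU_ACT_MS = 220.0
EHHV1_TAU_ACT_MS = 107.0
CPHV1_TAU_ACT_MS = 22.9

#: Zn2+ block fractions: heterologous wild-type vs the two S1-S2 loop histidine mutants
ZN_BLOCK_PRESETS = {"wild_type_hek": 0.84, "H197A": 0.27, "H203A": 0.28}
#: near-complete block of the native conductance by 30 uM free Zn2+ (calibrated)
NATIVE_ZN_BLOCK = 0.97


@dataclass(frozen=True)
class HvChannelParams:
    """Voltage-gated H+ channel. V_half = E_H + v_half_offset_mv.

    ``zn_block_fraction`` is the *currently applied* block (0 = no Zn2+);
    scenario events set it to a preset. ``background_permeability`` scales
    the GHK-form background H+ pathway (pA per mV per mol/L).
    """

    g_max_ns: float
    v_half_offset_mv: float = 5.0
    slope_k_mv: float = 6.0
    tau_act_ms: float = NATIVE_TAU_ACT_MS
    tau_deact_ms: float = NATIVE_TAU_ACT_MS
    zn_block_fraction: float = 0.0
    background_permeability: float = 0.0
    use_ghk_flux: bool = False
    ghk_permeability: float = 0.0  # gated-channel GHK scale, used only if use_ghk_flux

    def __post_init__(self):
        if self.g_max_ns < 0 or self.slope_k_mv <= 0:
            raise ValueError("g_max >= 0 and slope_k > 0 required")
        if self.tau_act_ms <= 0 or self.tau_deact_ms <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.zn_block_fraction <= 1.0:
            raise ValueError("zn_block_fraction in [0, 1]")


@dataclass(frozen=True)
class ClChannelParams:
    """Hyperpolarisation-activated inward Cl- rectifier (s_inf grows as v falls)."""

    g_max_ns: float
    e_cl_mv: float = -46.0
    v_half_mv: float = -60.0
    slope_k_mv: float = 10.0
    zn_sensitivity: float = 0.0  # fraction of g_max removed while Zn2+ is applied

    def __post_init__(self):
        if self.g_max_ns < 0 or self.slope_k_mv <= 0:
            raise ValueError("g_max >= 0 and slope_k > 0 required")


@dataclass(frozen=True)
class CellConfig:
    """Whole-cell parameters; defaults come from `native_config()`."""

    hv: HvChannelParams
    cl: ClChannelParams
    c_m_pf: float = 3.0
    v_cyt_l: float = 1e-13
    beta_mol_per_l_ph: float = 0.010
    j_calc_mol_s: float = 0.0
    k_sec_per_s: float = 0.025
    ph_set: float = 7.2
    g_leak_ns: float = 0.02
    e_leak_mv: float = -46.0
    ph_o: float = 8.0
    ph_i: float = 7.2
    temperature_c: float = 20.0
    nernst_slope_mv: float = 60.0  # rounded decade slope; E_H(8.0, 7.2) = −48 mV

    def __post_init__(self):
        if self.c_m_pf <= 0 or self.v_cyt_l <= 0 or self.beta_mol_per_l_ph <= 0:
            raise ValueError("c_m, v_cyt and beta must be positive")
        if self.k_sec_per_s < 0 or self.j_calc_mol_s < 0:
            raise ValueError("k_sec and j_calc must be non-negative")

    def e_h_mv(self, ph_i: float | None = None, ph_o: float | None = None) -> float:
        """H+ equilibrium potential with the config's decade slope."""
        ph_i = self.ph_i if ph_i is None else ph_i
        ph_o = self.ph_o if ph_o is None else ph_o
        return self.nernst_slope_mv * (ph_i - ph_o)

    @property
    def buffer_mol_per_ph(self) -> float:
        return self.beta_mol_per_l_ph * self.v_cyt_l


# ---------------------------------------------------------------------------
# membrane currents


def hv_steady_open(v_mv: float, e_h_mv: float, params: HvChannelParams) -> float:
    """Steady-state open probability: Boltzmann with midpoint E_H + δ.

    Strictly increasing in v; shifts one-to-one with E_H, so lowering pH_o
    (E_H more positive) moves activation to more positive voltages.
    """
    x = -(v_mv - (e_h_mv + params.v_half_offset_mv)) / params.slope_k_mv
    if x > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def _ghk_h_factor(v_mv: float, ph_i: float, ph_o: float, temperature_c: float) -> float:
    """Constant-field factor v·([H]_i − [H]_o e^{−v/Vt})/(1 − e^{−v/Vt}), H in mol/L."""
    h_i = 10.0 ** (-ph_i)
    h_o = 10.0 ** (-ph_o)
    vt = thermal_voltage_mv(temperature_c)
    u = v_mv / vt
    if abs(u) < 1e-9:
        return vt * (h_i - h_o)
    eu = math.exp(-u)
    return v_mv * (h_i - h_o * eu) / (1.0 - eu)


def hv_background_current(v_mv: float, ph_i: float, ph_o: float,
                          params: HvChannelParams, temperature_c: float = 20.0) -> float:
    """Ungated background H+ current (pA), GHK form, outward positive.

    Strongly inward-rectifying with [H+]_o: ~30x larger inward current at
    pH_o 6.5 than at 8.0 for the same driving force, which lets a single
    permeability both depolarise/acidify the cell at low pH_o and stay
    pH-neutral during hyperpolarisations at seawater pH.
    """
    if params.background_permeability == 0.0:
        return 0.0
    return params.background_permeability * _ghk_h_factor(v_mv, ph_i, ph_o, temperature_c)


def hv_current(v_mv: float, p_open: float, e_h_mv: float, params: HvChannelParams,
               ph_i: float | None = None, ph_o: float | None = None,
               temperature_c: float = 20.0) -> float:
    """Total H+ current (pA, outward positive): gated channel plus background.

    The gated branch is ohmic in (v − E_H) by default, or constant-field when
    ``use_ghk_flux`` is set. Zn2+ block scales only the gated branch. The
    background branch needs pH on both sides; omit them (None) only when
    ``background_permeability`` is zero.
    """
    if not 0.0 <= p_open <= 1.0:
        raise ValueError("p_open must lie in [0, 1]")
    avail = (1.0 - params.zn_block_fraction) * p_open
    if params.use_ghk_flux:
        if ph_i is None or ph_o is None:
            raise ValueError("GHK flux form needs ph_i and ph_o")
        gated = avail * params.ghk_permeability * _ghk_h_factor(v_mv, ph_i, ph_o, temperature_c)
    else:
        gated = avail * params.g_max_ns * (v_mv - e_h_mv)
    if params.background_permeability != 0.0:
        if ph_i is None or ph_o is None:
            raise ValueError("background term needs ph_i and ph_o")
        gated += hv_background_current(v_mv, ph_i, ph_o, params, temperature_c)
    return gated


def cl_current(v_mv: float, params: ClChannelParams) -> float:
    """Inward Cl- rectifier current (pA): I = g·s_inf(v)·(v − E_Cl), s_inf falling with v."""
    x = (v_mv - params.v_half_mv) / params.slope_k_mv
    s_inf = 0.0 if x > 700.0 else 1.0 / (1.0 + math.exp(x))
    return params.g_max_ns * s_inf * (v_mv - params.e_cl_mv)


def leak_current(v_mv: float, config: CellConfig) -> float:
    return config.g_leak_ns * (v_mv - config.e_leak_mv)


def total_steady_current(v_mv: float, config: CellConfig,
                         ph_i: float | None = None, ph_o: float | None = None) -> float:
    """Net membrane current (pA) with both gates at their steady state."""
    ph_i = config.ph_i if ph_i is None else ph_i
    ph_o = config.ph_o if ph_o is None else ph_o
    e_h = config.e_h_mv(ph_i, ph_o)
    p = hv_steady_open(v_mv, e_h, config.hv)
    i_h = hv_current(v_mv, p, e_h, config.hv, ph_i, ph_o, config.temperature_c)
    return i_h + cl_current(v_mv, config.cl) + leak_current(v_mv, config)


@dataclass(frozen=True)
class RestingPotential:
    v_rest_mv: float
    roots_mv: tuple
    stable: tuple


def resting_potential(config: CellConfig, ph_o: float | None = None,
                      ph_i: float | None = None,
                      v_range=(-120.0, 80.0), n_grid: int = 801) -> RestingPotential:
    """Zero-net-current membrane potential with gates at steady state.

    All sign changes of the steady I(V) over ``v_range`` are bracketed on a
    grid and refined; a root is stable when the local slope conductance is
    positive. The most negative stable root is the resting potential.
    """
    grid = np.linspace(v_range[0], v_range[1], n_grid)
    vals = np.array([total_steady_current(v, config, ph_i, ph_o) for v in grid])
    roots, stable = [], []
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0:
            roots.append(float(grid[k]))
        elif a * b < 0:
            r = optimize.brentq(lambda v: total_steady_current(v, config, ph_i, ph_o),
                                grid[k], grid[k + 1], xtol=1e-10)
            roots.append(float(r))
    if not roots:
        raise ValueError("no zero crossing of the steady current in the search range")
    eps = 1e-4
    for r in roots:
        didv = (total_steady_current(r + eps, config, ph_i, ph_o)
                - total_steady_current(r - eps, config, ph_i, ph_o)) / (2 * eps)
        stable.append(didv > 0)
    stable_roots = [r for r, s in zip(roots, stable) if s]
    if not stable_roots:
        raise ValueError("no stable zero-current potential found")
    return RestingPotential(min(stable_roots), tuple(roots), tuple(stable))


# ---------------------------------------------------------------------------
# scenarios and events


@dataclass(frozen=True)
class Event:
    """Timed manipulation. Kinds: set_ph_o {ph_o}, zn_on {block_fraction?},
    zn_off, gd_on, gd_off, ca_free, nh4cl_pulse {duration_s, acid_load_mol_s},
    voltage_step {level_mv, duration_s}."""

    time_s: float
    kind: str
    params: dict = field(default_factory=dict)


EVENT_KINDS = ("set_ph_o", "zn_on", "zn_off", "gd_on", "gd_off", "ca_free",
               "nh4cl_pulse", "voltage_step")


@dataclass(frozen=True)
class Scenario:
    name: str
    config: CellConfig
    events: tuple = ()
    duration_s: float = 300.0

    def __post_init__(self):
        times = [e.time_s for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be time-ordered")
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {e.kind!r}")


@dataclass
class _Runtime:
    ph_o: float
    zn_block: float = 0.0
    cl_scale: float = 1.0
    gd: bool = False
    j_calc: float = 0.0
    extra_acid: float = 0.0
    clamp_mv: float | None = None


@dataclass
class SimulationResult:
    """Time courses plus per-pathway cumulative H+ (mol, alkalinising positive)."""

    time_s: np.ndarray
    v_m_mv: np.ndarray
    ph_i: np.ndarray
    p_open: np.ndarray
    i_h_pa: np.ndarray        # gated channel
    i_bg_pa: np.ndarray       # background H+ pathway
    i_cl_pa: np.ndarray
    i_leak_pa: np.ndarray
    q_channel_mol: np.ndarray
    q_background_mol: np.ndarray
    q_calc_mol: np.ndarray    # cumulative acid load (calcification + pulses), positive
    q_sec_mol: np.ndarray     # secondary regulation, signed
    config: CellConfig
    clamped: bool

    def ph_at(self, t_s: float) -> float:
        return float(np.interp(t_s, self.time_s, self.ph_i))

    def delta_ph(self, t_start_s: float, t_end_s: float) -> float:
        return self.ph_at(t_end_s) - self.ph_at(t_start_s)


def _default_dt(config: CellConfig, clamped: bool) -> float:
    """Fixed RK4 step (s): fastest of gate and membrane time constants / 20."""
    taus = [config.hv.tau_act_ms, config.hv.tau_deact_ms]
    if not clamped:
        g_tot = config.hv.g_max_ns + config.cl.g_max_ns + config.g_leak_ns
        if g_tot > 0:
            taus.append(config.c_m_pf / g_tot)  # pF/nS = ms
    return min(taus) / 20.0 * 1e-3


def _integrate(config: CellConfig, timeline, y0, dt_s: float):
    """Fixed-step RK4 over piecewise-constant runtime segments.

    timeline: list of (t0_s, t1_s, _Runtime). State y = (v, p, pH, q_ch,
    q_bg, q_calc, q_sec). Clamped segments pin v to the clamp level.
    """
    hv, cl = config.hv, config.cl
    slope = config.nernst_slope_mv
    delta, kk = hv.v_half_offset_mv, hv.slope_k_mv
    tau_a, tau_d = hv.tau_act_ms * 1e-3, hv.tau_deact_ms * 1e-3
    g_h, p_bg = hv.g_max_ns, hv.background_permeability
    g_cl, e_cl, vh_cl, k_cl = cl.g_max_ns, cl.e_cl_mv, cl.v_half_mv, cl.slope_k_mv
    g_leak, e_leak = config.g_leak_ns, config.e_leak_mv
    c_m = config.c_m_pf
    bcap = config.buffer_mol_per_ph
    k_sec, ph_set = config.k_sec_per_s, config.ph_set
    vt = thermal_voltage_mv(config.temperature_c)
    kmol = MOL_PER_SECOND_PER_PA
    exp = math.exp

    def currents(v, p, ph, rt):
        e_h = slope * (ph - rt.ph_o)
        x = -(v - (e_h + delta)) / kk
        p_inf = 0.0 if x > 700.0 else 1.0 / (1.0 + exp(x))
        i_gated = 0.0 if rt.gd else (1.0 - rt.zn_block) * g_h * p * (v - e_h)
        if p_bg != 0.0:
            u = v / vt
            if abs(u) < 1e-9:
                fac = vt * (10.0 ** (-ph) - 10.0 ** (-rt.ph_o))
            else:
                eu = exp(-u)
                fac = v * (10.0 ** (-ph) - 10.0 ** (-rt.ph_o) * eu) / (1.0 - eu)
            i_bg = p_bg * fac
        else:
            i_bg = 0.0
        xc = (v - vh_cl) / k_cl
        s_inf = 0.0 if xc > 700.0 else 1.0 / (1.0 + exp(xc))
        i_cl = rt.cl_scale * g_cl * s_inf * (v - e_cl)
        i_leak = g_leak * (v - e_leak)
        return p_inf, i_gated, i_bg, i_cl, i_leak

    def deriv(y, rt):
        v, p, ph = y[0], y[1], y[2]
        p_inf, i_gated, i_bg, i_cl, i_leak = currents(v, p, ph, rt)
        dp = (p_inf - p) / (tau_a if p_inf > p else tau_d)
        acid = rt.j_calc + rt.extra_acid
        dph = ((i_gated + i_bg) * kmol - acid) / bcap + k_sec * (ph_set - ph)
        dv = 0.0 if rt.clamp_mv is not None else -(i_gated + i_bg + i_cl + i_leak) / c_m * 1e3
        return (dv, dp, dph, i_gated * kmol, i_bg * kmol, acid, k_sec * (ph_set - ph) * bcap)

    n_total = sum(max(1, math.ceil((t1 - t0) / dt_s - 1e-12)) for t0, t1, _ in timeline) + 1
    out = np.empty((n_total, 12))
    y = list(y0)
    idx = 0

    def record(t, rt):
        nonlocal idx
        v, p, ph = y[0], y[1], y[2]
        _, i_gated, i_bg, i_cl, i_leak = currents(v, p, ph, rt)
        out[idx] = (t, v, ph, p, i_gated, i_bg, i_cl, i_leak, y[3], y[4], y[5], y[6])
        idx += 1

    first = True
    for t0, t1, rt in timeline:
        if rt.clamp_mv is not None:
            y[0] = rt.clamp_mv  # ideal clamp: v follows the command exactly
        if first:
            record(t0, rt)
            first = False
        n = max(1, math.ceil((t1 - t0) / dt_s - 1e-12))
        h = (t1 - t0) / n
        t = t0
        for _ in range(n):
            k1 = deriv(y, rt)
            y2 = [y[j] + 0.5 * h * k1[j] for j in range(7)]
            k2 = deriv(y2, rt)
            y3 = [y[j] + 0.5 * h * k2[j] for j in range(7)]
            k3 = deriv(y3, rt)
            y4 = [y[j] + h * k3[j] for j in range(7)]
            k4 = deriv(y4, rt)
            for j in range(7):
                y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            y[1] = min(1.0, max(0.0, y[1]))
            t += h
            if not all(math.isfinite(y[j]) for j in range(3)):
                raise ArithmeticError(f"integration diverged at t = {t:.4g} s")
            record(t, rt)
    out = out[:idx]
    return out


def _build_timeline(config: CellConfig, events, duration_s, holding_mv=None):
    """Expand events into piecewise-constant runtime segments."""
    rt = _Runtime(ph_o=config.ph_o, zn_block=0.0, cl_scale=1.0, gd=False,
                  j_calc=config.j_calc_mol_s, extra_acid=0.0, clamp_mv=holding_mv)
    boundaries = {0.0, duration_s}
    expanded = []
    for e in events:
        if e.time_s < 0 or e.time_s > duration_s:
            raise ValueError(f"event at {e.time_s} s outside the run duration")
        expanded.append(e)
        boundaries.add(e.time_s)
        if e.kind in ("nh4cl_pulse", "voltage_step"):
            t_end = e.time_s + float(e.params["duration_s"])
            boundaries.add(min(t_end, duration_s))
    times = sorted(boundaries)
    timeline = []
    for a, b in zip(times[:-1], times[1:]):
        for e in expanded:
            if e.time_s == a:
                _apply_event(rt, e, config)
        for e in expanded:  # pulse terminations
            if e.kind == "nh4cl_pulse" and math.isclose(e.time_s + e.params["duration_s"], a):
                rt.extra_acid = 0.0
            if e.kind == "voltage_step" and math.isclose(e.time_s + e.params["duration_s"], a):
                rt.clamp_mv = holding_mv
        timeline.append((a, b, replace(rt)))
    return timeline


def _apply_event(rt: _Runtime, e: Event, config: CellConfig):
    if e.kind == "set_ph_o":
        rt.ph_o = float(e.params["ph_o"])
    elif e.kind == "zn_on":
        block = float(e.params.get("block_fraction",
                                   config.hv.zn_block_fraction or NATIVE_ZN_BLOCK))
        rt.zn_block = block
        rt.cl_scale = 1.0 - config.cl.zn_sensitivity
    elif e.kind == "zn_off":
        rt.zn_block = 0.0
        rt.cl_scale = 1.0
    elif e.kind == "gd_on":
        rt.gd = True
    elif e.kind == "gd_off":
        rt.gd = False
    elif e.kind == "ca_free":
        rt.j_calc = 0.0
    elif e.kind == "nh4cl_pulse":
        rt.extra_acid = float(e.params["acid_load_mol_s"])
    elif e.kind == "voltage_step":
        rt.clamp_mv = float(e.params["level_mv"])


def _result_from(out: np.ndarray, config: CellConfig, clamped: bool) -> SimulationResult:
    return SimulationResult(
        time_s=out[:, 0], v_m_mv=out[:, 1], ph_i=out[:, 2], p_open=out[:, 3],
        i_h_pa=out[:, 4], i_bg_pa=out[:, 5], i_cl_pa=out[:, 6], i_leak_pa=out[:, 7],
        q_channel_mol=out[:, 8], q_background_mol=out[:, 9],
        q_calc_mol=out[:, 10], q_sec_mol=out[:, 11],
        config=config, clamped=clamped)


def simulate_voltage_clamp(protocol, config: CellConfig, sweep: int = 0,
                           dt_max_s: float | None = None) -> SimulationResult:
    """Ideal-voltage-clamp simulation of one sweep of an ephys protocol.

    ``protocol`` is an `ephys.VoltageProtocol` (times in ms). The membrane
    follows the command exactly; the gate relaxes with τ_act/τ_deact and
    pH_i integrates the proton budget, so outward H+ current alkalinises.
    """
    dt = _default_dt(config, clamped=True)
    if dt_max_s is not None:
        dt = min(dt, dt_max_s)
    timeline = []
    for (a_ms, b_ms, level) in protocol.segments(sweep):
        rt = _Runtime(ph_o=config.ph_o, j_calc=config.j_calc_mol_s, clamp_mv=level,
                      zn_block=config.hv.zn_block_fraction)
        timeline.append((a_ms * 1e-3, b_ms * 1e-3, rt))
    e_h0 = config.e_h_mv()
    p0 = hv_steady_open(protocol.holding_mv, e_h0, config.hv)
    y0 = (protocol.holding_mv, p0, config.ph_i, 0.0, 0.0, 0.0, 0.0)
    out = _integrate(config, timeline, y0, dt)
    return _result_from(out, config, clamped=True)


def clamp_step(config: CellConfig, level_mv: float, duration_s: float = 10.0,
               holding_mv: float = -50.0, dt_max_s: float | None = None) -> tuple:
    """Single square voltage-clamp step; returns (SimulationResult, ΔpH over the step).

    ΔpH is pH_i at step end minus pH_i at step onset, the quantity reported
    for the +20/+70 mV depolarisation experiments.
    """
    from .ephys import VoltageProtocol  # local import to avoid a cycle

    proto = VoltageProtocol(holding_mv=holding_mv, sampling_interval_ms=1.0,
                            pre_ms=100.0, step_levels_mv=(level_mv,),
                            step_ms=duration_s * 1e3, post_ms=0.0)
    res = simulate_voltage_clamp(proto, config, dt_max_s=dt_max_s)
    t0, t1 = 0.1, 0.1 + duration_s
    return res, res.delta_ph(t0, t1)


def simulate_free_running(config: CellConfig, scenario: Scenario | None = None,
                          duration_s: float | None = None,
                          start_at_steady_state: bool = True,
                          dt_max_s: float | None = None) -> SimulationResult:
    """Free-running membrane potential with scenario events.

    c_m dV/dt = −(I_h + I_cl + I_leak); pH follows the proton budget. The
    run starts from the coupled (V, pH) steady state unless disabled.
    """
    events = scenario.events if scenario is not None else ()
    if duration_s is None:
        duration_s = scenario.duration_s if scenario is not None else 300.0
    dt = _default_dt(config, clamped=False)
    if dt_max_s is not None:
        dt = min(dt, dt_max_s)
    if start_at_steady_state:
        v0, ph0 = steady_state(config)
    else:
        v0, ph0 = resting_potential(config).v_rest_mv, config.ph_i
    p0 = hv_steady_open(v0, config.e_h_mv(ph0), config.hv)
    timeline = _build_timeline(config, events, duration_s, holding_mv=None)
    y0 = (v0, p0, ph0, 0.0, 0.0, 0.0, 0.0)
    out = _integrate(config, timeline, y0, dt)
    return _result_from(out, config, clamped=False)


def steady_state(config: CellConfig, ph_bracket=(5.5, 8.8)) -> tuple:
    """Coupled free-running steady state (V_rest, pH_i): zero net current and zero dpH/dt."""
    kmol = MOL_PER_SECOND_PER_PA

    def dph_at(ph: float) -> float:
        v = resting_potential(config, ph_i=ph).v_rest_mv
        e_h = config.e_h_mv(ph_i=ph)
        p = hv_steady_open(v, e_h, config.hv)
        i_h = hv_current(v, p, e_h, config.hv, ph, config.ph_o, config.temperature_c)
        return ((i_h * kmol - config.j_calc_mol_s) / config.buffer_mol_per_ph
                + config.k_sec_per_s * (config.ph_set - ph))

    lo, hi = ph_bracket
    f_lo, f_hi = dph_at(lo), dph_at(hi)
    if f_lo * f_hi > 0:
        raise ValueError("no pH steady state in the bracket")
    ph = optimize.brentq(dph_at, lo, hi, xtol=1e-10)
    return resting_potential(config, ph_i=ph).v_rest_mv, float(ph)


def proton_budget(result: SimulationResult) -> dict:
    """Conservation audit: buffer term vs summed pathway terms (mol H+).

    β·V_cyt·ΔpH_i must equal channel + background − acid load + secondary
    regulation; the relative residual checks the integrator.
    """
    bcap = result.config.buffer_mol_per_ph
    buffer_term = bcap * (result.ph_i[-1] - result.ph_i[0])
    terms = {
        "channel": float(result.q_channel_mol[-1]),
        "background": float(result.q_background_mol[-1]),
        "acid_load": -float(result.q_calc_mol[-1]),
        "secondary_regulation": float(result.q_sec_mol[-1]),
    }
    total = sum(terms.values())
    scale = max([abs(v) for v in terms.values()] + [abs(buffer_term), 1e-30])
    return {**terms, "buffer": float(buffer_term), "closure_residual": float(buffer_term - total),
            "relative_residual": float(abs(buffer_term - total) / scale)}
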