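"""Ground-truth synthetic data generators.

Every analysis operation in the package is testable without any recorded
data: these generators produce voltage-clamp sweep families (activation and
tail protocols), BCECF fluorescence-ratio traces and cross-polarised
birefringence series from known parameters, and return a TruthManifest
recording everything needed to reproduce the output bit-for-bit.

Noise models: additive Gaussian for currents (pA) and intensity (a.u.),
multiplicative Gaussian for fluorescence. Capacitance transients are
injected at step edges as decaying exponentials (charge C·ΔV, default
τ 0.5 ms) so tail-current blanking is genuinely exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .ephys import RecordingMetadata, SweepFamily, VoltageProtocol
from .imaging import (DEFAULT_WINDOWS_MIN, BirefringenceSeries, RatioCalibration,
                      RatioTrace, calcification_rates)
from .iontheory import SolutionComposition, ph_equilibrium_potential
from .model import HvChannelParams, hv_steady_open

#: default in-cell calibration anchors used by the ratio generator
DEFAULT_R75 = 2.0
DEFAULT_R65 = 1.2


@dataclass(frozen=True)
class TruthManifest:
    """Machine-readable ground truth for one generated dataset."""

    generator: str
    seed: int
    truth: dict
    version: str = __version__

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


def native_channel_truth(g_max_ns: float = 2.0, tau_ms: float = 220.0) -> HvChannelParams:
    """Whole-cell-scale H+ channel truth with native C. pelagicus kinetics."""
    return HvChannelParams(g_max_ns=g_max_ns, v_half_offset_mv=5.0, slope_k_mv=6.0,
                           tau_act_ms=tau_ms, tau_deact_ms=tau_ms)


def e_rev_from_solutions(inside: SolutionComposition, outside: SolutionComposition,
                         slope_mv: float | None = None) -> float:
    """True reversal potential of a perfectly H+-selective channel for a solution pair."""
    return ph_equilibrium_potential(
        outside.pH, inside.pH, slope_mv=slope_mv,
        temperature_c=None if slope_mv is not None else inside.temperature_c).value_mv


def _forward_currents(protocol: VoltageProtocol, truth: HvChannelParams,
                      e_rev_mv: float) -> np.ndarray:
    """Noiseless gated-channel currents for every sweep of a protocol.

    The command is piecewise constant, so the gate relaxes exactly
    exponentially within each segment: p(t) = p_inf + (p0 − p_inf)e^(−Δt/τ).
    Pipette buffering is assumed perfect (fixed E_rev).
    """
    t = protocol.times_ms
    out = np.empty((protocol.n_sweeps, protocol.n_samples))
    for s in range(protocol.n_sweeps):
        p0 = hv_steady_open(protocol.holding_mv, e_rev_mv, truth)
        i = np.zeros_like(t)
        for (a, b, level) in protocol.segments(s):
            mask = (t >= a) & (t < b)
            p_inf = hv_steady_open(level, e_rev_mv, truth)
            tau = truth.tau_act_ms if p_inf > p0 else truth.tau_deact_ms
            p_seg = p_inf + (p0 - p_inf) * np.exp(-(t[mask] - a) / tau)
            i[mask] = ((1.0 - truth.zn_block_fraction) * truth.g_max_ns
                       * p_seg * (level - e_rev_mv))
            p0 = p_inf + (p0 - p_inf) * np.exp(-(b - a) / tau)
        out[s] = i
    return out


def _capacitance_transients(protocol: VoltageProtocol, sweep: int,
                            c_pf: float, tau_ms: float) -> np.ndarray:
    t = protocol.times_ms
    i = np.zeros_like(t)
    prev = protocol.holding_mv
    for (a, _b, level) in protocol.segments(sweep):
        dv = level - prev
        if dv != 0.0:
            amp = c_pf * dv / tau_ms  # pA; integrates to the charge C·ΔV
            mask = t >= a
            i[mask] += amp * np.exp(-(t[mask] - a) / tau_ms)
        prev = level
    return i


def _assemble_family(protocol, truth, e_rev_mv, r_seal_gohm, noise_sigma_pa, seed,
                     cap_transients, cap_pf, cap_tau_ms, generator_name):
    rng = np.random.default_rng(seed)
    currents = _forward_currents(protocol, truth, e_rev_mv)
    for s in range(protocol.n_sweeps):
        if np.isfinite(r_seal_gohm):
            currents[s] += (protocol.command(s) - protocol.holding_mv) / r_seal_gohm
        if cap_transients:
            currents[s] += _capacitance_transients(protocol, s, cap_pf, cap_tau_ms)
    if noise_sigma_pa > 0:
        currents += rng.normal(0.0, noise_sigma_pa, size=currents.shape)
    meta = RecordingMetadata(seal_resistance_gohm=r_seal_gohm,
                             series_resistance_mohm=(10.0, 10.2, 10.5),
                             capacitance_pf=cap_pf, temperature_c=20.0,
                             leak_subtracted=False)
    family = SweepFamily(protocol, currents, meta)
    manifest = TruthManifest(
        generator=generator_name, seed=int(seed),
        truth={
            "g_max_ns": truth.g_max_ns, "e_rev_mv": e_rev_mv,
            "v_half_offset_mv": truth.v_half_offset_mv, "slope_k_mv": truth.slope_k_mv,
            "tau_act_ms": truth.tau_act_ms, "tau_deact_ms": truth.tau_deact_ms,
            "zn_block_fraction": truth.zn_block_fraction,
            "r_seal_gohm": None if np.isinf(r_seal_gohm) else r_seal_gohm,
            "noise_sigma_pa": noise_sigma_pa,
            "capacitance_transients": bool(cap_transients),
            "cap_pf": cap_pf, "cap_tau_ms": cap_tau_ms,
            "protocol": {
                "holding_mv": protocol.holding_mv, "pre_ms": protocol.pre_ms,
                "step_levels_mv": list(protocol.step_levels_mv),
                "step_ms": protocol.step_ms,
                "tail_levels_mv": (None if protocol.tail_levels_mv is None
                                   else list(protocol.tail_levels_mv)),
                "tail_ms": protocol.tail_ms, "post_ms": protocol.post_ms,
                "sampling_interval_ms": protocol.sampling_interval_ms,
            },
        })
    return family, manifest


def gen_sweep_family(truth: HvChannelParams, e_rev_mv: float = -29.1,
                     protocol: VoltageProtocol | None = None,
                     r_seal_gohm: float = np.inf, noise_sigma_pa: float = 0.0,
                     seed: int = 0, cap_transients: bool = True,
                     cap_pf: float = 3.0, cap_tau_ms: float = 0.5):
    """Synthetic activation (I-V) sweep family: forward model + leak + noise.

    Returns (SweepFamily, TruthManifest). With noise_sigma 0 and infinite
    seal resistance the traces equal the forward model exactly (capacitance
    transients can be disabled for that comparison).
    """
    if protocol is None:
        protocol = VoltageProtocol.iv_family()
    return _assemble_family(protocol, truth, e_rev_mv, r_seal_gohm, noise_sigma_pa,
                            seed, cap_transients, cap_pf, cap_tau_ms, "gen_sweep_family")


def gen_tail_family(truth: HvChannelParams, e_rev_mv: float = -29.1,
                    tail_levels_mv=tuple(range(-75, 30, 10)),
                    prepulse_mv: float = 40.0, prepulse_ms: float = 1000.0,
                    tail_ms: float = 500.0, holding_mv: float = -80.0,
                    r_seal_gohm: float = np.inf, noise_sigma_pa: float = 0.0,
                    seed: int = 0, cap_transients: bool = True,
                    cap_pf: float = 3.0, cap_tau_ms: float = 0.5,
                    sampling_interval_ms: float = 1.0):
    """Synthetic tail-current family: activating prepulse then test pulses."""
    protocol = VoltageProtocol.tail_family(
        holding_mv=holding_mv, prepulse_mv=prepulse_mv, prepulse_ms=prepulse_ms,
        tail_levels_mv=tuple(tail_levels_mv), tail_ms=tail_ms,
        sampling_interval_ms=sampling_interval_ms)
    return _assemble_family(protocol, truth, e_rev_mv, r_seal_gohm, noise_sigma_pa,
                            seed, cap_transients, cap_pf, cap_tau_ms, "gen_tail_family")


def gen_ratio_trace(ph, time_s=None, cal: RatioCalibration | None = None,
                    noise_fraction: float = 0.0, seed: int = 0,
                    f458_level: float = 1000.0):
    """BCECF ratio trace from a pH trajectory through the inverse calibration map.

    ``ph`` is an explicit pH series or a `model.SimulationResult`. Both
    channels get independent multiplicative Gaussian noise of relative
    width ``noise_fraction``.
    """
    if hasattr(ph, "ph_i"):  # SimulationResult
        time_s = np.asarray(ph.time_s, dtype=float)
        ph_arr = np.asarray(ph.ph_i, dtype=float)
    else:
        ph_arr = np.asarray(ph, dtype=float)
        if time_s is None:
            time_s = np.arange(len(ph_arr), dtype=float)
        time_s = np.asarray(time_s, dtype=float)
    if not np.all(np.isfinite(ph_arr)):
        raise ValueError("pH trajectory contains non-finite values")
    if cal is None:
        cal = RatioCalibration(DEFAULT_R75, DEFAULT_R65)
    rng = np.random.default_rng(seed)
    ratio_true = np.asarray(cal.ratio(ph_arr), dtype=float)
    f458 = np.full_like(ratio_true, f458_level)
    f488 = ratio_true * f458_level
    if noise_fraction > 0:
        f488 = f488 * (1.0 + rng.normal(0.0, noise_fraction, size=f488.shape))
        f458 = f458 * (1.0 + rng.normal(0.0, noise_fraction, size=f458.shape))
    trace = RatioTrace(time_s, f488, f458)
    manifest = TruthManifest(
        generator="gen_ratio_trace", seed=int(seed),
        truth={"r75": cal.r75, "r65": cal.r65, "noise_fraction": noise_fraction,
               "f458_level": f458_level,
               "ph_start": float(ph_arr[0]), "ph_end": float(ph_arr[-1]),
               "n_samples": int(len(ph_arr))})
    return trace, manifest


#: nominal per-window slope ratios for the calcification scenarios; treatment-window
#: values encode 69.0% (low external pH) and 67.0% (ammonium pulse) inhibition
BIREFRINGENCE_SCENARIOS = {
    "control": {"slopes_au_min": (10.0, 10.0, 10.0), "lag_min": 0.0},
    "ph6.5": {"slopes_au_min": (10.0, 3.1, 8.0), "lag_min": 60.0},
    "nh4cl": {"slopes_au_min": (10.0, 3.3, 8.0), "lag_min": 60.0},
}


def gen_birefringence(scenario: str = "control", noise_sigma: float = 0.0,
                      seed: int = 0, frame_interval_min: float = 3.0,
                      windows_min=DEFAULT_WINDOWS_MIN, baseline: float = 100.0):
    """Cross-polarised intensity series for a named calcification scenario.

    Intensity rises piecewise linearly: the first-window slope everywhere
    before treatment, the treatment slope inside the second window, and —
    after a restoration lag at the start of the third window during which the
    treatment slope persists — a partial-recovery slope. The manifest records
    both the nominal slopes and the realised per-window OLS slopes of the
    noiseless series.
    """
    if scenario not in BIREFRINGENCE_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"known: {', '.join(sorted(BIREFRINGENCE_SCENARIOS))}")
    spec = BIREFRINGENCE_SCENARIOS[scenario]
    s1, s2, s3 = spec["slopes_au_min"]
    lag = spec["lag_min"]
    (w1a, w1b), (w2a, w2b), (w3a, w3b) = windows_min
    t = np.arange(w1a, w3b + 0.5 * frame_interval_min, frame_interval_min)

    def slope_at(x):
        if x < w2a:
            return s1
        if x < w2b:
            return s2
        if x < w2b + lag:
            return s2
        return s3

    # integrate the slope profile; breakpoints keep each window exactly linear
    breaks = sorted({w1a, w2a, w2b, w2b + lag, w3b})
    intensity = np.empty_like(t)
    for k, x in enumerate(t):
        acc, prev = baseline, breaks[0]
        for b in breaks[1:]:
            if x <= prev:
                break
            seg_end = min(x, b)
            acc += slope_at(0.5 * (prev + seg_end)) * (seg_end - prev)
            prev = b
        if x > prev:  # beyond the last break
            acc += slope_at(x) * (x - prev)
        intensity[k] = acc
    realized = calcification_rates(
        BirefringenceSeries(t, intensity, tuple(windows_min))).slopes_au_per_min
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, size=intensity.shape)
    series = BirefringenceSeries(t, intensity, tuple(windows_min))
    manifest = TruthManifest(
        generator="gen_birefringence", seed=int(seed),
        truth={"scenario": scenario, "nominal_slopes_au_min": [s1, s2, s3],
               "lag_min": lag, "noise_sigma": noise_sigma,
               "frame_interval_min": frame_interval_min, "baseline": baseline,
               "windows_min": [list(w) for w in windows_min],
               "realized_window_slopes_au_min": list(realized),
               "treatment_inhibition_percent": 100.0 * (1.0 - s2 / s1)})
    return series, manifest
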