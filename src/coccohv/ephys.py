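"""Whole-cell voltage-clamp trace analysis for the coccolithophore H+ current.

Implements the standard processing chain for depolarisation-activated
currents: resistive (seal) leak subtraction, steady-state current-voltage
extraction, tail-current reversal-potential estimation by linear regression,
single-exponential activation-kinetics fitting, Nernst-slope regression of
E_rev against ΔpH, and series-resistance quality control.

Sign convention: outward current (positive charge leaving the cell) is
positive; voltages are membrane potentials in mV. Time origin t = 0 is the
sweep start and all windows are half-open [start, end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize


class FitError(RuntimeError):
    """Exponential fit failed to converge; message carries diagnostics."""


# ---------------------------------------------------------------------------
# protocol and family containers


@dataclass(frozen=True)
class VoltageProtocol:
    """Command-voltage protocol for a family of sweeps.

    Each sweep holds at ``holding_mv`` for ``pre_ms``, steps to its entry of
    ``step_levels_mv`` for ``step_ms``, optionally steps to its entry of
    ``tail_levels_mv`` for ``tail_ms`` (tail/test pulse), then returns to
    holding for ``post_ms``.
    """

    holding_mv: float
    sampling_interval_ms: float
    pre_ms: float
    step_levels_mv: tuple
    step_ms: float
    tail_levels_mv: tuple | None = None
    tail_ms: float = 0.0
    post_ms: float = 0.0

    def __post_init__(self):
        if self.sampling_interval_ms <= 0:
            raise ValueError("sampling_interval_ms must be positive")
        if self.step_ms <= 0 or not self.step_levels_mv:
            raise ValueError("protocol needs a non-empty step of positive duration")
        if self.tail_levels_mv is not None:
            if self.tail_ms <= 0:
                raise ValueError("tail_ms must be positive when tail levels are given")
            if len(self.step_levels_mv) not in (1, len(self.tail_levels_mv)):
                raise ValueError("step_levels_mv must be scalar-like or match tail_levels_mv")

    @classmethod
    def iv_family(cls, holding_mv=-80.0, levels_mv=tuple(range(-80, 70, 10)),
                  step_ms=1000.0, pre_ms=50.0, post_ms=100.0, sampling_interval_ms=1.0):
        """Incremental depolarising steps (native protocol: 1 s, −80 to +60 mV)."""
        return cls(holding_mv, sampling_interval_ms, pre_ms, tuple(levels_mv), step_ms,
                   post_ms=post_ms)

    @classmethod
    def tail_family(cls, holding_mv=-80.0, prepulse_mv=40.0, prepulse_ms=1000.0,
                    tail_levels_mv=tuple(range(-75, 30, 10)), tail_ms=500.0,
                    pre_ms=50.0, post_ms=100.0, sampling_interval_ms=1.0):
        """Activating prepulse followed by test pulses (tail protocol)."""
        return cls(holding_mv, sampling_interval_ms, pre_ms, (prepulse_mv,), prepulse_ms,
                   tail_levels_mv=tuple(tail_levels_mv), tail_ms=tail_ms, post_ms=post_ms)

    @property
    def n_sweeps(self) -> int:
        if self.tail_levels_mv is not None:
            return len(self.tail_levels_mv)
        return len(self.step_levels_mv)

    @property
    def sweep_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.tail_ms + self.post_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_ms / self.sampling_interval_ms))

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval_ms

    @property
    def step_onset_ms(self) -> float:
        return self.pre_ms

    @property
    def tail_onset_ms(self) -> float:
        return self.pre_ms + self.step_ms

    def step_level(self, sweep: int) -> float:
        if len(self.step_levels_mv) == 1:
            return self.step_levels_mv[0]
        return self.step_levels_mv[sweep]

    def segments(self, sweep: int) -> list:
        """(t_start_ms, t_end_ms, level_mv) pieces of the command, half-open."""
        segs = [(0.0, self.pre_ms, self.holding_mv)]
        t = self.pre_ms
        segs.append((t, t + self.step_ms, self.step_level(sweep)))
        t += self.step_ms
        if self.tail_levels_mv is not None:
            segs.append((t, t + self.tail_ms, self.tail_levels_mv[sweep]))
            t += self.tail_ms
        segs.append((t, t + self.post_ms, self.holding_mv))
        return [(a, b, v) for a, b, v in segs if b > a]

    def command(self, sweep: int) -> np.ndarray:
        """Command voltage at every sample of one sweep."""
        t = self.times_ms
        v = np.full(t.shape, self.holding_mv)
        for a, b, level in self.segments(sweep):
            v[(t >= a) & (t < b)] = level
        return v


@dataclass
class RecordingMetadata:
    seal_resistance_gohm: float = math.inf
    series_resistance_mohm: tuple = ()
    capacitance_pf: float = float("nan")
    temperature_c: float = 20.0
    inside_label: str = ""
    outside_label: str = ""
    leak_subtracted: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class SweepFamily:
    """A voltage-protocol-indexed set of current traces plus recording metadata."""

    protocol: VoltageProtocol
    currents_pa: np.ndarray  # (n_sweeps, n_samples)
    metadata: RecordingMetadata = field(default_factory=RecordingMetadata)

    def __post_init__(self):
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        expected = (self.protocol.n_sweeps, self.protocol.n_samples)
        if self.currents_pa.shape != expected:
            raise ValueError(
                f"currents shape {self.currents_pa.shape} != protocol shape {expected}")
        if not np.all(np.isfinite(self.currents_pa)):
            raise ValueError("currents contain non-finite samples")


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class IVCurve:
    voltages_mv: np.ndarray
    currents_pa: np.ndarray
    window_ms: tuple  # (start, end) relative to sweep start


@dataclass(frozen=True)
class ReversalEstimate:
    e_rev_mv: float
    slope_conductance_ns: float
    r_squared: float
    n_points: int
    standard_error_mv: float
    reliable: bool = True
    note: str = ""


@dataclass(frozen=True)
class TauFit:
    tau_ms: float
    amplitude_pa: float
    offset_pa: float
    rmse_pa: float
    fit_window_ms: tuple
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple
    max_series_resistance_change: float


# ---------------------------------------------------------------------------
# operations


def leak_subtract(family: SweepFamily, seal_resistance_gohm: float | None = None) -> SweepFamily:
    """Remove the linear seal-resistance leak from every trace.

    The leak current is (V_command − V_holding)/R_seal (mV/GΩ = pA), so
    holding-level current is untouched. R_seal = inf is an identity. A family
    already marked leak-subtracted is rejected to prevent double subtraction.
    """
    if family.metadata.leak_subtracted:
        raise ValueError("family is already leak-subtracted")
    r = seal_resistance_gohm if seal_resistance_gohm is not None \
        else family.metadata.seal_resistance_gohm
    if not r > 0:
        raise ValueError("seal resistance must be positive")
    meta = replace(family.metadata, leak_subtracted=True)
    if math.isinf(r):
        return SweepFamily(family.protocol, family.currents_pa.copy(), meta)
    proto = family.protocol
    corrected = np.empty_like(family.currents_pa)
    for s in range(proto.n_sweeps):
        leak = (proto.command(s) - proto.holding_mv) / r
        corrected[s] = family.currents_pa[s] - leak
    return SweepFamily(proto, corrected, meta)


def steady_state_iv(family: SweepFamily, window_ms: float = 40.0) -> IVCurve:
    """Mean current over the final ``window_ms`` of the depolarising step, per sweep.

    The averaging window is anchored to the end of the step so a slowly
    activating current is measured near its steady state. Points are returned
    sorted by step voltage.
    """
    proto = family.protocol
    if not 0 < window_ms <= proto.step_ms:
        raise ValueError("window must be positive and fit within the step")
    t = proto.times_ms
    end = proto.step_onset_ms + proto.step_ms
    mask = (t >= end - window_ms) & (t < end)
    if not mask.any():
        raise ValueError("averaging window contains no samples")
    volts = np.array([proto.step_level(s) for s in range(proto.n_sweeps)])
    means = family.currents_pa[:, mask].mean(axis=1)
    order = np.argsort(volts)
    return IVCurve(volts[order], means[order], (end - window_ms, end))


def _tail_peaks(family: SweepFamily, blank_ms: float, search_ms: float):
    proto = family.protocol
    if proto.tail_levels_mv is None:
        raise ValueError("family has no tail test levels")
    if blank_ms < 0 or search_ms <= blank_ms:
        raise ValueError("need 0 <= blank < search")
    t = proto.times_ms
    onset = proto.tail_onset_ms
    mask = (t >= onset + blank_ms) & (t < onset + search_ms)
    if not mask.any():
        raise ValueError("tail search window contains no samples")
    peaks = np.empty(proto.n_sweeps)
    for s in range(proto.n_sweeps):
        seg = family.currents_pa[s, mask]
        peaks[s] = seg[np.argmax(np.abs(seg))]  # signed extremum
    return np.array(proto.tail_levels_mv, dtype=float), peaks


def tail_reversal(family: SweepFamily, blank_ms: float = 2.0,
                  search_ms: float = 20.0) -> ReversalEstimate:
    """Reversal potential from peak tail currents vs test voltage.

    For each test level the tail peak is the signed extremum of the
    (leak-subtracted) current between ``blank_ms`` (capacitance-transient
    blanking) and ``search_ms`` after the test step onset. E_rev is the
    zero-crossing of a single ordinary-least-squares line through
    (test voltage, peak); the regression slope is the tail slope conductance.
    """
    volts, peaks = _tail_peaks(family, blank_ms, search_ms)
    n = len(volts)
    if n < 3:
        raise ValueError("need at least 3 tail test levels")
    if np.allclose(peaks, 0.0):
        raise ValueError("all tail peaks are zero; regression is degenerate")
    slope, intercept = np.polyfit(volts, peaks, 1)
    fit = slope * volts + intercept
    ss_res = float(np.sum((peaks - fit) ** 2))
    ss_tot = float(np.sum((peaks - peaks.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    reliable, note = True, ""
    if slope <= 0:
        same_sign = np.all(peaks >= 0) or np.all(peaks <= 0)
        reliable = False
        note = ("non-positive tail slope"
                + ("; all peaks share one sign (no crossing observed)" if same_sign else ""))
        if slope == 0:
            raise ValueError("tail regression slope is zero; no crossing")
    e_rev = -intercept / slope
    # standard error of the x-intercept (inverse prediction at I = 0)
    if n > 2 and slope != 0:
        s_res = math.sqrt(ss_res / (n - 2))
        sxx = float(np.sum((volts - volts.mean()) ** 2))
        se = (s_res / abs(slope)) * math.sqrt(1.0 / n + (e_rev - volts.mean()) ** 2 / sxx)
    else:
        se = float("nan")
    return ReversalEstimate(float(e_rev), float(slope), r2, n, float(se), reliable, note)


def fit_activation_tau(times_ms: np.ndarray, current_pa: np.ndarray,
                       fit_start_ms: float = 0.0, fit_end_ms: float | None = None,
                       flat_amplitude_pa: float = 1e-6) -> TauFit:
    """Fit I(t) = offset + amplitude·(1 − exp(−(t − t0)/τ)) from ``fit_start_ms`` on.

    A trace whose fitted amplitude is below ``flat_amplitude_pa`` (or smaller
    than its residual noise) is returned flagged: τ is unidentifiable on a
    flat trace.
    """
    t = np.asarray(times_ms, dtype=float)
    i = np.asarray(current_pa, dtype=float)
    if fit_end_ms is None:
        fit_end_ms = t[-1] + (t[1] - t[0] if len(t) > 1 else 0.0)
    mask = (t >= fit_start_ms) & (t < fit_end_ms)
    tt, ii = t[mask] - fit_start_ms, i[mask]
    if len(tt) < 4:
        raise ValueError("too few samples in the fit window")
    span = float(ii[-1] - ii[0])
    if np.ptp(ii) < flat_amplitude_pa:
        return TauFit(float("nan"), 0.0, float(ii.mean()), float(ii.std()),
                      (fit_start_ms, fit_end_ms), flagged=True,
                      note="flat trace: amplitude ~ 0, tau unidentifiable")

    def model(x, offset, amplitude, tau):
        return offset + amplitude * (1.0 - np.exp(-x / tau))

    p0 = (float(ii[0]), span if span != 0 else float(np.ptp(ii)), max(tt[-1] / 5.0, 1e-3))
    try:
        popt, _ = optimize.curve_fit(model, tt, ii, p0=p0,
                                     bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                                     maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"activation fit did not converge: {exc}; p0={p0}") from exc
    offset, amplitude, tau = (float(x) for x in popt)
    rmse = float(np.sqrt(np.mean((model(tt, *popt) - ii) ** 2)))
    flagged = abs(amplitude) < max(flat_amplitude_pa, rmse * 0.5)
    note = "amplitude indistinguishable from noise" if flagged else ""
    return TauFit(tau, amplitude, offset, rmse, (fit_start_ms, fit_end_ms), flagged, note)


def nernst_slope(points) -> tuple:
    """OLS slope of E_rev (mV) against ΔpH (= pH_o − pH_i).

    Returns (slope mV/pH, intercept mV, r²). An H+-selective conductance at
    20 °C gives −58.2 mV/pH; native recordings deviate sub-Nernstian.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (ΔpH, E_rev) points")
    dph, erev = pts[:, 0], pts[:, 1]
    if np.ptp(dph) == 0:
        raise ValueError("all ΔpH values identical; slope undefined")
    slope, intercept = np.polyfit(dph, erev, 1)
    fit = slope * dph + intercept
    ss_tot = float(np.sum((erev - erev.mean()) ** 2))
    r2 = 1.0 - float(np.sum((erev - fit) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def qc_recording(metadata: RecordingMetadata,
                 max_fractional_change: float = 0.15) -> QCResult:
    """Series-resistance stability check: fail if (max−min)/first exceeds 15%."""
    series = tuple(metadata.series_resistance_mohm)
    if not series:
        raise ValueError("series_resistance_series is empty")
    reasons = []
    if len(series) == 1:
        return QCResult(True, ("warning: single series-resistance reading",), 0.0)
    change = (max(series) - min(series)) / series[0]
    if change > max_fractional_change:
        reasons.append(
            f"series resistance varied by {change:.1%} (> {max_fractional_change:.0%})")
    return QCResult(not reasons, tuple(reasons), change)
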