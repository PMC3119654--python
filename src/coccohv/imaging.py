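"""Single-cell imaging quantification: BCECF pH ratios and birefringence calcification rates.

BCECF reports cytosolic pH through the ratio of emission under 488 nm and
458 nm excitation (F488/F458, increasing with pH). Calibration is two-point
linear between in-cell anchors at pH_i 7.5 and 6.5; for ester-loaded cells
only ΔpH is meaningful, so event summaries are window means of pH
differences. Background fluorescence subtraction is off by default (it was
negligible in the source recordings).

Calcification is quantified from cross-polarised light intensity: calcite is
birefringent, so grey-scale intensity is proportional to the calcite
produced and its slope in time is a calcification rate. Rates are computed
by ordinary least squares in fixed windows (default 0–150, 150–300,
300–600 min) and normalised to the first window, making the readout
invariant to the arbitrary intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RatioCalibration:
    """Two-point linear map between BCECF ratio and pH.

    pH(R) = 6.5 + (R − R65)·(7.5 − 6.5)/(R75 − R65). Ratios outside the
    anchor span by more than ``extrapolation_fraction`` of the span are
    flagged out-of-range (still converted).
    """

    r75: float
    r65: float
    ph_high: float = 7.5
    ph_low: float = 6.5
    mode: str = "two-point-linear"
    extrapolation_fraction: float = 0.2

    def __post_init__(self):
        if not self.r75 > self.r65 > 0:
            raise ValueError("need R75 > R65 > 0 (BCECF ratio increases with pH)")
        if self.ph_high == self.ph_low:
            raise ValueError("anchor pH values must differ")

    def ph(self, ratio):
        ratio = np.asarray(ratio, dtype=float)
        out = self.ph_low + (ratio - self.r65) * (self.ph_high - self.ph_low) / (self.r75 - self.r65)
        return out if out.ndim else float(out)

    def ratio(self, ph):
        """Forward map pH → ratio (used by the synthetic generator)."""
        ph = np.asarray(ph, dtype=float)
        out = self.r65 + (ph - self.ph_low) * (self.r75 - self.r65) / (self.ph_high - self.ph_low)
        return out if out.ndim else float(out)

    def out_of_range(self, ratio):
        span = self.r75 - self.r65
        lo = self.r65 - self.extrapolation_fraction * span
        hi = self.r75 + self.extrapolation_fraction * span
        ratio = np.asarray(ratio, dtype=float)
        return (ratio < lo) | (ratio > hi)


def calibrate_two_point(r75: float, r65: float, **kwargs) -> RatioCalibration:
    """Build the two-point calibration from mean steady-state ratios at pH_i 7.5 and 6.5."""
    return RatioCalibration(r75=r75, r65=r65, **kwargs)


@dataclass
class RatioTrace:
    """Fluorescence ratio time series (times in s, intensities in a.u.)."""

    time_s: np.ndarray
    f488: np.ndarray
    f458: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f488 = np.asarray(self.f488, dtype=float)
        self.f458 = np.asarray(self.f458, dtype=float)
        if not (len(self.time_s) == len(self.f488) == len(self.f458)):
            raise ValueError("time/f488/f458 lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.f458 <= 0):
            raise ValueError("f458 must be positive wherever the ratio is defined")

    @property
    def ratio(self) -> np.ndarray:
        return self.f488 / self.f458


@dataclass(frozen=True)
class PhSeries:
    time_s: np.ndarray
    ph: np.ndarray
    out_of_range: np.ndarray
    calibration: RatioCalibration
    ester_loaded: bool = False


def ratio_to_ph(trace: RatioTrace, cal: RatioCalibration,
                ester_loaded: bool = False) -> PhSeries:
    """Convert a ratio trace to a pH time series.

    With ``ester_loaded`` set, absolute values are not trustworthy (no
    in-cell calibration is possible) and only differences should be reported;
    the flag is carried on the result so ΔpH summaries remain valid.
    """
    ratio = trace.ratio
    return PhSeries(trace.time_s, cal.ph(ratio), cal.out_of_range(ratio), cal, ester_loaded)


def event_delta_ph(series: PhSeries, event_time_s: float,
                   pre_window_s: float = 60.0, post_window_s: float = 60.0,
                   post_delay_s: float = 0.0) -> float:
    """ΔpH for a perfusion event: mean(post window) − mean(pre window).

    Pre window is [event − pre_window, event); post window is
    [event + post_delay + … , +post_window), ending before any washout the
    caller excludes via ``post_window_s``.
    """
    t = series.time_s
    pre = (t >= event_time_s - pre_window_s) & (t < event_time_s)
    post = (t >= event_time_s + post_delay_s) & (t < event_time_s + post_delay_s + post_window_s)
    if not pre.any() or not post.any():
        raise ValueError("empty pre or post window")
    if (event_time_s + post_delay_s) < event_time_s:
        raise ValueError("pre and post windows overlap")
    return float(series.ph[post].mean() - series.ph[pre].mean())


# ---------------------------------------------------------------------------
# birefringence / calcification

DEFAULT_WINDOWS_MIN = ((0.0, 150.0), (150.0, 300.0), (300.0, 600.0))


@dataclass
class BirefringenceSeries:
    """Cross-polarised intensity time series (time in min, intensity in a.u.)."""

    time_min: np.ndarray
    intensity: np.ndarray
    windows_min: tuple = DEFAULT_WINDOWS_MIN

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.time_min) != len(self.intensity):
            raise ValueError("time/intensity lengths differ")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CalcificationRates:
    windows_min: tuple
    slopes_au_per_min: tuple
    normalized: tuple  # slope / slope(first window)


def calcification_rates(series: BirefringenceSeries,
                        min_samples_per_window: int = 3) -> CalcificationRates:
    """Per-window OLS slopes of intensity vs time, normalised to the first window."""
    slopes = []
    for (a, b) in series.windows_min:
        mask = (series.time_min >= a) & (series.time_min < b)
        if mask.sum() < min_samples_per_window:
            raise ValueError(f"window ({a}, {b}) min has {int(mask.sum())} samples; "
                             f"need >= {min_samples_per_window}")
        slope, _ = np.polyfit(series.time_min[mask], series.intensity[mask], 1)
        slopes.append(float(slope))
    if slopes[0] <= 0:
        raise ValueError("first-window slope is non-positive; cannot normalise")
    normalized = tuple(s / slopes[0] for s in slopes)
    return CalcificationRates(tuple(series.windows_min), tuple(slopes), normalized)


def inhibition_percent(rates: CalcificationRates, treatment_window_index: int = 1) -> float:
    """Percent inhibition of calcification in the treatment window: 100·(1 − normalised rate)."""
    norm = rates.normalized
    if not 0 <= treatment_window_index < len(norm):
        raise IndexError("treatment window index out of range")
    return 100.0 * (1.0 - norm[treatment_window_index])
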