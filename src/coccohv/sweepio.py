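"""Plain-text readers and writers for the package's tabular formats.

Sweep families travel as a CSV table (columns sweep_id, time_ms, voltage_mV,
current_pA) plus a YAML sidecar (`<file>.meta.yml`) of key: value lines
carrying the protocol, seal and series resistance, temperature and solution
labels. Ratio traces, birefringence series and simulation results are plain
CSV. All times are ms (except simulation results, in s), voltages mV,
currents pA; pH is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ephys import RecordingMetadata, SweepFamily, VoltageProtocol
from .imaging import BirefringenceSeries, RatioTrace
from .model import SimulationResult

SWEEP_COLUMNS = ("sweep_id", "time_ms", "voltage_mV", "current_pA")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line where possible."""


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.yml")


def write_sweep_family(family: SweepFamily, path) -> Path:
    """Write the data table and its metadata sidecar; returns the table path."""
    path = Path(path)
    proto = family.protocol
    frames = []
    for s in range(proto.n_sweeps):
        frames.append(pd.DataFrame({
            "sweep_id": s,
            "time_ms": proto.times_ms,
            "voltage_mV": proto.command(s),
            "current_pA": family.currents_pa[s],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format='%.17g')
    meta = family.metadata
    sidecar = {
        "protocol": {
            "holding_mv": proto.holding_mv,
            "sampling_interval_ms": proto.sampling_interval_ms,
            "pre_ms": proto.pre_ms,
            "step_levels_mv": list(proto.step_levels_mv),
            "step_ms": proto.step_ms,
            "tail_levels_mv": None if proto.tail_levels_mv is None else list(proto.tail_levels_mv),
            "tail_ms": proto.tail_ms,
            "post_ms": proto.post_ms,
        },
        "seal_resistance_gohm": ("inf" if math.isinf(meta.seal_resistance_gohm)
                                 else meta.seal_resistance_gohm),
        "series_resistance_mohm": list(meta.series_resistance_mohm),
        "capacitance_pf": None if math.isnan(meta.capacitance_pf) else meta.capacitance_pf,
        "temperature_c": meta.temperature_c,
        "inside_label": meta.inside_label,
        "outside_label": meta.outside_label,
        "leak_subtracted": meta.leak_subtracted,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_sweep_family(path) -> SweepFamily:
    """Read and validate a sweep family written by `write_sweep_family`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{sidecar}: metadata sidecar missing")
    meta_raw = yaml.safe_load(sidecar.read_text())
    p = meta_raw["protocol"]
    proto = VoltageProtocol(
        holding_mv=float(p["holding_mv"]),
        sampling_interval_ms=float(p["sampling_interval_ms"]),
        pre_ms=float(p["pre_ms"]),
        step_levels_mv=tuple(p["step_levels_mv"]),
        step_ms=float(p["step_ms"]),
        tail_levels_mv=None if p.get("tail_levels_mv") is None else tuple(p["tail_levels_mv"]),
        tail_ms=float(p.get("tail_ms", 0.0)),
        post_ms=float(p.get("post_ms", 0.0)),
    )
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in SWEEP_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    numeric = {}
    for col in SWEEP_COLUMNS:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise FormatError(f"{path}: non-numeric value {table[col][bad.idxmax()]!r} "
                              f"in column {col!r} at line {line}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise FormatError(f"{path}: empty cell in column {col!r} at line {line}")
        # numpy strtod is correctly rounded; pandas' fast parser is not
        numeric[col] = table[col].to_numpy(dtype="U32").astype(np.float64)
    sweep_ids = numeric["sweep_id"].astype(int)
    n_samples = proto.n_samples
    currents = np.empty((proto.n_sweeps, n_samples))
    for s in range(proto.n_sweeps):
        mask = sweep_ids == s
        if mask.sum() != n_samples:
            raise FormatError(f"{path}: sweep {s} has {int(mask.sum())} samples; "
                              f"protocol requires {n_samples}")
        t = numeric["time_ms"][mask]
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: non-monotone time in sweep {s}")
        currents[s] = numeric["current_pA"][mask]
    r_seal = meta_raw.get("seal_resistance_gohm", "inf")
    metadata = RecordingMetadata(
        seal_resistance_gohm=math.inf if r_seal in ("inf", None) else float(r_seal),
        series_resistance_mohm=tuple(meta_raw.get("series_resistance_mohm", ())),
        capacitance_pf=(float("nan") if meta_raw.get("capacitance_pf") is None
                        else float(meta_raw["capacitance_pf"])),
        temperature_c=float(meta_raw.get("temperature_c", 20.0)),
        inside_label=str(meta_raw.get("inside_label", "")),
        outside_label=str(meta_raw.get("outside_label", "")),
        leak_subtracted=bool(meta_raw.get("leak_subtracted", False)),
    )
    return SweepFamily(proto, currents, metadata)


def write_ratio_trace(trace: RatioTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "f488": trace.f488,
                  "f458": trace.f458}).to_csv(path, index=False, float_format='%.17g')
    return path


def read_ratio_trace(path) -> RatioTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "f488", "f458"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return RatioTrace(df["time_s"].to_numpy(), df["f488"].to_numpy(), df["f458"].to_numpy())


def write_birefringence(series: BirefringenceSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_min": series.time_min,
                  "intensity": series.intensity}).to_csv(path, index=False, float_format='%.17g')
    return path


def read_birefringence(path, windows_min=None) -> BirefringenceSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_min", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    kwargs = {} if windows_min is None else {"windows_min": tuple(windows_min)}
    return BirefringenceSeries(df["time_min"].to_numpy(), df["intensity"].to_numpy(), **kwargs)


def write_simulation_result(result: SimulationResult, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": result.time_s, "v_m_mV": result.v_m_mv, "pH_i": result.ph_i,
        "i_h_pA": result.i_h_pa, "i_bg_pA": result.i_bg_pa, "i_cl_pA": result.i_cl_pa,
        "i_leak_pA": result.i_leak_pa, "p_open": result.p_open,
    }).to_csv(path, index=False, float_format='%.17g')
    return path


@dataclass
class RunRecord:
    """Provenance stamp for one CLI invocation."""

    command: str
    parameters: dict
    inputs: list
    outputs: list
    version: str
    timestamp: str

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
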