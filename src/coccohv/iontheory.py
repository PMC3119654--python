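"""Closed-form electrochemistry for the coccolithophore H+ conductance.

Equilibrium (Nernst) potentials, the Goldman-Hodgkin-Katz (GHK) voltage
equation for mixtures of monovalent ions, the inverse selectivity problem
(how H+-selective must a conductance be for its reversal potential to sit
within a stated distance of E_H+), and the arithmetic linking calcification
H+ production to a cytosolic acidification rate.

Conventions
-----------
* ΔpH = pH_o − pH_i throughout the package.
* Concentrations are treated as activities (no activity-coefficient
  correction); a documented limitation.
* H+ concentration is always derived from pH (10^−pH mol/L), never stored.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import yaml

from .constants import FARADAY, MOL_PER_SECOND_PER_PA, nernst_slope_mv

MONOVALENT_CATIONS = ("H", "Na", "K")
MONOVALENT_ANIONS = ("Cl",)
SUPPORTED_IONS = MONOVALENT_CATIONS + MONOVALENT_ANIONS
ION_CHARGE = {"H": 1, "Na": 1, "K": 1, "Cl": -1, "Ca": 2, "Mg": 2}


class SelectivityNotFoundError(ValueError):
    """No permeability ratio in [1, 1e12] brings the GHK reversal within tolerance of E_H+."""


@dataclass(frozen=True)
class SolutionComposition:
    """Ionic composition of one side of the membrane.

    Concentrations are total millimolar of the free ion; ``H`` must not be
    supplied (it is derived from ``pH``).
    """

    label: str
    ions: dict = field(default_factory=dict)  # mM, keys among Na/K/Cl/Ca/Mg
    pH: float = 7.0
    temperature_c: float = 20.0
    buffer: str = ""

    def __post_init__(self):
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH {self.pH} outside [0, 14]")
        for ion, c in self.ions.items():
            if ion == "H":
                raise ValueError("H+ is derived from pH; do not list it as an ion")
            if ion not in ION_CHARGE:
                raise ValueError(f"unknown ion {ion!r}")
            if c < 0:
                raise ValueError(f"negative concentration for {ion}")

    def concentration_mM(self, ion: str) -> float:
        """Free concentration in mM; H+ computed from pH."""
        if ion == "H":
            return 10.0 ** (-self.pH) * 1e3
        return float(self.ions.get(ion, 0.0))


@dataclass(frozen=True)
class EquilibriumPotential:
    ion: str
    value_mv: float
    slope_used_mv: float  # mV per tenfold ratio, for z = 1
    temperature_c: float | None


@dataclass(frozen=True)
class AcidLoadEstimate:
    proton_flux_mol_s: float
    cytosolic_volume_l: float
    buffer_capacity: float  # mol L^-1 pH^-1
    rate_ph_min: float


def nernst_potential(z: int, c_out: float, c_in: float,
                     temperature_c: float = 20.0, ion: str = "") -> EquilibriumPotential:
    """Nernst equilibrium potential (2.303·RT/zF)·log10(c_out/c_in) in mV.

    z is the signed ionic charge; c_out/c_in in any common concentration unit.
    """
    if z == 0:
        raise ValueError("z must be nonzero")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    slope = nernst_slope_mv(temperature_c)
    value = slope / z * math.log10(c_out / c_in)
    return EquilibriumPotential(ion=ion, value_mv=value, slope_used_mv=slope,
                                temperature_c=temperature_c)


def ph_equilibrium_potential(ph_o: float, ph_i: float, slope_mv: float | None = None,
                             temperature_c: float | None = None) -> EquilibriumPotential:
    """E_H+ = slope·(pH_i − pH_o) in mV.

    Exactly one of ``slope_mv`` (explicit mV/decade, e.g. the rounded 60) or
    ``temperature_c`` (Nernstian slope at that temperature) must be given;
    the choice is deliberately caller-visible because a rounded slope is the
    convention behind the −48 mV resting E_H+ at pH_o 8.0 / pH_i 7.2.
    """
    for ph in (ph_o, ph_i):
        if not 0.0 <= ph <= 14.0:
            raise ValueError(f"pH {ph} outside [0, 14]")
    if (slope_mv is None) == (temperature_c is None):
        raise ValueError("give exactly one of slope_mv or temperature_c")
    slope = nernst_slope_mv(temperature_c) if slope_mv is None else float(slope_mv)
    return EquilibriumPotential(ion="H", value_mv=slope * (ph_i - ph_o),
                                slope_used_mv=slope, temperature_c=temperature_c)


def ghk_reversal(permeabilities: dict, inside: SolutionComposition,
                 outside: SolutionComposition) -> float:
    """GHK reversal potential (mV) for relative permeabilities of monovalent ions.

    ``permeabilities`` maps ion names (H, Na, K, Cl) to relative permeability.
    Cations enter with outside concentration in the numerator; Cl with sides
    swapped. Divalent ions are rejected: the monovalent voltage form does not
    treat them consistently.
    """
    cleaned = {ion: p for ion, p in permeabilities.items() if p != 0.0}
    if not cleaned:
        raise ValueError("at least one permeability must be positive")
    for ion, p in cleaned.items():
        if p < 0:
            raise ValueError(f"negative permeability for {ion}")
        if ion not in SUPPORTED_IONS:
            raise ValueError(f"ion {ion!r} unsupported by the monovalent GHK voltage form")
    num = 0.0
    den = 0.0
    for ion, p in cleaned.items():
        if ion in MONOVALENT_CATIONS:
            num += p * outside.concentration_mM(ion)
            den += p * inside.concentration_mM(ion)
        else:  # anion: sides swapped
            num += p * inside.concentration_mM(ion)
            den += p * outside.concentration_mM(ion)
    slope = nernst_slope_mv(inside.temperature_c)
    return slope * math.log10(num / den)


def min_selectivity_ratio(inside: SolutionComposition, outside: SolutionComposition,
                          contaminant_ion: str = "K", tolerance_mv: float = 10.0,
                          slope_mv: float | None = None) -> float:
    """Smallest P_H/P_contaminant putting the two-ion GHK reversal within tolerance of E_H+.

    The deviation |V_rev(r) − E_H+| decreases monotonically in the ratio r,
    so the threshold is located by bisection on log10(r) over [0, 12].
    Raises SelectivityNotFoundError if even r = 1e12 misses the tolerance.
    """
    if tolerance_mv <= 0:
        raise ValueError("tolerance must be positive")
    e_h = ph_equilibrium_potential(
        outside.pH, inside.pH,
        slope_mv=slope_mv,
        temperature_c=inside.temperature_c if slope_mv is None else None,
    ).value_mv

    def deviation(log10_r: float) -> float:
        v = ghk_reversal({"H": 10.0 ** log10_r, contaminant_ion: 1.0}, inside, outside)
        return abs(v - e_h)

    lo, hi = 0.0, 12.0
    if deviation(hi) > tolerance_mv:
        raise SelectivityNotFoundError(
            f"no P_H/P_{contaminant_ion} ratio up to 1e12 reaches ±{tolerance_mv} mV of E_H+")
    if deviation(lo) <= tolerance_mv:
        return 1.0
    for _ in range(80):  # bisection to ~1e-22 relative in log-ratio
        mid = 0.5 * (lo + hi)
        if deviation(mid) <= tolerance_mv:
            hi = mid
        else:
            lo = mid
    return 10.0 ** hi


def acid_load_rate(proton_flux_mol_s: float, cytosolic_volume_l: float,
                   buffer_capacity: float) -> AcidLoadEstimate:
    """Cytosolic acidification rate (pH min⁻¹) from an H+ production flux.

    rate = flux / (β · V_cyt) · 60, with β in mol L⁻¹ pH⁻¹. One mole of H+
    is produced per mole of calcite precipitated from bicarbonate, so for a
    calcifying cell the flux is the calcification rate.
    """
    if proton_flux_mol_s < 0:
        raise ValueError("proton flux must be non-negative")
    if cytosolic_volume_l <= 0 or buffer_capacity <= 0:
        raise ValueError("volume and buffer capacity must be positive")
    rate = proton_flux_mol_s / (buffer_capacity * cytosolic_volume_l) * 60.0
    return AcidLoadEstimate(proton_flux_mol_s, cytosolic_volume_l, buffer_capacity, rate)


def current_to_proton_flux(current_pa: float) -> float:
    """mol H+ s⁻¹ carried by a current in pA (outward positive; sign preserved)."""
    return current_pa * MOL_PER_SECOND_PER_PA


def proton_flux_to_current(flux_mol_s: float) -> float:
    """Inverse of current_to_proton_flux: pA equivalent of a mol s⁻¹ H+ flux."""
    return flux_mol_s * FARADAY * 1e12


def load_solutions() -> dict:
    """Packaged electrophysiology solution compositions, keyed by label (E1, P1a, ...)."""
    text = importlib.resources.files("coccohv").joinpath("data/solutions.yml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for label, entry in raw["solutions"].items():
        out[label] = SolutionComposition(
            label=label,
            ions={k: float(v) for k, v in entry.get("ions", {}).items()},
            pH=float(entry["pH"]),
            temperature_c=float(entry.get("temperature_c", 20.0)),
            buffer=str(entry.get("buffer", "")),
        )
    return out
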