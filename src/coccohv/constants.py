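"""Physical constants and temperature-dependent electrochemical slopes.

All potentials in the package are millivolts, currents picoamps,
concentrations millimolar (except where a function states otherwise),
temperatures degrees Celsius, and pH dimensionless.
"""

import math

GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1

#: mol of H+ carried per second by 1 pA of current (1e-12 / F)
MOL_PER_SECOND_PER_PA = 1e-12 / FARADAY


def kelvin(temperature_c: float) -> float:
    return temperature_c + 273.15


def thermal_voltage_mv(temperature_c: float) -> float:
    """RT/F in mV (≈25.3 mV at 20 °C)."""
    return GAS_CONSTANT * kelvin(temperature_c) / FARADAY * 1e3


def nernst_slope_mv(temperature_c: float) -> float:
    """2.303·RT/F in mV per tenfold concentration ratio (58.17 mV at 20 °C)."""
    return math.log(10.0) * thermal_voltage_mv(temperature_c)
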