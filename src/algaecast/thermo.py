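"""Moist-air helper relations used by the disaggregator and the pond model.

Saturation vapor pressure follows the Magnus form; pressures are in kPa and
temperatures in degrees Celsius throughout the package.
"""

from __future__ import annotations

import numpy as np

# Magnus coefficients (Alduchov-Eskridge style fit over liquid water)
_A = 0.6108  # kPa
_B = 17.27
_C = 237.3  # degC

EPSILON = 0.622  # molecular-weight ratio of water vapor to dry air


def saturation_vapor_pressure(temp_c):
    """Saturation vapor pressure (kPa) over liquid water at ``temp_c`` (degC)."""
    t = np.asarray(temp_c, dtype=float)
    out = _A * np.exp(_B * t / (t + _C))
    return float(out) if out.ndim == 0 else out


def dewpoint_from_vapor_pressure(vapor_pressure_kpa):
    """Invert the Magnus curve: dewpoint (degC) at actual vapor pressure (kPa)."""
    e = np.asarray(vapor_pressure_kpa, dtype=float)
    if np.any(e <= 0):
        raise ValueError("vapor pressure must be positive")
    ln_ratio = np.log(e / _A)
    out = _C * ln_ratio / (_B - ln_ratio)
    return float(out) if out.ndim == 0 else out


def vapor_pressure_from_specific_humidity(specific_humidity, pressure_kpa):
    """Actual vapor pressure (kPa) from specific humidity (kg/kg) and air pressure."""
    q = np.asarray(specific_humidity, dtype=float)
    p = np.asarray(pressure_kpa, dtype=float)
    out = q * p / (EPSILON + (1.0 - EPSILON) * q)
    return float(out) if out.ndim == 0 else out


def specific_humidity_from_dewpoint(dewpoint_c, pressure_kpa):
    """Specific humidity (kg/kg) of air saturated at ``dewpoint_c`` under ``pressure_kpa``."""
    e = saturation_vapor_pressure(dewpoint_c)
    out = EPSILON * e / (np.asarray(pressure_kpa, dtype=float) - (1.0 - EPSILON) * e)
    return float(out) if np.ndim(out) == 0 else out


def dewpoint_from_specific_humidity(specific_humidity, pressure_kpa):
    """Dewpoint (degC) implied by specific humidity (kg/kg) and pressure (kPa)."""
    e = vapor_pressure_from_specific_humidity(specific_humidity, pressure_kpa)
    return dewpoint_from_vapor_pressure(e)
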