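"""Well-mixed (0-D) raceway-pond water temperature model.

The pond is treated as a single fully mixed water column of fixed depth whose
temperature responds to the hourly surface energy balance:

    net = SW*(1 - albedo) + LW_down - LW_up - latent - sensible + conduction

with Stefan-Boltzmann longwave exchange (atmospheric emissivity from dewpoint
via a Brutsaert-type clear-sky formula), mass-transfer latent heat with a
linear wind function, Bowen-ratio sensible heat, and linear conduction to the
ground.  Temperature is advanced by explicit Euler steps with automatic
sub-stepping for stability.  All exchange coefficients are configurable; the
defaults are generic pond-model values, not a site calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .meteo import HourlyMeteoSeries
from .thermo import saturation_vapor_pressure

logger = logging.getLogger(__name__)

STEFAN_BOLTZMANN = 5.670374419e-8  # W/m^2/K^4
KELVIN = 273.15


@dataclass
class ThermalParams:
    """Coefficients of the pond surface energy balance.

    wind_function_a/b define the evaporative mass-transfer function
    f(u) = a + b*u in W/m^2 per kPa of vapor-pressure deficit;
    ``sky_emissivity`` overrides the dewpoint-based clear-sky emissivity when
    set (useful for idealized radiative-equilibrium configurations).
    """

    water_albedo: float = 0.06
    water_emissivity: float = 0.97
    sky_emissivity: float | None = None
    wind_function_a: float = 30.0  # W/m^2/kPa
    wind_function_b: float = 20.0  # W/m^2/kPa per m/s
    bowen_coefficient: float = 0.061  # kPa/degC
    conduction_coefficient: float = 0.5  # W/m^2/degC
    ground_temp: float = 15.0  # degC
    water_density: float = 1000.0  # kg/m^3
    specific_heat: float = 4186.0  # J/kg/degC
    temp_floor: float = -5.0  # degC, physical clipping window
    temp_ceiling: float = 45.0
    max_substep_dt_change: float = 0.5  # degC allowed per explicit sub-step
    max_substeps: int = 256

    def __post_init__(self):
        if not 0.0 <= self.water_albedo < 1.0:
            raise DomainError("water_albedo must be in [0, 1)")
        if not 0.0 < self.water_emissivity <= 1.0:
            raise DomainError("water_emissivity must be in (0, 1]")
        if self.water_density <= 0 or self.specific_heat <= 0:
            raise DomainError("heat-capacity terms must be positive")


@dataclass
class FluxComponents:
    """Surface energy balance decomposition (W/m^2, positive = pond gains)."""

    shortwave_absorbed: float
    longwave_down: float
    longwave_up: float
    latent: float
    sensible: float
    conduction: float

    @property
    def net(self) -> float:
        return (
            self.shortwave_absorbed
            + self.longwave_down
            - self.longwave_up
            - self.latent
            - self.sensible
            + self.conduction
        )


@dataclass
class WaterTempSeries:
    """Hourly pond water temperature aligned to the driving meteorology."""

    temps: pd.Series  # degC, DatetimeIndex matching the forcing

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.temps.index


def _sky_emissivity(air_temp: float, dewpoint: float, params: ThermalParams) -> float:
    if params.sky_emissivity is not None:
        return params.sky_emissivity
    e_hpa = saturation_vapor_pressure(dewpoint) * 10.0  # kPa -> hPa
    eps = 1.24 * (e_hpa / (air_temp + KELVIN)) ** (1.0 / 7.0)
    return min(eps, 1.0)


def surface_fluxes(
    water_temp: float,
    met,
    params: ThermalParams | None = None,
) -> FluxComponents:
    """Evaluate every surface-flux component for one hourly record.

    ``met`` is any mapping with air_temp, dewpoint, wind_speed, shortwave
    (pressure is carried for completeness but not used by the flux forms).
    """
    params = params or ThermalParams()
    air = float(met["air_temp"])
    dew = float(met["dewpoint"])
    wind = float(met["wind_speed"])
    sw = float(met["shortwave"])
    emis = params.water_emissivity

    sw_abs = sw * (1.0 - params.water_albedo)
    eps_sky = _sky_emissivity(air, dew, params)
    lw_down = emis * eps_sky * STEFAN_BOLTZMANN * (air + KELVIN) ** 4
    lw_up = emis * STEFAN_BOLTZMANN * (water_temp + KELVIN) ** 4
    f_wind = params.wind_function_a + params.wind_function_b * wind
    vpd = saturation_vapor_pressure(water_temp) - saturation_vapor_pressure(dew)
    latent = f_wind * vpd
    sensible = f_wind * params.bowen_coefficient * (water_temp - air)
    conduction = params.conduction_coefficient * (params.ground_temp - water_temp)
    return FluxComponents(sw_abs, lw_down, lw_up, latent, sensible, conduction)


def step_water_temp(
    water_temp: float,
    net_flux: float,
    depth_cm: float,
    params: ThermalParams | None = None,
    dt_s: float = 3600.0,
) -> float:
    """One explicit energy-balance step: T' = T + net*dt / (rho*c*d)."""
    params = params or ThermalParams()
    if depth_cm <= 0:
        raise DomainError("depth must be positive")
    if dt_s <= 0:
        raise DomainError("dt must be positive")
    heat_capacity = params.water_density * params.specific_heat * (depth_cm / 100.0)
    return water_temp + net_flux * dt_s / heat_capacity


def simulate_pond(
    met: HourlyMeteoSeries,
    depth_cm: float,
    params: ThermalParams | None = None,
    initial_temp: float = 5.0,
) -> WaterTempSeries:
    """Simulate hourly pond water temperature under the given forcing.

    Explicit Euler with automatic sub-stepping: each hour is subdivided until
    no sub-step changes the temperature by more than
    ``params.max_substep_dt_change``; exceeding ``max_substeps`` aborts with a
    diagnostic.  The default initial temperature is the 5 degC cold-start
    used to remove initial-condition memory from monthly runs.
    """
    params = params or ThermalParams()
    if depth_cm <= 0:
        raise DomainError("depth must be positive")
    if len(met) == 0:
        raise DataError("empty forcing series")

    heat_capacity = params.water_density * params.specific_heat * (depth_cm / 100.0)
    air = met.data["air_temp"].to_numpy().tolist()
    dew = met.data["dewpoint"].to_numpy().tolist()
    wind = met.data["wind_speed"].to_numpy().tolist()
    sw = met.data["shortwave"].to_numpy().tolist()

    emis = params.water_emissivity
    albedo = params.water_albedo
    bowen = params.bowen_coefficient
    cond_k = params.conduction_coefficient
    t_ground = params.ground_temp
    a_w, b_w = params.wind_function_a, params.wind_function_b
    eps_fixed = params.sky_emissivity

    temp = float(initial_temp)
    out = np.empty(len(air))
    clipped = False
    for i in range(len(air)):
        ta, td, u, s = air[i], dew[i], wind[i], sw[i]
        # hour-constant pieces of the flux
        e_dew = 0.6108 * math.exp(17.27 * td / (td + 237.3))
        if eps_fixed is not None:
            eps_sky = eps_fixed
        else:
            eps_sky = min(1.24 * ((e_dew * 10.0) / (ta + KELVIN)) ** (1.0 / 7.0), 1.0)
        gain = (
            s * (1.0 - albedo)
            + emis * eps_sky * STEFAN_BOLTZMANN * (ta + KELVIN) ** 4
        )
        f_wind = a_w + b_w * u

        n_sub = 1
        while True:
            t = temp
            dt = 3600.0 / n_sub
            ok = True
            for _ in range(n_sub):
                e_w = 0.6108 * math.exp(17.27 * t / (t + 237.3))
                net = (
                    gain
                    - emis * STEFAN_BOLTZMANN * (t + KELVIN) ** 4
                    - f_wind * (e_w - e_dew)
                    - f_wind * bowen * (t - ta)
                    + cond_k * (t_ground - t)
                )
                delta = net * dt / heat_capacity
                if abs(delta) > params.max_substep_dt_change:
                    ok = False
                    break
                t += delta
            if ok:
                break
            n_sub *= 2
            if n_sub > params.max_substeps:
                raise DataError(
                    f"pond simulation unstable at hour {i} "
                    f"(|dT| > {params.max_substep_dt_change} degC even with "
                    f"{params.max_substeps} sub-steps)"
                )
        temp = t
        if temp < params.temp_floor or temp > params.temp_ceiling:
            temp = min(max(temp, params.temp_floor), params.temp_ceiling)
            clipped = True
        out[i] = temp
    if clipped:
        logger.warning(
            "simulate_pond: water temperature clipped to [%s, %s] degC",
            params.temp_floor, params.temp_ceiling,
        )
    return WaterTempSeries(pd.Series(out, index=met.index, name="water_temp"))
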