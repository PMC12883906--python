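"""MTCLIM-style temporal disaggregation of daily weather to hourly forcing.

Seasonal forecast products typically issue daily values (Tmax, Tmin,
precipitation, humidity, wind, pressure), while the pond and growth models
need hourly air temperature, shortwave radiation and dewpoint.  This module
converts daily members to hourly series using:

* cubic (third-order) polynomial temperature segments anchored at the daily
  minimum (sunrise) and maximum (mid-afternoon),
* a Bristow-Campbell-type atmospheric transmittance driven by the daily
  temperature range, reduced on days with precipitation (precipitation is the
  proxy for cloud cover), applied to top-of-atmosphere flux from solar
  geometry,
* dewpoint held at the daily minimum temperature (or derived from specific
  humidity when available), clamped so it never exceeds air temperature.

The scheme is deterministic: re-aggregating its output recovers the daily
tmax/tmin exactly and the daily precipitation total to float precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from . import thermo
from .errors import DataError, DomainError
from .meteo import DailyMeteoSeries, HourlyMeteoSeries, SiteInfo

#: total solar irradiance at the mean earth-sun distance, W/m^2
SOLAR_CONSTANT = 1361.0

#: maximum |latitude| handled (no polar day/night logic)
MAX_LATITUDE = 66.5


@dataclass
class DisaggregationConfig:
    """Tunables of the daily-to-hourly scheme.

    hour_of_tmax : local hour at which the temperature curve peaks.
    hour_of_tmin : ``"sunrise"`` (computed from solar geometry) or a fixed hour.
    transmittance_max : clear-sky atmospheric transmittance ceiling.
    wet_day_transmittance_factor : multiplier applied on any day with precip > 0.
    bristow_campbell_b, bristow_campbell_c : coefficients of the
        transmittance response to daily temperature range,
        tau = tau_max * (1 - exp(-B * dT**C)).
    """

    hour_of_tmax: int = 15
    hour_of_tmin: str | int = "sunrise"
    transmittance_max: float = 0.75
    wet_day_transmittance_factor: float = 0.75
    bristow_campbell_b: float = 0.036
    bristow_campbell_c: float = 2.4

    def __post_init__(self):
        if not 0.0 < self.transmittance_max <= 1.0:
            raise DomainError("transmittance_max must be in (0, 1]")
        if not 0.0 < self.wet_day_transmittance_factor <= 1.0:
            raise DomainError("wet_day_transmittance_factor must be in (0, 1]")


def _declination_deg(day_of_year: int) -> float:
    """Solar declination (degrees), Cooper's approximation."""
    return 23.45 * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)


def solar_geometry(latitude: float, day_of_year: int, hour: float):
    """Instantaneous solar position and top-of-atmosphere flux.

    Returns ``(zenith_deg, toa_flux_w_m2, daylight)`` for the given local
    standard-time hour (solar noon assumed at hour 12).
    """
    if abs(latitude) > MAX_LATITUDE:
        raise DomainError(f"|latitude| must be <= {MAX_LATITUDE}")
    decl = math.radians(_declination_deg(day_of_year))
    lat = math.radians(latitude)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(
        hour_angle
    )
    cos_zen = max(-1.0, min(1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))
    daylight = cos_zen > 0.0
    flux = SOLAR_CONSTANT * cos_zen if daylight else 0.0
    return zenith, flux, daylight


def sunrise_hour(latitude: float, day_of_year: int) -> float:
    """Local standard-time hour of sunrise (fractional)."""
    if abs(latitude) > MAX_LATITUDE:
        raise DomainError(f"|latitude| must be <= {MAX_LATITUDE}")
    decl = math.radians(_declination_deg(day_of_year))
    lat = math.radians(latitude)
    cos_h0 = -math.tan(lat) * math.tan(decl)
    cos_h0 = max(-1.0, min(1.0, cos_h0))
    half_day_hours = math.degrees(math.acos(cos_h0)) / 15.0
    return 12.0 - half_day_hours


def _tmin_anchor_hour(config: DisaggregationConfig, latitude: float, day_of_year: int) -> int:
    if config.hour_of_tmin == "sunrise":
        h = int(round(sunrise_hour(latitude, day_of_year)))
    else:
        h = int(config.hour_of_tmin)
    # keep the anchor strictly before the afternoon maximum
    return max(0, min(h, config.hour_of_tmax - 1))


def diurnal_temperature(
    day: pd.Series,
    prev_day: pd.Series | None = None,
    next_day: pd.Series | None = None,
    config: DisaggregationConfig | None = None,
    latitude: float = 33.4,
) -> np.ndarray:
    """24 hourly air temperatures for one day from (tmax, tmin) anchors.

    Cubic Hermite segments with zero slope at each anchor connect the previous
    day's maximum, today's minimum (at sunrise), today's maximum (at
    ``hour_of_tmax``) and the next day's minimum, giving a smooth third-order
    polynomial curve that attains tmax and tmin exactly and is continuous
    across midnight.  Output is clipped to ``[tmin, tmax]``.
    """
    config = config or DisaggregationConfig()
    tmax, tmin = float(day["tmax"]), float(day["tmin"])
    if tmax < tmin:
        raise DomainError("tmax < tmin")
    doy = int(pd.Timestamp(day.name).dayofyear)
    t_min_h = _tmin_anchor_hour(config, latitude, doy)
    t_max_h = config.hour_of_tmax

    prev_tmax = float(prev_day["tmax"]) if prev_day is not None else tmax
    next_tmin = float(next_day["tmin"]) if next_day is not None else tmin
    if next_day is not None:
        next_doy = int(pd.Timestamp(next_day.name).dayofyear)
        next_min_h = _tmin_anchor_hour(config, latitude, next_doy)
    else:
        next_min_h = t_min_h

    x = np.array([t_max_h - 24.0, float(t_min_h), float(t_max_h), 24.0 + next_min_h])
    y = np.array([prev_tmax, tmin, tmax, next_tmin])
    spline = CubicHermiteSpline(x, y, np.zeros(4))
    hours = np.arange(24.0)
    temps = spline(hours)
    return np.clip(temps, tmin, tmax)


def estimate_solar(
    day: pd.Series,
    latitude: float = 33.4,
    config: DisaggregationConfig | None = None,
) -> np.ndarray:
    """24 hourly shortwave fluxes (W/m^2) from the daily temperature range.

    Transmittance tau = tau_max * (1 - exp(-B * dT**C)); days with any
    precipitation get tau scaled by ``wet_day_transmittance_factor``.
    Hourly flux is tau times the top-of-atmosphere flux at that hour.
    """
    config = config or DisaggregationConfig()
    tmax, tmin = float(day["tmax"]), float(day["tmin"])
    if tmax < tmin:
        raise DomainError("tmax < tmin")
    delta_t = tmax - tmin
    tau = config.transmittance_max * (
        1.0 - math.exp(-config.bristow_campbell_b * delta_t**config.bristow_campbell_c)
    )
    if float(day["precip"]) > 0.0:
        tau *= config.wet_day_transmittance_factor
    doy = int(pd.Timestamp(day.name).dayofyear)
    flux = np.array([solar_geometry(latitude, doy, h)[1] for h in range(24)])
    return tau * flux


def estimate_humidity(day: pd.Series) -> np.ndarray:
    """24 hourly dewpoints (degC) for one day.

    The dewpoint is held at the daily minimum temperature (the standard
    MTCLIM assumption that the air saturates around dawn).  If the daily
    record carries ``specific_humidity`` (kg/kg), the dewpoint is instead
    derived from it and the daily pressure through the saturation curve.
    """
    q = day.get("specific_humidity", None)
    if q is not None and np.isfinite(q):
        dewpoint = thermo.dewpoint_from_specific_humidity(float(q), float(day["pressure"]))
    else:
        dewpoint = float(day["tmin"])
    return np.full(24, dewpoint)


def disaggregate_member(
    daily: DailyMeteoSeries,
    latitude: float | None = None,
    config: DisaggregationConfig | None = None,
) -> HourlyMeteoSeries:
    """Convert a contiguous daily series to an hourly series.

    Composes the diurnal-temperature, solar and humidity estimators; wind and
    pressure persist within each day; daily precipitation is spread uniformly
    over the 24 hours.  Dewpoint is clamped to the concurrent air temperature.
    """
    config = config or DisaggregationConfig()
    if latitude is None:
        latitude = daily.site.latitude
    df = daily.data
    if len(df) == 0:
        raise DataError("empty daily series")
    gaps = np.diff(df.index.view("int64"))
    if len(gaps) and np.any(gaps != 86_400_000_000_000):
        raise DataError("daily series must be contiguous (1-day spacing)")

    n = len(df)
    rows = [df.iloc[i] for i in range(n)]
    air, dew, sw, precip, wind, pres = [], [], [], [], [], []
    for i, day in enumerate(rows):
        prev_day = rows[i - 1] if i > 0 else None
        next_day = rows[i + 1] if i < n - 1 else None
        t = diurnal_temperature(day, prev_day, next_day, config, latitude)
        d = np.minimum(estimate_humidity(day), t)
        air.append(t)
        dew.append(d)
        sw.append(estimate_solar(day, latitude, config))
        precip.append(np.full(24, float(day["precip"]) / 24.0))
        wind.append(np.full(24, float(day["wind_speed"])))
        pres.append(np.full(24, float(day["pressure"])))

    index = pd.date_range(df.index[0], periods=24 * n, freq="h")
    data = pd.DataFrame(
        {
            "air_temp": np.concatenate(air),
            "dewpoint": np.concatenate(dew),
            "wind_speed": np.concatenate(wind),
            "pressure": np.concatenate(pres),
            "shortwave": np.concatenate(sw),
            "precip": np.concatenate(precip),
        },
        index=index,
    )
    site = SiteInfo(latitude=latitude, longitude=daily.site.longitude,
                    elevation=daily.site.elevation)
    return HourlyMeteoSeries(data, site=site)
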