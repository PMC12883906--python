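"""Core meteorological containers, unit conventions, CSV I/O, and aggregation.

Package-wide unit conventions
-----------------------------
=============  ==============  =========
field          unit            notes
=============  ==============  =========
air_temp       degC
dewpoint       degC            <= air_temp + 0.5 degC tolerance
wind_speed     m/s
pressure       kPa
shortwave      W/m^2           downwelling at the surface, >= 0
precip         mm/h (hourly) / mm/day (daily)
=============  ==============  =========

Timestamps are local standard time (no DST shifts) at strict 1-hour spacing;
solar-geometry calculations rely on the fixed offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError
from . import thermo

logger = logging.getLogger(__name__)

HOURLY_FIELDS = ("air_temp", "dewpoint", "wind_speed", "pressure", "shortwave", "precip")
DAILY_FIELDS = ("tmax", "tmin", "precip", "wind_speed", "pressure")

#: tolerance (degC) by which dewpoint may exceed air temperature before it is
#: considered a data error (supersaturation from instrument rounding is common)
DEWPOINT_TOLERANCE_C = 0.5

# Unit converters normalising declared input units to the package conventions.
_UNIT_CONVERTERS = {
    "degC": lambda x: x,
    "C": lambda x: x,
    "degF": lambda x: (x - 32.0) * 5.0 / 9.0,
    "F": lambda x: (x - 32.0) * 5.0 / 9.0,
    "K": lambda x: x - 273.15,
    "kPa": lambda x: x,
    "Pa": lambda x: x / 1000.0,
    "hPa": lambda x: x / 10.0,
    "mb": lambda x: x / 10.0,
    "m/s": lambda x: x,
    "km/h": lambda x: x / 3.6,
    "mph": lambda x: x * 0.44704,
    "W/m2": lambda x: x,
    "mm": lambda x: x,
    "in": lambda x: x * 25.4,
}


@dataclass
class SiteInfo:
    """Geographic metadata attached to a meteorological series."""

    latitude: float = 33.4  # degrees north
    longitude: float = -111.7  # degrees east
    elevation: float = 420.0  # m above sea level


@dataclass
class HourlyMeteoSeries:
    """Hourly meteorological forcing with site metadata.

    ``data`` holds one row per hour with a strictly increasing, gap-free
    DatetimeIndex and the columns listed in :data:`HOURLY_FIELDS`.
    """

    data: pd.DataFrame
    site: SiteInfo = field(default_factory=SiteInfo)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [c for c in HOURLY_FIELDS if c not in self.data.columns]
        if missing:
            raise FormatError(f"hourly series missing columns: {missing}")
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise FormatError("hourly series index must be a DatetimeIndex")
        if len(idx) == 0:
            return
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate timestamp {dup}")
        diffs = np.diff(idx.view("int64"))
        if np.any(diffs <= 0):
            raise DataError("timestamps are not strictly increasing")
        if np.any(diffs != 3_600_000_000_000):
            raise DataError("hourly series must be contiguous at 1 h spacing")
        if (self.data["shortwave"] < 0).any():
            raise DataError("negative shortwave radiation")
        if (self.data["precip"] < 0).any():
            raise DataError("negative precipitation")
        excess = self.data["dewpoint"] - self.data["air_temp"]
        if (excess > DEWPOINT_TOLERANCE_C).any():
            raise DataError(
                f"dewpoint exceeds air temperature by more than {DEWPOINT_TOLERANCE_C} degC"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def slice_month(self, year: int, month: int) -> "HourlyMeteoSeries":
        """Return the sub-series covering one calendar month (must be complete)."""
        mask = (self.index.year == year) & (self.index.month == month)
        sub = self.data.loc[mask]
        expected = pd.Period(f"{year}-{month:02d}").days_in_month * 24
        if len(sub) != expected:
            raise DataError(
                f"month {year}-{month:02d}: found {len(sub)} of {expected} hours"
            )
        return HourlyMeteoSeries(sub.copy(), site=self.site)

    def with_data(self, data: pd.DataFrame) -> "HourlyMeteoSeries":
        return HourlyMeteoSeries(data, site=replace(self.site))


@dataclass
class DailyMeteoSeries:
    """Daily meteorological summaries (forecast members, aggregation output)."""

    data: pd.DataFrame  # DatetimeIndex (midnight), columns DAILY_FIELDS (+ specific_humidity)
    site: SiteInfo = field(default_factory=SiteInfo)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [c for c in DAILY_FIELDS if c not in self.data.columns]
        if missing:
            raise FormatError(f"daily series missing columns: {missing}")
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise FormatError("daily series index must be a DatetimeIndex")
        if len(idx) == 0:
            return
        if idx.has_duplicates:
            raise DataError("duplicate date in daily series")
        if not idx.is_monotonic_increasing:
            raise DataError("dates are not increasing")
        if (self.data["tmax"] < self.data["tmin"]).any():
            raise DataError("tmax < tmin")
        if (self.data["precip"] < 0).any():
            raise DataError("negative precipitation")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index


def _convert_units(df: pd.DataFrame, units: dict | None) -> pd.DataFrame:
    if not units:
        return df
    for col, unit in units.items():
        if col not in df.columns:
            raise FormatError(f"units declared for unknown column {col!r}")
        try:
            conv = _UNIT_CONVERTERS[unit]
        except KeyError:
            raise FormatError(f"unknown unit {unit!r} for column {col!r}") from None
        df[col] = conv(df[col].astype(float))
    return df


def read_hourly_csv(
    path,
    column_map: dict | None = None,
    units: dict | None = None,
    site: SiteInfo | None = None,
    timestamp_column: str = "timestamp",
) -> HourlyMeteoSeries:
    """Read an hourly forcing CSV.

    Parameters
    ----------
    column_map
        Mapping from file column names to the canonical field names.
    units
        Mapping from canonical field name to the declared unit in the file
        (e.g. ``{"dewpoint": "degF"}``); values are converted to package units.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if timestamp_column not in df.columns:
        raise FormatError(f"missing timestamp column {timestamp_column!r}")
    missing = [c for c in HOURLY_FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns after mapping: {missing}")
    df[timestamp_column] = pd.to_datetime(df[timestamp_column])
    df = df.set_index(timestamp_column)[list(HOURLY_FIELDS)].astype(float)
    df = _convert_units(df, units)
    return HourlyMeteoSeries(df, site=site or SiteInfo())


def write_hourly_csv(series: HourlyMeteoSeries, path) -> None:
    """Write an hourly series in the canonical CSV layout (round-trip safe)."""
    out = series.data.copy()
    out.index.name = "timestamp"
    out.to_csv(path, float_format="%.10g")


def read_daily_csv(
    path,
    column_map: dict | None = None,
    site: SiteInfo | None = None,
    date_column: str = "date",
) -> DailyMeteoSeries:
    """Read a daily summary CSV (e.g. one forecast member)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if date_column not in df.columns:
        raise FormatError(f"missing date column {date_column!r}")
    missing = [c for c in DAILY_FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns after mapping: {missing}")
    df[date_column] = pd.to_datetime(df[date_column])
    cols = list(DAILY_FIELDS) + (
        ["specific_humidity"] if "specific_humidity" in df.columns else []
    )
    df = df.set_index(date_column)[cols].astype(float)
    return DailyMeteoSeries(df, site=site or SiteInfo())


def write_daily_csv(series: DailyMeteoSeries, path) -> None:
    out = series.data.copy()
    out.index.name = "date"
    out.to_csv(out if path is None else path, float_format="%.10g")


def aggregate_daily(series: HourlyMeteoSeries) -> DailyMeteoSeries:
    """Collapse hourly forcing to daily summaries.

    tmax/tmin are the max/min of the day's hourly air temperature, precip is
    the daily total, wind and pressure are daily means. Days with fewer than
    24 records (series edges) are dropped with a logged warning.
    """
    df = series.data
    if len(df) == 0:
        empty = pd.DataFrame(columns=list(DAILY_FIELDS), index=pd.DatetimeIndex([]))
        return DailyMeteoSeries(empty, site=series.site)
    day = df.index.normalize()
    counts = df.groupby(day).size()
    complete = counts[counts == 24].index
    dropped = counts[counts != 24]
    if len(dropped):
        logger.warning(
            "aggregate_daily: dropping %d incomplete day(s): %s",
            len(dropped),
            ", ".join(str(d.date()) for d in dropped.index),
        )
    sub = df[np.isin(day, complete)]
    g = sub.groupby(sub.index.normalize())
    out = pd.DataFrame(
        {
            "tmax": g["air_temp"].max(),
            "tmin": g["air_temp"].min(),
            "precip": g["precip"].sum(),
            "wind_speed": g["wind_speed"].mean(),
            "pressure": g["pressure"].mean(),
        }
    )
    # daily humidity summary from mean dewpoint, handy for forecast-member files
    mean_dew = g["dewpoint"].mean()
    out["specific_humidity"] = thermo.specific_humidity_from_dewpoint(
        mean_dew.to_numpy(), out["pressure"].to_numpy()
    )
    return DailyMeteoSeries(out, site=series.site)


#: fraction of broadband shortwave that is photosynthetically active
PAR_FRACTION = 0.45
#: photon content of PAR energy, umol photons per joule
PAR_QUANTA_PER_JOULE = 4.57


def shortwave_to_par(shortwave, par_fraction: float = PAR_FRACTION,
                     quanta_per_joule: float = PAR_QUANTA_PER_JOULE):
    """Convert shortwave irradiance (W/m^2) to PAR (umol photons/m^2/s)."""
    sw = np.asarray(shortwave, dtype=float)
    if np.any(sw < 0):
        raise DomainError("shortwave must be >= 0")
    out = sw * par_fraction * quanta_per_joule
    return float(out) if out.ndim == 0 else out
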