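"""Synthetic weather archives, forecast members, and archetype strains.

Everything the forecasting chain consumes can be generated here with no
external data: a multi-year hourly archive with a seasonal temperature cycle,
AR(1) interannual and synoptic anomalies, a diurnal cycle, intermittent
precipitation and cloud-reduced solar radiation; daily forecast members whose
error shrinks with a skill parameter; and smooth warm/cold archetype
growth-rate surfaces.  All outputs are deterministic given the seeds.

Daily weather for a given year depends only on the climate spec and that
year (per-year seeding), so regenerating any sub-period reproduces the same
values regardless of the span requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disaggregation import DisaggregationConfig, disaggregate_member
from .errors import DomainError
from .growth import StrainParams
from .meteo import DailyMeteoSeries, HourlyMeteoSeries, SiteInfo

_BASE_YEAR = 1900  # anchor for the interannual AR(1) recursion


@dataclass
class ClimateSpec:
    """Parameters of the synthetic climate (defaults: hot semi-arid site).

    wet_day_prob is (DJF, MAM, JJA, SON); temperatures in degC, precip in mm.
    """

    latitude: float = 33.4
    longitude: float = -111.7
    elevation: float = 360.0
    annual_mean_temp: float = 20.0
    seasonal_amplitude: float = 9.0
    diurnal_amplitude: float = 10.0
    interannual_sd: float = 0.9
    anomaly_autocorr: float = 0.6
    synoptic_sd: float = 1.8
    synoptic_autocorr: float = 0.7
    wet_day_prob: tuple[float, float, float, float] = (0.15, 0.06, 0.12, 0.08)
    mean_wet_day_precip: float = 6.0
    wind_mean: float = 3.0
    pressure_kpa: float = 97.0
    seed: int = 42

    def __post_init__(self):
        if self.seasonal_amplitude < 0 or self.diurnal_amplitude < 0:
            raise DomainError("amplitudes must be >= 0")
        if not 0 <= self.anomaly_autocorr < 1:
            raise DomainError("anomaly_autocorr must be in [0, 1)")
        if any(not 0 <= p <= 1 for p in self.wet_day_prob):
            raise DomainError("wet-day probabilities must be in [0, 1]")

    @property
    def site(self) -> SiteInfo:
        return SiteInfo(self.latitude, self.longitude, self.elevation)


@dataclass
class StrainArchetype:
    """Compact description of a strain used to build a smooth rate surface."""

    name: str
    optimum_temp: float  # degC
    thermal_breadth: float  # degC, Gaussian half-width
    max_growth_rate: float  # 1/day
    light_half_saturation: float  # umol/m^2/s
    photoinhibition_onset: float | None = None  # umol/m^2/s
    dark_respiration: float = 0.05  # 1/day

    def __post_init__(self):
        if self.max_growth_rate <= 0 or self.thermal_breadth <= 0:
            raise DomainError("max rate and breadth must be positive")


def warm_archetype() -> StrainArchetype:
    """Warm-water strain: peak growth near 30 degC, collapses below ~15 degC."""
    return StrainArchetype(
        name="warm_archetype", optimum_temp=30.0, thermal_breadth=6.0,
        max_growth_rate=2.8, light_half_saturation=250.0, dark_respiration=0.18,
    )


def cold_archetype() -> StrainArchetype:
    """Cold-tolerant strain: peak near 18 degC with a broad thermal niche."""
    return StrainArchetype(
        name="cold_archetype", optimum_temp=18.0, thermal_breadth=8.0,
        max_growth_rate=2.0, light_half_saturation=200.0, dark_respiration=0.12,
    )


def _annual_anomaly(spec: ClimateSpec, year: int) -> float:
    """Interannual AR(1) temperature anomaly, reproducible per year."""
    rho = spec.anomaly_autocorr
    innov_sd = spec.interannual_sd * np.sqrt(1.0 - rho**2)
    a = 0.0
    for y in range(_BASE_YEAR, year + 1):
        eps = np.random.default_rng([spec.seed, 1, y]).standard_normal()
        a = rho * a + innov_sd * eps
    return float(a)


_SEASON_OF_MONTH = {12: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1,
                    6: 2, 7: 2, 8: 2, 9: 3, 10: 3, 11: 3}


def _daily_skeleton(spec: ClimateSpec, start_year: int, end_year: int) -> DailyMeteoSeries:
    """Daily tmax/tmin/precip/wind/pressure for whole calendar years."""
    if end_year < start_year:
        raise DomainError("end_year must be >= start_year")
    frames = []
    for year in range(start_year, end_year + 1):
        rng = np.random.default_rng([spec.seed, 2, year])
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        seasonal = spec.annual_mean_temp + spec.seasonal_amplitude * np.cos(
            2.0 * np.pi * (doy - 197) / 365.25
        )
        # synoptic AR(1) anomaly, restarted each year from its stationary draw
        n = len(dates)
        rho = spec.synoptic_autocorr
        innov = rng.standard_normal(n) * spec.synoptic_sd * np.sqrt(1 - rho**2)
        syn = np.empty(n)
        syn[0] = rng.standard_normal() * spec.synoptic_sd
        for i in range(1, n):
            syn[i] = rho * syn[i - 1] + innov[i]
        tmean = seasonal + _annual_anomaly(spec, year) + syn

        months = dates.month.to_numpy()
        p_wet = np.array([spec.wet_day_prob[_SEASON_OF_MONTH[m]] for m in months])
        wet = rng.random(n) < p_wet
        precip = np.where(wet, rng.exponential(spec.mean_wet_day_precip, n), 0.0)

        drange = spec.diurnal_amplitude * np.exp(rng.normal(0.0, 0.08, n))
        drange = np.where(wet, drange * 0.7, drange)
        drange = np.maximum(drange, 0.5)

        wind = np.maximum(0.5, spec.wind_mean * (1.0 + rng.normal(0.0, 0.25, n)))
        pressure = spec.pressure_kpa + rng.normal(0.0, 0.15, n)
        frames.append(
            pd.DataFrame(
                {
                    "tmax": tmean + drange / 2.0,
                    "tmin": tmean - drange / 2.0,
                    "precip": precip,
                    "wind_speed": wind,
                    "pressure": pressure,
                },
                index=dates,
            )
        )
    return DailyMeteoSeries(pd.concat(frames), site=spec.site)


def generate_archive(
    spec: ClimateSpec,
    start_year: int,
    end_year: int,
    config: DisaggregationConfig | None = None,
) -> HourlyMeteoSeries:
    """Multi-year hourly archive (the stand-in for a historical forcing record).

    Daily weather is drawn per the spec and disaggregated to hourly with the
    same scheme applied to forecast members, so archive statistics and
    disaggregated forecasts share diurnal structure by construction.
    """
    daily = _daily_skeleton(spec, start_year, end_year)
    return disaggregate_member(daily, latitude=spec.latitude, config=config)


def generate_forecast_members(
    spec: ClimateSpec,
    target_year: int,
    target_month: int,
    n_members: int,
    skill: float,
    seed: int,
) -> dict[str, DailyMeteoSeries]:
    """Daily forecast members for one month as truth plus scaled noise.

    Members equal the truth daily series (with one buffer day on each side
    for diurnal continuity) perturbed by member-specific bias and daily noise
    whose amplitude scales with (1 - skill); ``skill=1`` reproduces the truth
    exactly.  Ensemble spread therefore shrinks monotonically as skill rises.
    """
    if n_members < 1:
        raise DomainError("n_members must be >= 1")
    if not 0.0 <= skill <= 1.0:
        raise DomainError("skill must be in [0, 1]")
    skeleton = _daily_skeleton(spec, target_year - 1, target_year + 1)
    start = pd.Timestamp(year=target_year, month=target_month, day=1)
    end = start + pd.offsets.MonthEnd(0)
    window = skeleton.data.loc[start - pd.Timedelta(days=1): end + pd.Timedelta(days=1)]
    amp = 1.0 - skill
    members: dict[str, DailyMeteoSeries] = {}
    for m in range(n_members):
        if amp == 0.0:  # perfect skill: members are the truth, bit for bit
            members[f"m{m:02d}"] = DailyMeteoSeries(window.copy(), site=spec.site)
            continue
        rng = np.random.default_rng([seed, 3, m])
        n = len(window)
        bias = rng.normal(0.0, 2.5)
        noise = rng.normal(0.0, 2.0, n)
        range_factor = np.exp(rng.normal(0.0, 0.2, n) * amp)
        flip = rng.random(n) < 0.3 * amp
        new_amounts = rng.exponential(spec.mean_wet_day_precip, n)
        precip_factor = np.exp(rng.normal(0.0, 0.5, n) * amp)

        tmean = (window["tmax"] + window["tmin"]) / 2.0 + amp * (bias + noise)
        drange = (window["tmax"] - window["tmin"]) * range_factor
        precip = window["precip"].to_numpy() * precip_factor
        wet = precip > 0
        precip = np.where(flip & wet, 0.0, precip)
        precip = np.where(flip & ~wet, new_amounts, precip)
        df = pd.DataFrame(
            {
                "tmax": tmean + drange / 2.0,
                "tmin": tmean - drange / 2.0,
                "precip": precip,
                "wind_speed": window["wind_speed"].to_numpy()
                * np.exp(rng.normal(0.0, 0.15, n) * amp),
                "pressure": window["pressure"].to_numpy(),
            },
            index=window.index,
        )
        members[f"m{m:02d}"] = DailyMeteoSeries(df, site=spec.site)
    return members


def build_strain_surface(
    arch: StrainArchetype,
    temp_grid=None,
    light_grid=None,
) -> StrainParams:
    """Gridded growth-rate surface from an archetype.

    rate(T, I) = mu_max * exp(-((T - T_opt)/breadth)^2) * f(I) - r_dark,
    with f a saturating light response (optionally photoinhibited) that
    vanishes at I = 0, so the zero-light column is exactly -r_dark.
    """
    if temp_grid is None:
        temp_grid = np.arange(0.0, 40.1, 2.5)
    if light_grid is None:
        light_grid = np.linspace(0.0, 2000.0, 21)
    temp_grid = np.asarray(temp_grid, dtype=float)
    light_grid = np.asarray(light_grid, dtype=float)
    T = temp_grid[:, None]
    I = light_grid[None, :]
    thermal = np.exp(-(((T - arch.optimum_temp) / arch.thermal_breadth) ** 2))
    light_response = I / (I + arch.light_half_saturation)
    if arch.photoinhibition_onset is not None:
        excess = np.maximum(0.0, I - arch.photoinhibition_onset)
        light_response = light_response / (1.0 + excess / arch.photoinhibition_onset)
    surface = arch.max_growth_rate * thermal * light_response - arch.dark_respiration
    return StrainParams(
        name=arch.name,
        temp_grid=temp_grid,
        light_grid=light_grid,
        growth_rate_surface=surface,
        dark_respiration_rate=arch.dark_respiration,
        valid_temp_range=(float(temp_grid[0]), float(temp_grid[-1])),
        out_of_range_behavior="clamp",
    )


def default_strain_registry() -> dict[str, StrainParams]:
    """The two archetype strains keyed by name (warm first)."""
    warm = build_strain_surface(warm_archetype())
    cold = build_strain_surface(cold_archetype())
    return {warm.name: warm, cold.name: cold}
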