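"""Light- and temperature-dependent algal biomass growth and harvesting.

The growth model is deliberately empirical: each strain is described by a
measured net specific growth rate surface over a (water temperature, PAR)
grid — the same quantity a laboratory photobioreactor parameterization
produces — plus a dark respiration rate (the loss rate when PAR is zero).
Rates between grid nodes are bilinearly interpolated.

The pond light climate couples depth to growth: surface PAR is averaged over
the water column with Beer-Lambert attenuation whose extinction coefficient
increases with biomass concentration (self-shading), so deeper or denser
ponds see less light per cell.  Biomass is advanced hourly with exponential
updates; a concentration threshold triggers harvesting back to a residual
concentration, and the month's production is the harvested mass plus the
algae still standing in the pond at month end, expressed per unit pond area.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError
from .meteo import PAR_FRACTION, PAR_QUANTA_PER_JOULE, HourlyMeteoSeries
from .pond import WaterTempSeries


@dataclass
class StrainParams:
    """Growth-rate surface and metadata defining one strain.

    ``growth_rate_surface[i, j]`` is the net specific growth rate (1/day) at
    ``temp_grid[i]`` degC and ``light_grid[j]`` umol/m^2/s.  The first light
    column must equal ``-dark_respiration_rate`` (no light -> respiratory
    loss), which is enforced at construction.  Outside ``valid_temp_range``
    the rate either clamps to the boundary ("clamp") or switches to a
    configured die-off rate ("dieoff").
    """

    name: str
    temp_grid: np.ndarray  # degC, strictly ascending
    light_grid: np.ndarray  # umol/m^2/s, strictly ascending, starts at 0
    growth_rate_surface: np.ndarray  # 1/day, shape (n_temp, n_light)
    dark_respiration_rate: float  # 1/day, >= 0
    valid_temp_range: tuple[float, float] | None = None
    out_of_range_behavior: str = "clamp"  # "clamp" | "dieoff"
    dieoff_rate: float = 0.5  # 1/day loss applied under "dieoff"
    salinity: float | None = None  # PSU, metadata only

    def __post_init__(self):
        self.temp_grid = np.asarray(self.temp_grid, dtype=float)
        self.light_grid = np.asarray(self.light_grid, dtype=float)
        self.growth_rate_surface = np.asarray(self.growth_rate_surface, dtype=float)
        if np.any(np.diff(self.temp_grid) <= 0) or np.any(np.diff(self.light_grid) <= 0):
            raise DataError("parameter grids must be strictly ascending")
        if self.light_grid[0] != 0.0:
            raise DataError("light grid must start at 0")
        if self.growth_rate_surface.shape != (len(self.temp_grid), len(self.light_grid)):
            raise DataError("growth_rate_surface shape does not match grids")
        if not np.all(np.isfinite(self.growth_rate_surface)):
            raise DataError("growth_rate_surface must be finite")
        if self.dark_respiration_rate < 0:
            raise DataError("dark_respiration_rate must be >= 0")
        dark_col = self.growth_rate_surface[:, 0]
        if not np.allclose(dark_col, -self.dark_respiration_rate, atol=1e-6):
            raise DataError(
                "growth rate at zero light must equal -dark_respiration_rate"
            )
        if self.valid_temp_range is None:
            self.valid_temp_range = (float(self.temp_grid[0]), float(self.temp_grid[-1]))
        if self.out_of_range_behavior not in ("clamp", "dieoff"):
            raise DataError("out_of_range_behavior must be 'clamp' or 'dieoff'")
        # cached python lists for the fast scalar interpolation path
        self._tg = self.temp_grid.tolist()
        self._lg = self.light_grid.tolist()
        self._rates = self.growth_rate_surface.tolist()


@dataclass
class HarvestPolicy:
    """Concentration-triggered harvesting rule (g/L)."""

    trigger_conc: float = 0.5
    residual_conc: float = 0.1
    initial_conc: float = 0.05

    def __post_init__(self):
        if not self.residual_conc < self.trigger_conc:
            raise DomainError("residual_conc must be below trigger_conc")
        if self.initial_conc <= 0:
            raise DomainError("initial_conc must be positive")


@dataclass
class LightAttenuation:
    """Beer-Lambert extinction: k = k_w + k_c * concentration (g/L)."""

    background_extinction: float = 0.2  # 1/m, water + non-algal turbidity
    biomass_extinction: float = 50.0  # 1/m per g/L of biomass

    def __post_init__(self):
        if self.background_extinction < 0 or self.biomass_extinction < 0:
            raise DomainError("extinction coefficients must be >= 0")


@dataclass
class MonthlyProduction:
    """Outcome of one month of cultivation for one strategy.

    areal_production is (total harvested + final standing mass) per pond area
    per day of the month, g/m^2/day.
    """

    areal_production: float
    harvest_events: list[tuple[pd.Timestamp, float]]
    final_standing: float  # g/m^2 at month end
    initial_standing: float  # g/m^2 inoculum
    grown_mass: float  # g/m^2, net biological increment over the month
    concentration: pd.Series  # hourly g/L (after any harvest that hour)
    water_temp: pd.Series  # hourly degC, echo of the driving series

    @property
    def harvested_total(self) -> float:
        return sum(h for _, h in self.harvest_events)


def growth_rate(strain: StrainParams, light: float, water_temp: float) -> float:
    """Net specific growth rate (1/day) by bilinear surface interpolation.

    Light outside the grid clamps to the nearest edge; temperature outside
    ``valid_temp_range`` follows the strain's out-of-range behavior.
    """
    if light < 0:
        raise DomainError("light must be >= 0")
    lo, hi = strain.valid_temp_range
    if water_temp < lo or water_temp > hi:
        if strain.out_of_range_behavior == "dieoff":
            return -strain.dieoff_rate
        water_temp = lo if water_temp < lo else hi
    tg, lg, rates = strain._tg, strain._lg, strain._rates
    t = min(max(water_temp, tg[0]), tg[-1])
    l = min(max(light, lg[0]), lg[-1])
    i = min(max(bisect_right(tg, t) - 1, 0), len(tg) - 2)
    j = min(max(bisect_right(lg, l) - 1, 0), len(lg) - 2)
    ft = (t - tg[i]) / (tg[i + 1] - tg[i])
    fl = (l - lg[j]) / (lg[j + 1] - lg[j])
    r00, r01 = rates[i][j], rates[i][j + 1]
    r10, r11 = rates[i + 1][j], rates[i + 1][j + 1]
    return (
        r00 * (1 - ft) * (1 - fl)
        + r10 * ft * (1 - fl)
        + r01 * (1 - ft) * fl
        + r11 * ft * fl
    )


def depth_average_light(
    surface_par: float,
    conc: float,
    depth_cm: float,
    atten: LightAttenuation | None = None,
) -> float:
    """Column-averaged PAR under Beer-Lambert attenuation.

    I_avg = I0 * (1 - exp(-k d)) / (k d) with k = k_w + k_c * C and d in m;
    the transparent limit k d -> 0 returns the surface value.
    """
    atten = atten or LightAttenuation()
    if surface_par < 0 or conc < 0 or depth_cm < 0:
        raise DomainError("inputs must be >= 0")
    k = atten.background_extinction + atten.biomass_extinction * conc
    kd = k * depth_cm / 100.0
    if kd < 1e-12:
        return surface_par
    return surface_par * (1.0 - math.exp(-kd)) / kd


def step_biomass(conc: float, mu: float, dt_h: float) -> float:
    """Exponential biomass update: C' = C * exp(mu * dt/24), mu in 1/day."""
    if conc < 0:
        raise DomainError("concentration must be >= 0")
    return conc * math.exp(mu * dt_h / 24.0)


def apply_harvest(conc: float, depth_cm: float, policy: HarvestPolicy | None = None):
    """Harvest down to the residual concentration when the trigger is reached.

    Returns ``(new_conc, harvested_g_m2)``; the harvested areal mass is
    (C - residual) * depth * 10 with C in g/L and depth in cm.
    """
    policy = policy or HarvestPolicy()
    if conc < 0:
        raise DomainError("concentration must be >= 0")
    if conc >= policy.trigger_conc:
        harvested = (conc - policy.residual_conc) * depth_cm * 10.0
        return policy.residual_conc, harvested
    return conc, 0.0


def _areal(conc: float, depth_cm: float) -> float:
    """g/m^2 standing mass of concentration ``conc`` g/L over ``depth_cm``."""
    return conc * depth_cm * 10.0


def simulate_month(
    met: HourlyMeteoSeries,
    water_temp: WaterTempSeries,
    strain: StrainParams,
    depth_cm: float,
    policy: HarvestPolicy | None = None,
    atten: LightAttenuation | None = None,
    subtract_inoculum: bool = False,
) -> MonthlyProduction:
    """Run one calendar month of hourly growth with harvest accounting.

    Every hour: PAR from shortwave, depth-averaged light at the current
    concentration, growth-rate lookup against pond water temperature,
    exponential biomass update, then a harvest check.  Production is
    (harvested + final standing) areal mass divided by the days in the month
    (the inoculum counts as standing mass unless ``subtract_inoculum``).
    """
    policy = policy or HarvestPolicy()
    atten = atten or LightAttenuation()
    if len(met) != len(water_temp) or not met.index.equals(water_temp.index):
        raise DataError("meteorology and water temperature series are misaligned")
    idx = met.index
    if len(idx) % 24 != 0:
        raise DataError("series must cover whole days")
    n_days = len(idx) // 24
    if idx[0].day != 1 or idx[0].hour != 0 or len({(t.year, t.month) for t in idx[:: 24]}) != 1:
        raise DataError("series must span exactly one full calendar month")
    if pd.Period(f"{idx[0].year}-{idx[0].month:02d}").days_in_month != n_days:
        raise DataError("series does not cover the full calendar month")
    if depth_cm <= 0:
        raise DomainError("depth must be positive")

    sw = met.data["shortwave"].to_numpy().tolist()
    temps = water_temp.temps.to_numpy().tolist()
    k_w = atten.background_extinction
    k_c = atten.biomass_extinction
    d_m = depth_cm / 100.0
    resp = strain.dark_respiration_rate

    par_factor = PAR_FRACTION * PAR_QUANTA_PER_JOULE
    conc = policy.initial_conc
    conc_out = np.empty(len(sw))
    harvest_events: list[tuple[pd.Timestamp, float]] = []
    grown = 0.0
    for i in range(len(sw)):
        par = sw[i] * par_factor
        if par <= 0.0:
            mu = -resp
        else:
            kd = (k_w + k_c * conc) * d_m
            i_avg = par if kd < 1e-12 else par * (1.0 - math.exp(-kd)) / kd
            mu = growth_rate(strain, i_avg, temps[i])
        new_conc = conc * math.exp(mu / 24.0)
        grown += new_conc - conc
        conc = new_conc
        if conc >= policy.trigger_conc:
            harvested = (conc - policy.residual_conc) * depth_cm * 10.0
            harvest_events.append((idx[i], harvested))
            conc = policy.residual_conc
        conc_out[i] = conc

    final_standing = _areal(conc, depth_cm)
    harvested_total = sum(h for _, h in harvest_events)
    total = harvested_total + final_standing
    initial_standing = _areal(policy.initial_conc, depth_cm)
    if subtract_inoculum:
        total -= initial_standing
    return MonthlyProduction(
        areal_production=total / n_days,
        harvest_events=harvest_events,
        final_standing=final_standing,
        initial_standing=initial_standing,
        grown_mass=grown * depth_cm * 10.0,
        concentration=pd.Series(conc_out, index=idx, name="concentration"),
        water_temp=water_temp.temps,
    )


# ---------------------------------------------------------------------------
# Strain parameter files: '#'-prefixed header block, then long-format rows
# (temp_C, light_umol, growth_rate_per_day).

def write_strain_csv(strain: StrainParams, path) -> None:
    path = Path(path)
    lines = [
        f"# name: {strain.name}",
        f"# dark_respiration_per_day: {float(strain.dark_respiration_rate)!r}",
        f"# valid_temp_min: {float(strain.valid_temp_range[0])!r}",
        f"# valid_temp_max: {float(strain.valid_temp_range[1])!r}",
        f"# out_of_range: {strain.out_of_range_behavior}",
        f"# dieoff_rate: {float(strain.dieoff_rate)!r}",
    ]
    if strain.salinity is not None:
        lines.append(f"# salinity_psu: {float(strain.salinity)!r}")
    lines.append("temp_C,light_umol,growth_rate_per_day")
    for i, t in enumerate(strain.temp_grid):
        for j, l in enumerate(strain.light_grid):
            lines.append(
                f"{float(t)!r},{float(l)!r},{float(strain.growth_rate_surface[i, j])!r}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_strain_csv(path) -> StrainParams:
    path = Path(path)
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([\w]+)\s*:\s*(.*)", line)
                if m:
                    header[m.group(1)] = m.group(2).strip()
            else:
                rows.append(line)
    if not rows or rows[0].split(",")[:3] != ["temp_C", "light_umol", "growth_rate_per_day"]:
        raise FormatError(f"{path}: missing temp_C,light_umol,growth_rate_per_day table")
    if "name" not in header or "dark_respiration_per_day" not in header:
        raise FormatError(f"{path}: header must declare name and dark_respiration_per_day")
    df = pd.DataFrame(
        [tuple(float(v) for v in r.split(",")) for r in rows[1:]],
        columns=["temp_C", "light_umol", "growth_rate_per_day"],
    )
    temp_grid = np.array(sorted(df["temp_C"].unique()))
    light_grid = np.array(sorted(df["light_umol"].unique()))
    surface = (
        df.pivot(index="temp_C", columns="light_umol", values="growth_rate_per_day")
        .loc[temp_grid, light_grid]
        .to_numpy()
    )
    if np.isnan(surface).any():
        raise FormatError(f"{path}: growth-rate table is not a complete grid")
    vrange = None
    if "valid_temp_min" in header and "valid_temp_max" in header:
        vrange = (float(header["valid_temp_min"]), float(header["valid_temp_max"]))
    return StrainParams(
        name=header["name"],
        temp_grid=temp_grid,
        light_grid=light_grid,
        growth_rate_surface=surface,
        dark_respiration_rate=float(header["dark_respiration_per_day"]),
        valid_temp_range=vrange,
        out_of_range_behavior=header.get("out_of_range", "clamp"),
        dieoff_rate=float(header.get("dieoff_rate", 0.5)),
        salinity=float(header["salinity_psu"]) if "salinity_psu" in header else None,
    )
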