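"""Strategy enumeration, ensemble forecasting of production, and selection.

A cultivation *strategy* is a (strain, pond depth) pair chosen for one month.
For every ensemble member and every strategy the pond temperature and biomass
growth are simulated; the strategy with the highest ensemble-mean areal
production is selected.  A fixed State-of-Technology (SOT) schedule — 20 cm
depth year-round, cold strain November-March, warm strain otherwise — serves
as the operational baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ensembles import ForecastEnsemble
from .errors import DataError, DomainError
from .growth import HarvestPolicy, LightAttenuation, StrainParams, simulate_month
from .meteo import HourlyMeteoSeries
from .pond import ThermalParams, simulate_pond


@dataclass(frozen=True)
class Strategy:
    """One candidate operating point: strain name and pond depth (cm)."""

    strain: str
    depth_cm: float

    @property
    def label(self) -> str:
        depth = int(self.depth_cm) if float(self.depth_cm).is_integer() else self.depth_cm
        return f"{self.strain}-{depth}"


@dataclass
class StrategyForecastTable:
    """Per-strategy member productions (g/m^2/day) and ensemble statistics."""

    strategies: list[Strategy]
    productions: pd.DataFrame  # index member_ids, one column per strategy label
    target_year: int
    target_month: int
    source: str

    @property
    def ensemble_mean(self) -> pd.Series:
        return self.productions.mean(axis=0)

    @property
    def ensemble_spread(self) -> pd.Series:
        return self.productions.std(axis=0, ddof=0)


@dataclass
class Decision:
    """Selected strategy plus the full forecast table for auditability."""

    selected: Strategy
    table: StrategyForecastTable
    tie_broken: bool = False


def enumerate_strategies(strains, depths_cm) -> list[Strategy]:
    """Cartesian product of strains and depths, strain order x ascending depth."""
    strains = list(strains)
    depths = sorted(depths_cm)
    if not strains or not depths:
        raise DomainError("strains and depths must be nonempty")
    for d in depths:
        if d <= 0:
            raise DomainError("depths must be positive")
    return [Strategy(s, float(d)) for s in strains for d in depths]


def simulate_strategy_production(
    met: HourlyMeteoSeries,
    strategy: Strategy,
    strain_registry: dict[str, StrainParams],
    thermal: ThermalParams | None = None,
    policy: HarvestPolicy | None = None,
    atten: LightAttenuation | None = None,
    initial_water_temp: float = 5.0,
) -> float:
    """Pond + growth simulation for one forcing series and one strategy."""
    if strategy.strain not in strain_registry:
        raise DataError(f"strain {strategy.strain!r} not in registry")
    water = simulate_pond(met, strategy.depth_cm, thermal, initial_water_temp)
    prod = simulate_month(
        met, water, strain_registry[strategy.strain], strategy.depth_cm, policy, atten
    )
    return prod.areal_production


def forecast_strategies(
    ensemble: ForecastEnsemble,
    strategies: list[Strategy],
    thermal: ThermalParams | None = None,
    strain_registry: dict[str, StrainParams] | None = None,
    policy: HarvestPolicy | None = None,
    atten: LightAttenuation | None = None,
    initial_water_temp: float = 5.0,
) -> StrategyForecastTable:
    """Run every ensemble member through every strategy.

    Pond simulations are shared across strategies with the same depth, since
    water temperature does not depend on the strain.
    """
    if strain_registry is None:
        raise DomainError("strain_registry is required")
    missing = {s.strain for s in strategies} - set(strain_registry)
    if missing:
        raise DataError(f"strains missing from registry: {sorted(missing)}")
    depths = sorted({s.depth_cm for s in strategies})
    columns = {s.label: [] for s in strategies}
    for member in ensemble.members:
        water_by_depth = {
            d: simulate_pond(member, d, thermal, initial_water_temp) for d in depths
        }
        for s in strategies:
            prod = simulate_month(
                member,
                water_by_depth[s.depth_cm],
                strain_registry[s.strain],
                s.depth_cm,
                policy,
                atten,
            )
            columns[s.label].append(prod.areal_production)
    table = pd.DataFrame(columns, index=list(ensemble.member_ids))
    return StrategyForecastTable(
        strategies=list(strategies),
        productions=table,
        target_year=ensemble.target_year,
        target_month=ensemble.target_month,
        source=ensemble.source,
    )


def _argmax_strategy(values: pd.Series, strategies: list[Strategy]):
    """Best strategy by value; exact ties resolved by shallower depth then
    position in the strategy list.  Returns (strategy, tie_broken)."""
    best = values.max()
    candidates = [
        (s.depth_cm, i, s)
        for i, s in enumerate(strategies)
        if values[s.label] == best
    ]
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2], len(candidates) > 1


def select_strategy(table: StrategyForecastTable) -> Decision:
    """Pick the strategy maximizing the ensemble-mean production."""
    if not table.strategies:
        raise DataError("empty strategy table")
    selected, tie = _argmax_strategy(table.ensemble_mean, table.strategies)
    return Decision(selected=selected, table=table, tie_broken=tie)


def truth_strategy(
    met: HourlyMeteoSeries,
    strategies: list[Strategy],
    thermal: ThermalParams | None = None,
    strain_registry: dict[str, StrainParams] | None = None,
    policy: HarvestPolicy | None = None,
    atten: LightAttenuation | None = None,
    initial_water_temp: float = 5.0,
):
    """Observation-driven "truth" run: productions and the optimal strategy.

    Uses the same simulator as the forecasts, driven by observed meteorology,
    so truth and forecast differ only in forcing.  Returns
    ``(productions: pd.Series, optimal: Strategy)``.
    """
    if strain_registry is None:
        raise DomainError("strain_registry is required")
    depths = sorted({s.depth_cm for s in strategies})
    water_by_depth = {
        d: simulate_pond(met, d, thermal, initial_water_temp) for d in depths
    }
    values = {}
    for s in strategies:
        prod = simulate_month(
            met, water_by_depth[s.depth_cm], strain_registry[s.strain],
            s.depth_cm, policy, atten,
        )
        values[s.label] = prod.areal_production
    series = pd.Series(values)
    optimal, _ = _argmax_strategy(series, strategies)
    return series, optimal


#: months in which the SOT baseline runs the cold-water strain
SOT_COLD_MONTHS = (11, 12, 1, 2, 3)


def sot_strategy(
    month: int,
    warm_strain: str = "P. celeri",
    cold_strain: str = "T. striata",
    depth_cm: float = 20.0,
) -> Strategy:
    """State-of-Technology baseline: fixed depth, cold strain Nov-Mar."""
    if not 1 <= int(month) == month:
        raise DomainError("month must be an integer in 1..12")
    if not 1 <= month <= 12:
        raise DomainError("month must be in 1..12")
    strain = cold_strain if month in SOT_COLD_MONTHS else warm_strain
    return Strategy(strain, float(depth_cm))
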