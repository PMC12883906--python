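"""End-to-end synthetic validation harness.

Glues the generator, ensemble builder, simulators, decision engine and
verification together: for each validation month a "truth" run driven by the
synthetic archive defines the optimal strategy, forecast members of chosen
skill are turned into an ensemble decision, and selection accuracy is scored.
This is the desk-scale analogue of validating a forecasting system against
observation-driven simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision import (
    Decision,
    Strategy,
    enumerate_strategies,
    forecast_strategies,
    select_strategy,
    truth_strategy,
)
from .ensembles import assemble_model_ensemble, build_climatology_ensemble
from .evaluation import confusion_and_accuracy
from .growth import HarvestPolicy, LightAttenuation, StrainParams
from .meteo import HourlyMeteoSeries
from .pond import ThermalParams
from .synthetic import ClimateSpec, default_strain_registry, generate_archive, \
    generate_forecast_members


@dataclass
class HarnessConfig:
    """Study conditions of the synthetic decision experiment."""

    climate: ClimateSpec = field(default_factory=ClimateSpec)
    strain_registry: dict[str, StrainParams] = field(
        default_factory=default_strain_registry
    )
    depths_cm: tuple = (15.0, 30.0)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    policy: HarvestPolicy = field(default_factory=HarvestPolicy)
    atten: LightAttenuation = field(default_factory=LightAttenuation)
    n_members: int = 6

    @property
    def strategies(self) -> list[Strategy]:
        return enumerate_strategies(self.strain_registry.keys(), self.depths_cm)


@dataclass
class MonthResult:
    year: int
    month: int
    selected: Strategy
    optimal: Strategy
    decision: Decision


@dataclass
class HarnessResult:
    months: list[MonthResult]
    total_accuracy: float
    strain_only_accuracy: float


def _score(months: list[MonthResult]) -> HarnessResult:
    _, total, strain_only = confusion_and_accuracy(
        [m.selected for m in months], [m.optimal for m in months]
    )
    return HarnessResult(months, total, strain_only)


def compute_truth(
    config: HarnessConfig,
    archive: HourlyMeteoSeries,
    year: int,
    months,
) -> dict[int, Strategy]:
    """Observation-driven optimal strategy per month (reusable across seeds)."""
    truth = {}
    for month in months:
        met = archive.slice_month(year, month)
        _, truth[month] = truth_strategy(
            met, config.strategies, config.thermal, config.strain_registry,
            config.policy, config.atten,
        )
    return truth


def run_skill_harness(
    config: HarnessConfig,
    year: int,
    months,
    skill: float,
    seed: int,
    truth_archive: HourlyMeteoSeries | None = None,
    truth: dict[int, Strategy] | None = None,
) -> HarnessResult:
    """Score forecast-informed decisions of a given skill against truth.

    For each month of ``year``: the truth archive (generated from the climate
    spec if not supplied; it must include the year before for diurnal
    continuity) defines the optimal strategy; ``n_members`` forecast members
    of the given skill are assembled into an ensemble whose mean-best
    strategy is the forecast decision.  ``truth`` may carry precomputed
    per-month optima to avoid rerunning the truth simulations.
    """
    months = list(months)
    if truth is None:
        if truth_archive is None:
            truth_archive = generate_archive(config.climate, year - 1, year)
        truth = compute_truth(config, truth_archive, year, months)
    results = []
    for month in months:
        optimal = truth[month]
        members = generate_forecast_members(
            config.climate, year, month, config.n_members, skill,
            seed=int(np.random.default_rng([seed, month]).integers(0, 2**31 - 1)),
        )
        ensemble = assemble_model_ensemble(
            members, year, month, latitude=config.climate.latitude, source="synthetic"
        )
        table = forecast_strategies(
            ensemble, config.strategies, config.thermal, config.strain_registry,
            config.policy, config.atten,
        )
        decision = select_strategy(table)
        results.append(MonthResult(year, month, decision.selected, optimal, decision))
    return _score(results)


def run_climatology_harness(
    config: HarnessConfig,
    archive: HourlyMeteoSeries,
    target_year: int,
    months,
) -> HarnessResult:
    """Score ESP climatology decisions for one target year against truth."""
    results = []
    for month in months:
        truth_met = archive.slice_month(target_year, month)
        _, optimal = truth_strategy(
            truth_met, config.strategies, config.thermal, config.strain_registry,
            config.policy, config.atten,
        )
        ensemble = build_climatology_ensemble(archive, target_year, month)
        table = forecast_strategies(
            ensemble, config.strategies, config.thermal, config.strain_registry,
            config.policy, config.atten,
        )
        decision = select_strategy(table)
        results.append(
            MonthResult(target_year, month, decision.selected, optimal, decision)
        )
    return _score(results)
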