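"""Forecast-informed strategy selection for one target month.

A climatology (ESP-style) ensemble replays the same calendar month from all
prior archive years; every member is run through pond + growth for every
strain x depth strategy, and the strategy with the best ensemble-mean
production is selected.  The truth run (observed-weather simulation) shows
whether the forecast picked the optimum.
"""

from algaecast import (
    ClimateSpec, build_climatology_ensemble, default_strain_registry,
    enumerate_strategies, forecast_strategies, generate_archive,
    select_strategy, sot_strategy, truth_strategy,
)

spec = ClimateSpec(seed=42)
archive = generate_archive(spec, 2014, 2021)
registry = default_strain_registry()
strategies = enumerate_strategies(registry.keys(), [15.0, 20.0, 25.0, 30.0])

target_year, target_month = 2021, 4
ensemble = build_climatology_ensemble(archive, target_year, target_month)
print(f"climatology ensemble for {target_year}-{target_month:02d}: "
      f"{len(ensemble)} members (source years {ensemble.member_ids[0]}..{ensemble.member_ids[-1]})")

table = forecast_strategies(ensemble, strategies, strain_registry=registry)
for label in table.productions.columns:
    print(f"  {label:20s} mean {table.ensemble_mean[label]:6.2f} "
          f"+/- {table.ensemble_spread[label]:5.2f} g/m2/day")

decision = select_strategy(table)
truth_met = archive.slice_month(target_year, target_month)
truth_prod, optimal = truth_strategy(truth_met, strategies, strain_registry=registry)
sot = sot_strategy(target_month, warm_strain="warm_archetype",
                   cold_strain="cold_archetype")
print(f"forecast selects {decision.selected.label}; "
      f"truth optimum is {optimal.label}; fixed baseline would run {sot.label}")
print(f"truth production: selected {truth_prod[decision.selected.label]:.2f} vs "
      f"optimal {truth_prod[optimal.label]:.2f} g/m2/day")
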