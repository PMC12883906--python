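"""One month of biomass growth with harvest accounting, warm vs cold strain.

Hourly PAR is depth-averaged with Beer-Lambert self-shading, the strain's
growth-rate surface is interpolated at (light, water temperature), and any
hour the concentration reaches 0.5 g/L the pond is harvested back to
0.1 g/L.  Production is harvested plus standing biomass per area per day.
"""

from algaecast import (
    ClimateSpec, default_strain_registry, generate_archive, simulate_month,
    simulate_pond,
)

archive = generate_archive(ClimateSpec(seed=42), 2020, 2021)
registry = default_strain_registry()

for month, name in ((1, "January"), (7, "July")):
    met = archive.slice_month(2021, month)
    water = simulate_pond(met, depth_cm=20.0)
    print(f"{name}: water {water.temps.mean():.1f} degC mean")
    for strain_name, strain in registry.items():
        prod = simulate_month(met, water, strain, depth_cm=20.0)
        print(f"  {strain_name:15s}: {prod.areal_production:6.2f} g/m2/day, "
              f"{len(prod.harvest_events)} harvests, "
              f"{prod.harvested_total:6.1f} g/m2 harvested")

print("The warm archetype dominates midsummer and collapses in winter; the "
      "cold archetype does the reverse — the seasonal reversal that makes "
      "strain selection a forecasting problem.")
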