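"""Generate a synthetic hourly weather archive and summarize its climate.

The generator produces multi-year hourly forcing (temperature, dewpoint,
wind, pressure, shortwave, precipitation) with a seasonal cycle, AR(1)
interannual/synoptic anomalies, a diurnal cycle and intermittent
precipitation — everything the pond and growth models need, with no
external data.
"""

from algaecast import ClimateSpec, aggregate_daily, generate_archive

spec = ClimateSpec(seed=42)
archive = generate_archive(spec, 2018, 2021)
print(f"archive: {len(archive)} hourly records, "
      f"{archive.index[0].date()} .. {archive.index[-1].date()}")

temps = archive.data["air_temp"]
for month, name in ((1, "January"), (7, "July")):
    sel = temps[temps.index.month == month]
    print(f"{name:8s} air temp: mean {sel.mean():5.1f} degC, "
          f"range {sel.min():5.1f} .. {sel.max():5.1f}")

daily = aggregate_daily(archive)
wet = (daily.data["precip"] > 0).mean()
print(f"wet days: {100 * wet:.0f}% of days, "
      f"mean wet-day precip {daily.data.loc[daily.data['precip'] > 0, 'precip'].mean():.1f} mm")
print("July should be ~18 degC warmer than January: the seasonal cycle the "
      "strain/depth decision problem is built on.")
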