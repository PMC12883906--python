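"""Published benchmark production tables for an Arizona raceway case study.

These are reported monthly areal productions (g/m^2/day) from a desert
testbed evaluation of forecast-informed cultivation against the fixed
State-of-Technology (SOT) operating rule, used here as inputs for the
production-comparison arithmetic.  ``FY2024_MONTHS`` spans the fiscal year
September 2023 - June 2024 (July/August 2024 had no forecast data).
"""

FY2024_MONTHS = [
    (2023, 9), (2023, 10), (2023, 11), (2023, 12),
    (2024, 1), (2024, 2), (2024, 3), (2024, 4), (2024, 5), (2024, 6),
]

#: SOT baseline: 20 cm year-round, cold strain Nov-Mar, warm strain otherwise
SOT_PRODUCTION = [21.8, 11.9, 10.2, 6.1, 6.0, 10.2, 15.5, 16.6, 24.3, 31.9]

#: climatology-forecast-informed strategy productions, same months
CLIMATOLOGY_PRODUCTION = [23.3, 18.0, 10.5, 6.6, 6.5, 10.7, 16.0, 24.6, 29.5, 32.0]
CLIMATOLOGY_MONTHLY_DIFF_PCT = [7.0, 50.9, 3.2, 8.1, 8.5, 4.2, 3.4, 47.6, 21.7, 0.4]

#: dynamical-forecast-informed (best single model) strategy productions
GEOS_PRODUCTION = [24.2, 18.0, 10.5, 6.6, 6.5, 10.7, 16.0, 24.6, 29.9, 31.4]
GEOS_MONTHLY_DIFF_PCT = [11.0, 50.9, 3.2, 8.1, 8.5, 4.2, 3.4, 47.6, 23.5, -1.3]

#: average production over months where each forecasting method picked a
#: suboptimal strategy: (optimal average, forecast average, reported diff %)
SUBOPTIMAL_MONTH_AVERAGES = {
    "climatology": (30.66, 29.97, -2.2),
    "ccsm4": (31.26, 29.49, -5.7),
    "cfsv2": (31.60, 27.35, -13.4),
    "geos5": (28.95, 27.39, -5.4),
    "mme": (30.71, 29.23, -4.8),
}

#: reported fiscal-year averages and headline gains over the SOT baseline
REPORTED_AVERAGES = {
    "sot": 15.45,
    "climatology": 17.77,
    "geos5": 17.84,
    "climatology_gain_pct": 15.0,
    "geos5_gain_pct": 15.5,
}
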