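"""Physical constants and accounting defaults.

Units are stated next to each constant. "Metric ton" (t) is 10^6 g throughout;
emission factors are areal rates in grams per square meter per year.
"""

#: Square meters per hectare.
M2_PER_HA = 10_000.0

#: Square meters per acre, rounded survey conversion (exact: 4,046.8564).
#: Land-inventory acreages are converted at this rounded figure.
M2_PER_ACRE = 4_047.0

#: Mass of CH4 per mass of C (16/12): converts carbon-basis methane fluxes
#: to methane mass.
CH4_PER_C = 16.0 / 12.0

#: Salinity (psu) above which a marsh is considered saline enough to shut
#: down net methanogenesis.
SALINITY_THRESHOLD_PSU = 18.0

#: Default 100-year global warming potential of non-fossil methane (AR6).
DEFAULT_GWP_CH4 = 27.2

#: Default voluntary-market credit price, $ per metric ton CO2e.
DEFAULT_CREDIT_PRICE = 20.0

#: Default crediting / valuation window (inclusive).
DEFAULT_START_YEAR = 2021
DEFAULT_END_YEAR = 2050

#: Default social-cost-of-methane discount rate, percent.
DEFAULT_DISCOUNT_RATE = 3.0
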