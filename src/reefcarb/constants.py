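"""Physical constants and unit conversions shared across the package.

Molar masses follow CODATA/IUPAC values; outputs that the literature prints
as rounded figures (e.g. 1.25 PgCaCO3 y-1 for 150 TgC y-1) are obtained by
rounding final results, never intermediates.
"""

M_C = 12.011          # g mol-1, carbon
M_CACO3 = 100.0869    # g mol-1, calcium carbonate
M_CO2 = 44.009        # g mol-1, carbon dioxide

#: fixed seawater density used for mol m-3 <-> mol kg-1 conversion (kg m-3)
RHO_SEAWATER = 1026.5

SECONDS_PER_YEAR = 365.25 * 86400.0
SV_TO_M3_PER_YEAR = 1.0e6 * SECONDS_PER_YEAR   # 1 Sverdrup = 1e6 m3 s-1

#: grams of carbon per mole, expressed in Pg (1 Pg = 1e15 g)
PGC_PER_MOLC = M_C * 1e-15

#: GtCO2 released per PgC of carbon (molar-mass ratio 44.009/12.011)
GTCO2_PER_PGC = M_CO2 / M_C

EARTH_RADIUS_M = 6.371e6
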