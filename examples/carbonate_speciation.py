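"""Resolve the seawater CO2 system for a deep-fjord bottle sample.

A discrete water sample carries measured total alkalinity (TA) and
dissolved inorganic carbon (DIC); everything else — total-scale pH, pCO2,
carbonate ion and the aragonite saturation state Omega_arag — is computed
from that pair at in-situ temperature, salinity and pressure.
"""

from coralvar import WaterSample, depth_to_pressure, solve_ph_from_ta_dic

# a 300 m sample: cold, salty, carbon-rich bottom water of a stratified fjord
sample = WaterSample(
    station_id="Ed",
    season="summer",
    temperature=11.4,
    salinity=32.8,
    pressure=depth_to_pressure(300.0),
    ta=2283.0,
    dic=2290.0,
    phosphate=1.5,
    silicate=15.0,
)

state = solve_ph_from_ta_dic(sample)
print(f"pH (total scale)   : {state.ph_total:.4f}")
print(f"pCO2               : {state.pco2:.1f} uatm")
print(f"HCO3-              : {state.hco3:.1f} umol/kg")
print(f"CO3 2-             : {state.co3:.1f} umol/kg")
print(f"Omega aragonite    : {state.omega_arag:.3f}")

# Omega < 1 means bare aragonite is thermodynamically favoured to dissolve:
# this is the corrosive deep water in which the fastest-calcifying corals live.
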