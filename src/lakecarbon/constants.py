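"""Physical constants shared across the package.

All molar masses are in g mol**-1 (IUPAC 2021 standard atomic weights,
rounded to the precision conventional in limnological work).
"""

MOLAR_MASS_C = 12.011
MOLAR_MASS_O2 = 31.998
MOLAR_MASS_CO2 = 44.009

CELSIUS_TO_KELVIN = 273.15

#: Default atmospheric CO2 partial pressure, μatm.
PCO2_ATM_DEFAULT = 380.0

#: O2:CO2 molar conversion (respiratory quotient) used to convert oxygen
#: consumption to carbon respired.
MOLAR_CONVERSION_O2_TO_C = 1.0

#: Shore-distance threshold separating littoral from pelagic stations, m.
LITTORAL_PELAGIC_THRESHOLD_M = 1000.0
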