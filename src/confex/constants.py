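"""Physical constants in the unit system used throughout the package.

Energies are in kcal/mol (entropies in cal/(mol·K)), temperatures in kelvin,
rates in s⁻¹ and concentrations in molar unless a function says otherwise.
"""

#: Gas constant, kcal/(mol·K)
R_KCAL = 1.987204259e-3

#: Gas constant, cal/(mol·K)
R_CAL = 1.987204259

#: Boltzmann constant over Planck constant, K⁻¹·s⁻¹ (Eyring prefactor k_B·T/h)
KB_OVER_H = 2.083661912e10

#: Reference temperature for all rate laws, K (25 °C)
T_REF = 298.15

#: Celsius → Kelvin offset
CELSIUS_OFFSET = 273.15
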