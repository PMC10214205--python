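"""Physical constants (SI, CODATA 2018) and unit helpers."""

KB = 1.380649e-23
"""Boltzmann constant, J/K."""

NA = 6.02214076e23
"""Avogadro constant, 1/mol."""

E_CHARGE = 1.602176634e-19
"""Elementary charge, C."""

EPS0 = 8.8541878128e-12
"""Vacuum permittivity, F/m."""

DEFAULT_TEMPERATURE_K = 298.0
"""Default temperature for thermodynamic conversions, K (room temperature)."""

NM3_TO_M3 = 1e-27
NM_TO_M = 1e-9
UM2_TO_NM2 = 1e6
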