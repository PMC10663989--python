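"""Physical constants and unit helpers (SI unless noted)."""

BOLTZMANN = 1.380649e-23        # J/K
AVOGADRO = 6.02214076e23        # 1/mol
STANDARD_GRAVITY = 9.81         # m/s^2, measurement-site value
ROOM_TEMPERATURE_K = 295.15     # 22 C, the imaging temperature

# unit conversions
UM = 1e-6
UL = 1e-9                       # m^3
ANGSTROM = 1e-10
NM = 1e-9
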