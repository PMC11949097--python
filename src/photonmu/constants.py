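"""Physical constants (CODATA 2018) used throughout the package.

All lengths in cm, energies in MeV, masses in g unless noted.
"""

#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: Electron rest energy, MeV
ELECTRON_REST_MEV = 0.51099895

#: Classical electron radius, cm
R_ELECTRON_CM = 2.8179403262e-13

#: 1 barn in cm^2
BARN_CM2 = 1e-24

#: Thomson cross section, cm^2 (8*pi/3 * r_e^2)
import math as _math

SIGMA_THOMSON_CM2 = 8.0 * _math.pi / 3.0 * R_ELECTRON_CM**2

#: Electron-positron pair production threshold, MeV
PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV
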