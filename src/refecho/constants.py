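"""Physical constants used throughout, in SI units.

All couplings and frequencies inside the package are angular frequencies
(rad s^-1); user-facing tables and reports convert to Hz/kHz/MHz.
"""
import math

from scipy import constants as _const

#: mu_0 / 4 pi  (T m / A)
MU0_OVER_4PI = _const.mu_0 / (4.0 * math.pi)

#: reduced Planck constant (J s)
HBAR = _const.hbar

#: Bohr magneton (J / T)
MU_B = _const.physical_constants["Bohr magneton"][0]

#: free-electron g value (magnitude); nitroxide g anisotropy (~1e-3) is
#: negligible for coupling magnitudes and is not modelled
G_E = 2.00232

#: electron gyromagnetic ratio, rad s^-1 T^-1 (positive sign convention)
GAMMA_E = G_E * MU_B / HBAR

#: proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA)
GAMMA_H = _const.physical_constants["proton gyromag. ratio"][0]

#: proton number density of pure water at ambient density, protons per A^3.
#: Water and water/glycerol mixtures have nearly identical proton
#: concentrations, so this single default covers both matrices.
WATER_PROTON_DENSITY = 0.0668

TWO_PI = 2.0 * math.pi
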