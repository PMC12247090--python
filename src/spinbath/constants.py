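"""Physical constants for dipolar couplings, in interface units.

All couplings cross module boundaries as ordinary (cyclic) frequencies —
MHz for hyperfine quantities, kHz for nuclear-nuclear quantities — and are
converted to angular frequencies in rad/us only inside the Hamiltonian
builder.  The dipolar constants below are derived from CODATA values at
import time rather than hard-coded.
"""

import math

from scipy import constants as _const

_GAMMA_H = _const.physical_constants["proton gyromag. ratio"][0]  # rad s^-1 T^-1
_GAMMA_E = _const.physical_constants["electron gyromag. ratio"][0]  # rad s^-1 T^-1

#: proton-proton dipolar constant, kHz * Angstrom^3 (cyclic frequency)
D_HH_KHZ_A3 = _const.mu_0 / (4 * _const.pi) * _GAMMA_H**2 * _const.hbar \
    * 1e30 / (2 * _const.pi) / 1e3

#: electron-proton dipolar constant, MHz * Angstrom^3 (cyclic frequency)
D_EH_MHZ_A3 = _const.mu_0 / (4 * _const.pi) * _GAMMA_E * _GAMMA_H * _const.hbar \
    * 1e30 / (2 * _const.pi) / 1e6

#: tetrahedral angle, rad
TETRAHEDRAL_ANGLE = math.acos(-1.0 / 3.0)

# Rotational constant of a rigid CH3 rotor, GHz: three protons on a circle of
# radius r_CH * sin(tetrahedral angle) with r_CH = 1.09 Angstrom.
_R_PERP = 1.09e-10 * math.sin(TETRAHEDRAL_ANGLE)
_I_CH3 = 3 * _const.physical_constants["proton mass"][0] * _R_PERP**2
B_CH3_GHZ = _const.hbar**2 / (2 * _I_CH3) / _const.h / 1e9

#: kJ/mol -> GHz conversion for torsional barriers
KJMOL_TO_GHZ = 1e3 / _const.Avogadro / _const.h / 1e9

MHZ_TO_RAD_PER_US = 2 * _const.pi
KHZ_TO_RAD_PER_US = 2 * _const.pi * 1e-3
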