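"""Physical constants and unit conversions shared across the package.

Internal units are fixed package-wide: lengths in nm, times in ns, magnetic
fields in Tesla, angular frequencies in rad/s.  Converters to and from other
unit systems live at the I/O boundary, never inside analysis code.

All fundamental constants are taken from :mod:`scipy.constants` (CODATA).
"""

from __future__ import annotations

import scipy.constants as _sc

#: vacuum permeability, N A^-2
MU0 = _sc.mu_0
#: reduced Planck constant, J s
HBAR = _sc.hbar
#: electron gyromagnetic ratio, rad s^-1 T^-1 (positive magnitude)
GAMMA_E = _sc.physical_constants["electron gyromag. ratio"][0]
#: Boltzmann constant, J K^-1
KB = _sc.k
#: elementary charge, C
E_CHARGE = _sc.e
#: vacuum permittivity, F m^-1
EPS0 = _sc.epsilon_0
#: Avogadro constant, mol^-1
AVOGADRO = _sc.N_A

#: NV zero-field splitting between m_s = 0 and m_s = +-1, Hz
NV_ZERO_FIELD_SPLITTING_HZ = 2.87e9

# unit conversions
NM_PER_M = 1e9
M_PER_NM = 1e-9
NS_PER_S = 1e9
S_PER_NS = 1e-9
ANGSTROM_PER_NM = 10.0

#: number density (nm^-3) of a 1 mM solution: 1 mM = 1 mol m^-3
NM3_DENSITY_PER_MM = AVOGADRO / 1e27


def molar_to_per_nm3(concentration_mM: float) -> float:
    """Convert a concentration in mM to a number density in nm^-3."""
    return concentration_mM * NM3_DENSITY_PER_MM
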