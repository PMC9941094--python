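"""Physical constants and unit conversions.

Internal unit system: lengths in Angstrom, charges in elementary charge e,
potentials in kT/e at ``TEMPERATURE_K``.
"""

import math

from scipy import constants as _sc

TEMPERATURE_K = 298.0

#: thermal energy at TEMPERATURE_K, in eV
KT_EV = _sc.k * TEMPERATURE_K / _sc.e

#: Coulomb prefactor e^2/(4*pi*eps0) expressed in kT*Angstrom/e^2, i.e. the
#: potential (kT/e) of a unit charge at 1 Angstrom in vacuum.
COULOMB_KT_ANG = (_sc.e / (4.0 * math.pi * _sc.epsilon_0 * 1e-10)) / KT_EV


def bjerrum_length(eps: float) -> float:
    """Bjerrum length (Angstrom) in a medium of relative permittivity eps."""
    return COULOMB_KT_ANG / eps


def inverse_debye_length(ionic_strength_M: float, eps: float) -> float:
    """Inverse Debye screening length kappa (1/Angstrom).

    kappa^2 = 8*pi*l_B*n with n the number density of a 1:1 electrolyte at
    the given molar ionic strength.
    """
    if ionic_strength_M < 0:
        raise ValueError("ionic strength must be >= 0")
    n_per_A3 = _sc.N_A * ionic_strength_M * 1e3 / 1e30
    return math.sqrt(8.0 * math.pi * bjerrum_length(eps) * n_per_A3)
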