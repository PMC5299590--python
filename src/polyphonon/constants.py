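"""Physical constants and unit conversions.

Internal unit system: kJ mol^-1 (energy), Å (length), amu (mass), e (charge),
GPa (pressure), K (temperature), cm^-1 (phonon frequency).  Everything that
crosses a unit boundary goes through the factors defined here.
"""

import math

# CODATA 2018
AVOGADRO = 6.02214076e23          # mol^-1
PLANCK_H = 6.62607015e-34         # J s
BOLTZMANN_J = 1.380649e-23        # J K^-1
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm s^-1
ELEMENTARY_CHARGE = 1.602176634e-19  # C
EPSILON_0 = 8.8541878128e-12      # F m^-1

#: Coulomb constant in kJ mol^-1 Å e^-2:  e^2 N_A / (4 pi eps0 * 1 Å) / 1000
COULOMB_KJMOL_ANG = (
    ELEMENTARY_CHARGE**2 * AVOGADRO / (4.0 * math.pi * EPSILON_0 * 1e-10) / 1000.0
)  # = 1389.35457...

#: k_B in kJ mol^-1 K^-1
KB_KJMOL = BOLTZMANN_J * AVOGADRO / 1000.0  # 0.00831446...

#: h*c in kJ mol^-1 per cm^-1  (energy of a mode of wavenumber 1 cm^-1)
HC_KJMOL_CM = PLANCK_H * SPEED_OF_LIGHT_CM * AVOGADRO / 1000.0  # 0.0119627...

#: sqrt(kJ mol^-1 / (Å^2 amu)) -> cm^-1.
#: omega[rad/s] = 1e13 * sqrt(lambda), nu~ = omega / (2 pi c)
FREQ_CM_PER_SQRT = 1.0e13 / (2.0 * math.pi * SPEED_OF_LIGHT_CM)  # 53.0883...

#: kJ mol^-1 Å^-3 -> GPa
KJMOL_ANG3_TO_GPA = 1000.0 / AVOGADRO / 1e-30 / 1e9  # 1.6605390...

#: GPa -> kJ mol^-1 Å^-3 (for P*V terms)
GPA_TO_KJMOL_ANG3 = 1.0 / KJMOL_ANG3_TO_GPA
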