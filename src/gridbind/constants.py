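"""Physical constants and unit helpers.

All energies in the package are in kcal/mol, distances in Å, angles in
radians internally, temperatures in kelvin.
"""

import numpy as np

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: Avogadro's constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Volume per molecule at 1 M standard concentration, in Å^3 (1 L / N_A).
STANDARD_VOLUME_A3 = 1e27 / N_AVOGADRO

#: Conversion factor for harmonic force constants quoted per degree^2
#: into per radian^2 (multiplicative).
DEG2_TO_RAD2 = (180.0 / np.pi) ** 2


def rt(temperature: float) -> float:
    """RT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
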