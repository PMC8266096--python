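"""Unit conventions and conversion constants.

Working units throughout the package:

* length / diameter: micrometers (um)
* pressure: mmHg
* volumetric flow: nl/min
* viscosity: centipoise (cP)
* wall shear stress: dyn/cm^2
* time (simulation): days
* oxygen content: cm^3 O2 (STP)
* growth-factor concentration: dimensionless (scaled to its maximum)

All conversions between these and cgs quantities are funneled through the
constants below so no magic numbers appear in formulas elsewhere.
"""

import math

#: dyn/cm^2 per mmHg
MMHG_TO_DYN_CM2 = 1333.22

#: nl/min per cm^3/s  (1 cm^3 = 1e6 nl, 1 min = 60 s)
CM3_PER_S_TO_NL_PER_MIN = 6.0e7

#: cm per um
UM_TO_CM = 1.0e-4

#: cm^3 per nl
NL_TO_CM3 = 1.0e-6

#: minutes per day
MIN_PER_DAY = 1440.0

#: seconds per minute
S_PER_MIN = 60.0


def poiseuille_resistance(length_um: float, diameter_um: float,
                          viscosity_cp: float) -> float:
    """Hydraulic resistance R = 128 L eta / (pi D^4) of a cylindrical segment.

    Returned in mmHg/(nl/min), so that ``Q [nl/min] = dP [mmHg] / R``.
    """
    if diameter_um <= 0.0:
        raise ValueError("diameter must be positive")
    if length_um <= 0.0:
        raise ValueError("length must be positive")
    length_cm = length_um * UM_TO_CM
    diameter_cm = diameter_um * UM_TO_CM
    visc_poise = viscosity_cp * 1.0e-2
    r_cgs = 128.0 * length_cm * visc_poise / (math.pi * diameter_cm ** 4)
    # dyn s / cm^5  ->  mmHg / (nl/min)
    return r_cgs / (MMHG_TO_DYN_CM2 * CM3_PER_S_TO_NL_PER_MIN)


def wall_shear_stress(diameter_um: float, dp_mmhg: float,
                      length_um: float) -> float:
    """Wall shear stress tau_w = D dP / (4 L) in dyn/cm^2.

    ``dp_mmhg`` is the pressure drop magnitude along the segment.
    """
    return (diameter_um * UM_TO_CM) * abs(dp_mmhg) * MMHG_TO_DYN_CM2 / (
        4.0 * length_um * UM_TO_CM)
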