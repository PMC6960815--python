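"""Physical constants and unit conversions.

All internal energies are expressed in units of kBT at the fixed working
temperature T = 298.15 K.  Lengths are nm, forces pN.  Interface angles are
degrees; internal angle arithmetic is done in radians.
"""

import math

#: working temperature (K); the electrostatic and elastic conversion factors
#: below are only valid at this temperature.
TEMPERATURE_K = 298.15

#: Bjerrum length of water at 298.15 K (nm).
BJERRUM_NM = 0.7

#: Debye length prefactor: kappa^-1 [nm] = DEBYE_COEF_NM / sqrt(I [M]).
DEBYE_COEF_NM = 0.304

#: kBT at 298.15 K expressed in pN nm.
KT_PN_NM = 4.1164

#: 1 kcal/mol in kBT units at 298.15 K.
KCAL_MOL_TO_KT = 1.6878

LN10 = math.log(10.0)


def debye_length_nm(ionic_strength_M: float) -> float:
    """Screening length kappa^-1 in nm for an aqueous 1:1 electrolyte.

    ``ionic_strength_M == 0`` returns ``inf`` (unscreened Coulomb).
    """
    if ionic_strength_M < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength_M == 0:
        return math.inf
    return DEBYE_COEF_NM / math.sqrt(ionic_strength_M)


def kappa_per_nm(ionic_strength_M: float) -> float:
    """Inverse Debye length in nm^-1 (0 for zero ionic strength)."""
    lam = debye_length_nm(ionic_strength_M)
    return 0.0 if math.isinf(lam) else 1.0 / lam


def k_length_to_kt_nm2(k_kcal_mol_A2: float) -> float:
    """Bond-stretching constant kcal mol^-1 A^-2 -> kBT nm^-2."""
    return k_kcal_mol_A2 * KCAL_MOL_TO_KT * 100.0


def k_angle_to_kt_rad2(k_kcal_mol_deg2: float) -> float:
    """Bond-bending constant kcal mol^-1 deg^-2 -> kBT rad^-2."""
    return k_kcal_mol_deg2 * KCAL_MOL_TO_KT * (180.0 / math.pi) ** 2
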