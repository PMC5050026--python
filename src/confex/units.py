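"""Unit conventions and conversion constants.

All simulation modules work in reduced units (kBT = 1 by default, unit
mass, unit length).  Thermodynamic quantities that are compared against
laboratory numbers are expressed in kcal/mol at room temperature via the
constants below.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: Room temperature in Kelvin used for all kcal/mol conversions.
T_ROOM = 298.15

#: RT at room temperature, kcal/mol.
RT_KCAL = R_KCAL * T_ROOM

#: kJ per kcal.
KJ_PER_KCAL = 4.184


def kcal_to_kbt(value_kcal: float, temperature: float = T_ROOM) -> float:
    """Convert an energy in kcal/mol to units of kBT at ``temperature``."""
    return value_kcal / (R_KCAL * temperature)


def kbt_to_kcal(value_kbt: float, temperature: float = T_ROOM) -> float:
    """Convert an energy in kBT at ``temperature`` to kcal/mol."""
    return value_kbt * R_KCAL * temperature
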