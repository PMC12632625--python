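"""Energy units and physical constants.

All thermodynamic bookkeeping in this package is carried out in kJ/mol;
QTAIM inputs arrive in atomic units (often tabulated as au x 10^3) and the
Afonin relation natively yields kcal/mol, so exact conversions between the
four unit systems are provided here.
"""

from __future__ import annotations

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.31446

#: Thermochemical calorie: 1 kcal = 4.184 kJ (exact by definition).
KCAL_TO_KJ = 4.184

#: 1 hartree in kJ/mol.
HARTREE_TO_KJ = 2625.4996

#: Default analysis temperature (25 degC), K.
T_STANDARD = 298.15

# canonical unit names -> factor to kJ/mol
_TO_KJ = {
    "kJ/mol": 1.0,
    "kcal/mol": KCAL_TO_KJ,
    "au": HARTREE_TO_KJ,
    # densities and energy densities are commonly tabulated as au x 10^3
    "au*1e3": HARTREE_TO_KJ / 1e3,
}

_ALIASES = {
    "kj/mol": "kJ/mol",
    "kj": "kJ/mol",
    "kcal/mol": "kcal/mol",
    "kcal": "kcal/mol",
    "au": "au",
    "hartree": "au",
    "au*1e3": "au*1e3",
    "au*1000": "au*1e3",
    "au x 10^3": "au*1e3",
    "mau": "au*1e3",
}


def _canonical(unit: str) -> str:
    key = unit.strip().lower().replace("×", "x")
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(
        f"unknown energy unit {unit!r}; known units: kJ/mol, kcal/mol, au, au*1e3"
    )


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between kJ/mol, kcal/mol, hartree (au) and au x 10^3.

    Conversions use 1 kcal = 4.184 kJ and 1 hartree = 2625.4996 kJ/mol;
    round trips close to machine precision.
    """
    src = _canonical(from_unit)
    dst = _canonical(to_unit)
    return value * _TO_KJ[src] / _TO_KJ[dst]
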