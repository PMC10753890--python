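"""Standard atomic masses and element inference from atom names.

Masses are CODATA/IUPAC standard atomic weights in unified atomic mass
units.  The element of an atom is inferred from its (force-field style)
name: exact matches for common ion and virtual-site names first, then the
leading alphabetic character (H11A -> H, C32 -> C, OW -> O).
"""

from __future__ import annotations

__all__ = ["ATOMIC_MASSES", "atom_mass"]

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
    "K": 39.0983,
    "NA": 22.98976928,
    "CL": 35.45,
    "MG": 24.305,
    "CA": 40.078,
}

#: Mass of one water molecule, used for united single-site water carriers.
WATER_MASS = 18.01528

_SPECIAL_NAMES: dict[str, float] = {
    "CL": ATOMIC_MASSES["CL"],
    "CLA": ATOMIC_MASSES["CL"],
    "K": ATOMIC_MASSES["K"],
    "POT": ATOMIC_MASSES["K"],
    "NA": ATOMIC_MASSES["NA"],
    "SOD": ATOMIC_MASSES["NA"],
    "MG": ATOMIC_MASSES["MG"],
    "CAL": ATOMIC_MASSES["CA"],
    # united-atom water site (one carrier per molecule)
    "MW": WATER_MASS,
    "W": WATER_MASS,
}


def atom_mass(atom_name: str, residue_name: str = "") -> float:
    """Mass in u for an atom, inferred from its name.

    Raises ``KeyError`` naming the atom when no element can be resolved.
    """
    name = atom_name.upper()
    if name in _SPECIAL_NAMES:
        return _SPECIAL_NAMES[name]
    for ch in name:
        if ch.isalpha():
            if ch in ATOMIC_MASSES:
                return ATOMIC_MASSES[ch]
            break
    raise KeyError(f"cannot infer element for atom {atom_name!r} "
                   f"(residue {residue_name!r})")
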