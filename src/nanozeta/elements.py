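"""Bundled element property table for composition-derived descriptors.

The cores in the zeta-potential dataset are metals and metal oxides, so only
the elements that plausibly occur in such formulas are tabulated.  Properties:

- ``atomic_weight``  [g/mol], IUPAC conventional atomic weights.
- ``ionization_kj_mol``  first ionization energy [kJ/mol] (CRC values).
- ``electronegativity``  Pauling scale.
- ``valence_electrons``  group-based valence electron count.
- ``atomic_number``  Z.

Everything that is not oxygen is treated as a "metal" for the purpose of the
metal-atom count; the metalloid Si is included because silica cores are common
in nanomaterial libraries and its atoms are counted the same way.
"""

from __future__ import annotations

from .exceptions import ParseError

#: element -> {atomic_weight, ionization_kj_mol, electronegativity,
#:             valence_electrons, atomic_number}
ELEMENT_PROPERTIES: dict[str, dict[str, float]] = {
    "O":  {"atomic_weight": 15.999,  "ionization_kj_mol": 1313.9, "electronegativity": 3.44, "valence_electrons": 6,  "atomic_number": 8},
    "Mg": {"atomic_weight": 24.305,  "ionization_kj_mol": 737.7,  "electronegativity": 1.31, "valence_electrons": 2,  "atomic_number": 12},
    "Al": {"atomic_weight": 26.982,  "ionization_kj_mol": 577.5,  "electronegativity": 1.61, "valence_electrons": 3,  "atomic_number": 13},
    "Si": {"atomic_weight": 28.085,  "ionization_kj_mol": 786.5,  "electronegativity": 1.90, "valence_electrons": 4,  "atomic_number": 14},
    "Ca": {"atomic_weight": 40.078,  "ionization_kj_mol": 589.8,  "electronegativity": 1.00, "valence_electrons": 2,  "atomic_number": 20},
    "Ti": {"atomic_weight": 47.867,  "ionization_kj_mol": 658.8,  "electronegativity": 1.54, "valence_electrons": 4,  "atomic_number": 22},
    "Mn": {"atomic_weight": 54.938,  "ionization_kj_mol": 717.3,  "electronegativity": 1.55, "valence_electrons": 7,  "atomic_number": 25},
    "Fe": {"atomic_weight": 55.845,  "ionization_kj_mol": 762.5,  "electronegativity": 1.83, "valence_electrons": 8,  "atomic_number": 26},
    "Co": {"atomic_weight": 58.933,  "ionization_kj_mol": 760.4,  "electronegativity": 1.88, "valence_electrons": 9,  "atomic_number": 27},
    "Ni": {"atomic_weight": 58.693,  "ionization_kj_mol": 737.1,  "electronegativity": 1.91, "valence_electrons": 10, "atomic_number": 28},
    "Cu": {"atomic_weight": 63.546,  "ionization_kj_mol": 745.5,  "electronegativity": 1.90, "valence_electrons": 11, "atomic_number": 29},
    "Zn": {"atomic_weight": 65.38,   "ionization_kj_mol": 906.4,  "electronegativity": 1.65, "valence_electrons": 12, "atomic_number": 30},
    "Zr": {"atomic_weight": 91.224,  "ionization_kj_mol": 640.1,  "electronegativity": 1.33, "valence_electrons": 4,  "atomic_number": 40},
    "Mo": {"atomic_weight": 95.95,   "ionization_kj_mol": 684.3,  "electronegativity": 2.16, "valence_electrons": 6,  "atomic_number": 42},
    "Pd": {"atomic_weight": 106.42,  "ionization_kj_mol": 804.4,  "electronegativity": 2.20, "valence_electrons": 10, "atomic_number": 46},
    "Ag": {"atomic_weight": 107.868, "ionization_kj_mol": 731.0,  "electronegativity": 1.93, "valence_electrons": 11, "atomic_number": 47},
    "Sn": {"atomic_weight": 118.710, "ionization_kj_mol": 708.6,  "electronegativity": 1.96, "valence_electrons": 4,  "atomic_number": 50},
    "Ba": {"atomic_weight": 137.327, "ionization_kj_mol": 502.9,  "electronegativity": 0.89, "valence_electrons": 2,  "atomic_number": 56},
    "Ce": {"atomic_weight": 140.116, "ionization_kj_mol": 534.4,  "electronegativity": 1.12, "valence_electrons": 4,  "atomic_number": 58},
    "W":  {"atomic_weight": 183.84,  "ionization_kj_mol": 770.0,  "electronegativity": 2.36, "valence_electrons": 6,  "atomic_number": 74},
    "Pt": {"atomic_weight": 195.084, "ionization_kj_mol": 870.0,  "electronegativity": 2.28, "valence_electrons": 10, "atomic_number": 78},
    "Au": {"atomic_weight": 196.967, "ionization_kj_mol": 890.1,  "electronegativity": 2.54, "valence_electrons": 11, "atomic_number": 79},
}

#: full set of IUPAC element symbols, used to distinguish "unknown element"
#: from "element not in the bundled property table".
KNOWN_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)


def get_property(element: str, prop: str) -> float:
    """Look up one property of one element in the bundled table.

    Raises :class:`ParseError` naming the element and property when either is
    absent, as composition descriptors must never silently default.
    """
    try:
        row = ELEMENT_PROPERTIES[element]
    except KeyError:
        raise ParseError(
            f"element {element!r} is not in the bundled property table"
        ) from None
    try:
        return row[prop]
    except KeyError:
        raise ParseError(
            f"property {prop!r} not tabulated for element {element!r}"
        ) from None
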