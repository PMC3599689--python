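"""Element symbols and the legacy charge-code table.

The atom block of a V2000 connection table identifies atoms by element
symbol.  Besides the periodic table, the format allows a small set of
pseudo-atoms (query atoms, R-groups, lone pairs, deuterium/tritium).
``check_entry`` treats anything outside these sets as a plausibility
warning, never a hard error.
"""

from __future__ import annotations

ELEMENT_SYMBOLS: frozenset[str] = frozenset(
    """
    H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I
    Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt
    Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr
    Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og
    """.split()
)

#: Pseudo-atom symbols the MDL connection-table dialect allows in the atom
#: block: unspecified (*), any (A), heteroatom (Q), atom list (L), lone pair
#: (LP), R-group (R, R#), and the hydrogen isotopes D and T.
PSEUDO_ATOM_SYMBOLS: frozenset[str] = frozenset(
    {"*", "A", "Q", "L", "LP", "R", "R#", "D", "T", "X"}
)

#: Legacy counts-column charge codes (atom-block field ccc).  The code is
#: stored raw on the Atom record; this table is for interpretation-level
#: consumers.  Code 4 marks a doublet radical, not a charge.  ``M  CHG``
#: property lines, when present, supersede these codes.
CHARGE_CODE_TO_CHARGE: dict[int, int | None] = {
    0: 0,      # no charge
    1: 3,      # +3
    2: 2,      # +2
    3: 1,      # +1
    4: None,   # doublet radical
    5: -1,
    6: -2,
    7: -3,
}


def is_known_symbol(symbol: str) -> bool:
    """True if *symbol* is a periodic-table element or an allowed pseudo-atom."""
    return symbol in ELEMENT_SYMBOLS or symbol in PSEUDO_ATOM_SYMBOLS
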