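"""Periodic-table data used for electron counting and nuclear repulsion."""

from __future__ import annotations

_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()

ATOMIC_NUMBER: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}

ANGSTROM_TO_BOHR = 1.8897259886

# 1 hartree in kcal/mol, reporting-layer conversion
HARTREE_TO_KCAL = 627.509


def atomic_number(symbol: str) -> int:
    """Return Z for an element symbol (case-normalized); raise for unknown symbols."""
    sym = symbol.strip().capitalize()
    try:
        return ATOMIC_NUMBER[sym]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
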