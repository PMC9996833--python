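"""Electron-count bookkeeping and the orbital-space partition.

A spin-multiplet state with total spin S is treated as an ensemble over all
S_z components.  N_I = 2S electrons occupy single-electron subspaces (one
spatial orbital each, occupation n = 1/2 per spin); the remaining
N_II = N - N_I electrons are spin-paired.  The paired orbital space splits
into N_II/2 mutually disjoint subspaces, each containing one strongly
occupied orbital and N_g weakly occupied partners, with a per-subspace
(spin-summed) occupancy of exactly 2.

Index convention (1-based in reports, 0-based arrays internally): strongly
occupied block first (1..N_II/2), then the single-electron block
(..N_Omega with N_Omega = N_II/2 + N_I), then the weakly occupied block
(..N_Omega + N_II/2 * N_g), then frozen empty virtuals up to N_B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .elements import ANGSTROM_TO_BOHR, atomic_number

__all__ = [
    "MolecularSystem",
    "PairingScheme",
    "Region",
    "build_system",
    "build_pairing",
    "variably_occupied_orbital_count",
]


class Region(str, Enum):
    """Block membership of an orbital index."""

    STRONG = "omega_II_b"   # strongly occupied paired orbitals, p <= N_II/2
    SINGLE = "omega_I"      # single-electron orbitals, N_II/2 < p <= N_Omega
    WEAK = "omega_a"        # weakly occupied partners, p > N_Omega
    FROZEN = "frozen"       # uncoupled empty virtuals (excluded from the energy)


@dataclass(frozen=True)
class MolecularSystem:
    """Molecular geometry plus the electron counts defining the multiplet.

    Attributes
    ----------
    atoms : list of (symbol, xyz) with coordinates in Angstrom.
    charge : total charge.
    multiplicity : 2S + 1; the highest-multiplicity convention S = N_I/2.
    N : electron count; N_I : single (spin-defining) electrons; N_II : paired.
    E_nuc : nuclear repulsion energy in hartree.
    """

    atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    charge: int
    multiplicity: int
    N: int
    N_I: int
    N_II: int
    E_nuc: float

    @property
    def spin(self) -> float:
        return self.N_I / 2.0

    @property
    def coords_bohr(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float) * ANGSTROM_TO_BOHR

    @property
    def charges(self) -> np.ndarray:
        return np.array([atomic_number(s) for s, _ in self.atoms], dtype=float)


def _nuclear_repulsion(atoms) -> float:
    coords = np.array([xyz for _, xyz in atoms], dtype=float) * ANGSTROM_TO_BOHR
    z = np.array([atomic_number(s) for s, _ in atoms], dtype=float)
    e = 0.0
    for i in range(len(atoms)):
        for j in range(i):
            e += z[i] * z[j] / np.linalg.norm(coords[i] - coords[j])
    return e


def build_system(geometry, charge: int = 0, multiplicity: int = 1) -> MolecularSystem:
    """Build a :class:`MolecularSystem` from an atom list.

    Parameters
    ----------
    geometry : iterable of (element symbol, (x, y, z)) in Angstrom.
    charge, multiplicity : integers; multiplicity = 2S + 1 >= 1.

    Raises
    ------
    ValueError
        For unknown elements, multiplicity < 1, or when N - (multiplicity - 1)
        is negative or odd (no valid number of paired electrons exists).
    """
    atoms = tuple((s, (float(x), float(y), float(z))) for s, (x, y, z) in geometry)
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    n_elec = int(sum(atomic_number(s) for s, _ in atoms)) - int(charge)
    n_single = multiplicity - 1
    n_paired = n_elec - n_single
    if n_paired < 0 or n_paired % 2:
        raise ValueError(
            f"multiplicity {multiplicity} incompatible with {n_elec} electrons: "
            f"N_II = {n_paired} must be even and non-negative"
        )
    return MolecularSystem(
        atoms=atoms,
        charge=int(charge),
        multiplicity=int(multiplicity),
        N=n_elec,
        N_I=n_single,
        N_II=n_paired,
        E_nuc=_nuclear_repulsion(atoms),
    )


@dataclass(frozen=True)
class PairingScheme:
    """Partition of N_B spatial orbitals into pairing subspaces.

    Subspace labels g run 0..N_Omega-1 (0-based): paired subspaces first
    (g < N_II/2), then single-electron subspaces.  ``subspace_of[p] = -1``
    marks frozen virtuals.
    """

    N: int
    N_I: int
    N_II: int
    N_B: int
    N_g: int
    subspace_of: np.ndarray = field(repr=False)  # (N_B,) int, -1 for frozen

    @property
    def n_pairs(self) -> int:
        return self.N_II // 2

    @property
    def N_Omega(self) -> int:
        return self.n_pairs + self.N_I

    @property
    def n_coupled(self) -> int:
        """Orbitals entering the energy: strong + singles + weak."""
        return self.n_pairs * (1 + self.N_g) + self.N_I

    def region_of(self, p: int) -> Region:
        """Block membership of 0-based orbital index ``p``."""
        if p < self.n_pairs:
            return Region.STRONG
        if p < self.N_Omega:
            return Region.SINGLE
        if p < self.n_coupled:
            return Region.WEAK
        return Region.FROZEN

    @property
    def regions(self) -> np.ndarray:
        return np.array([self.region_of(p) for p in range(self.N_B)], dtype=object)

    def members(self, g: int) -> np.ndarray:
        """Orbital indices (0-based) of subspace ``g``."""
        return np.flatnonzero(self.subspace_of == g)


def build_pairing(system: MolecularSystem, N_B: int, coupling="perfect") -> PairingScheme:
    """Assign orbitals to pairing subspaces.

    ``coupling`` is ``"perfect"`` (N_g = 1), ``"extended"`` (the maximum
    uniform N_g the basis allows, floor((N_B - N_Omega)/(N_II/2))), or an
    explicit positive integer.  Strong orbital g takes weak partners
    N_Omega + g*N_g .. N_Omega + (g+1)*N_g - 1 (0-based); leftover orbitals
    are frozen empty.
    """
    n_pairs = system.N_II // 2
    n_omega = n_pairs + system.N_I
    if N_B < n_omega:
        raise ValueError(f"basis too small: N_B={N_B} < N_Omega={n_omega}")
    if coupling == "perfect":
        n_g = 1
    elif coupling == "extended":
        if system.N_II == 0:
            raise ValueError("extended coupling undefined when N_II = 0")
        n_g = (N_B - n_omega) // n_pairs
    else:
        n_g = int(coupling)
    if n_pairs > 0:
        max_ng = (N_B - n_omega) // n_pairs
        if n_g < 1:
            raise ValueError(f"N_g must be >= 1 (basis allows at most {max_ng})")
        if n_g > max_ng:
            raise ValueError(f"N_g={n_g} exceeds the basis-determined maximum {max_ng}")
    else:
        n_g = 1  # no paired subspaces; value is irrelevant
    sub = np.full(N_B, -1, dtype=int)
    for g in range(n_pairs):
        sub[g] = g
        lo = n_omega + g * n_g
        sub[lo : lo + n_g] = g
    for i in range(system.N_I):
        sub[n_pairs + i] = n_pairs + i
    return PairingScheme(
        N=system.N, N_I=system.N_I, N_II=system.N_II, N_B=int(N_B), N_g=n_g, subspace_of=sub
    )


def variably_occupied_orbital_count(scheme: PairingScheme) -> int:
    """Number of orbitals whose occupations are optimization variables.

    Single-electron orbitals carry fixed n = 1/2 and are excluded; the count
    is N_II/2 * (1 + N_g).
    """
    return scheme.n_pairs * (1 + scheme.N_g)
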