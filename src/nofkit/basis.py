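"""Gaussian basis sets: bundled data, shell construction, AO evaluation.

Angular functions are real spherical harmonics (pure functions) throughout:
a shell of angular momentum l contributes 2l+1 atomic orbitals.  Contracted
shells are built from normalized Cartesian primitives; every final AO is
renormalized to unit self-overlap, which makes the bundled contraction
coefficients convention-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .pairing import MolecularSystem

__all__ = ["Shell", "BasisSet", "load_basis", "build_basis", "count_basis_functions"]

_ALIASES = {"sto-3g": "sto-3g", "sto3g": "sto-3g", "minimal": "sto-3g",
            "6-31g": "6-31g", "631g": "6-31g",
            "6-31g*": "6-31g*", "6-31gs": "6-31g*", "dzp": "6-31g*"}
_FILES = {"sto-3g": "sto-3g.json", "6-31g": "6-31g.json", "6-31g*": "6-31gs.json"}


@dataclass(frozen=True)
class Shell:
    """One contracted shell: angular momentum, primitives, center (bohr)."""

    l: int
    exps: np.ndarray
    coefs: np.ndarray  # coefficients w.r.t. normalized Cartesian primitives
    center: np.ndarray
    atom: int

    @property
    def n_sph(self) -> int:
        return 2 * self.l + 1

    @property
    def n_cart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _load_element_table(name: str) -> dict:
    with resources.files("nofkit.data.basis").joinpath(_FILES[name]).open() as fh:
        data = json.load(fh)
    table: dict[str, list] = {}
    if "extends" in data:
        base = _load_element_table(_ALIASES[data["extends"]])
        for el, shells in base.items():
            table[el] = list(shells)
    for el, shells in data["elements"].items():
        table[el] = table.get(el, []) + shells
    return table


class BasisSet:
    """Element -> shell-definition table for a named basis."""

    def __init__(self, name: str, table: dict):
        self.name = name
        self.table = table

    def shells_for(self, element: str):
        el = element.strip().capitalize()
        if el not in self.table:
            raise ValueError(f"basis {self.name!r} has no functions for element {el!r}")
        return self.table[el]


def load_basis(name: str) -> BasisSet:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ValueError(f"unknown basis set: {name!r}")
    canonical = _ALIASES[key]
    return BasisSet(canonical, _load_element_table(canonical))


def build_basis(system: MolecularSystem, basis) -> list[Shell]:
    """Instantiate shells on every atom of ``system``.

    ``basis`` is a basis-set name or a :class:`BasisSet`.
    """
    bset = load_basis(basis) if isinstance(basis, str) else basis
    coords = system.coords_bohr
    shells = []
    for ia, (sym, _) in enumerate(system.atoms):
        for sh in bset.shells_for(sym):
            shells.append(
                Shell(
                    l=int(sh["l"]),
                    exps=np.asarray(sh["exps"], dtype=float),
                    coefs=np.asarray(sh["coefs"], dtype=float),
                    center=coords[ia].copy(),
                    atom=ia,
                )
            )
    return shells


def count_basis_functions(system: MolecularSystem, basis) -> int:
    """Spatial basis dimension N_B with spherical-harmonic angular functions."""
    return sum(sh.n_sph for sh in build_basis(system, basis))


# ---------------------------------------------------------------------------
# Cartesian monomials and real solid harmonics
# ---------------------------------------------------------------------------

def cart_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian (lx, ly, lz) components of a shell, canonical ordering."""
    return [(l - i, i - j, j) for i in range(l + 1) for j in range(i + 1)]


# Monomial expansions of the real solid harmonics, rows m = -l..l, columns in
# cart_components order.  Row scale is arbitrary: every AO is renormalized to
# unit self-overlap downstream.
_SPH_TABLES = {
    0: np.array([[1.0]]),
    # cart order: x, y, z ; rows m=-1(y), 0(z), +1(x)
    1: np.array([
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [1.0, 0.0, 0.0],
    ]),
    # cart order: xx, xy, xz, yy, yz, zz
    2: np.array([
        [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],      # xy
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],      # yz
        [-1.0, 0.0, 0.0, -1.0, 0.0, 2.0],    # 2zz-xx-yy
        [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],      # xz
        [1.0, 0.0, 0.0, -1.0, 0.0, 0.0],     # xx-yy
    ]),
    # cart order: xxx,xxy,xxz,xyy,xyz,xzz,yyy,yyz,yzz,zzz
    3: np.array([
        [0.0, 3.0, 0.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0],   # y(3xx-yy)
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],    # xyz
        [0.0, -1.0, 0.0, 0.0, 0.0, 0.0, -1.0, 0.0, 4.0, 0.0],  # y(4zz-xx-yy)
        [0.0, 0.0, -3.0, 0.0, 0.0, 0.0, 0.0, -3.0, 0.0, 2.0],  # z(2zz-3xx-3yy)
        [-1.0, 0.0, 0.0, -1.0, 0.0, 4.0, 0.0, 0.0, 0.0, 0.0],  # x(4zz-xx-yy)
        [0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0],   # z(xx-yy)
        [1.0, 0.0, 0.0, -3.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # x(xx-3yy)
    ]),
}


def sph_transform(l: int) -> np.ndarray:
    """(2l+1, n_cart) Cartesian-monomial -> real-spherical map, rows m=-l..l."""
    if l not in _SPH_TABLES:
        raise NotImplementedError(f"angular momentum l={l} not supported (max 3)")
    return _SPH_TABLES[l]


def _prim_norm(alpha: float, l: int) -> float:
    """Normalization of an axis-aligned Cartesian primitive x^l exp(-a r^2)."""
    df = 1.0
    for k in range(2 * l - 1, 0, -2):
        df *= k
    return (2 * alpha / np.pi) ** 0.75 * (4 * alpha) ** (l / 2) / np.sqrt(df)


def eval_shell(shell: Shell, points: np.ndarray) -> np.ndarray:
    """Evaluate the spherical AOs of a shell on points, (n_points, 2l+1).

    Same monomial/contraction convention as the integral engine; callers
    apply the engine's per-AO normalization so grids and matrices agree.
    """
    d = points - shell.center
    r2 = np.einsum("ij,ij->i", d, d)
    radial = np.zeros(len(points))
    for a, c in zip(shell.exps, shell.coefs):
        radial += c * _prim_norm(a, shell.l) * np.exp(-a * r2)
    carts = cart_components(shell.l)
    mono = np.stack(
        [d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz for lx, ly, lz in carts], axis=1
    )
    return (mono @ sph_transform(shell.l).T) * radial[:, None]
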