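"""Desk-scale model systems, brute-force oracles, and geometry I/O.

Every test input is generated from internal coordinates — no downloads.
The FCI oracle performs exact diagonalization with the package's own
integrals, providing an implementation-independent reference for the
pair functionals on few-electron systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import solver as sv
from .elements import atomic_number
from .fci import FCIResult, fci_ground_state
from .integrals import compute_ao_integrals
from .pairing import MolecularSystem, build_pairing, build_system
from .scf import run_scf

__all__ = ["Fixture", "make_fixture", "fci_oracle", "dissociation_scan",
           "load_xyz", "load_external_geometry", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("H", "H2", "H4_chain", "LiH", "H2O")


@dataclass
class Fixture:
    """A named desk-scale test system with its default basis."""

    name: str
    system: MolecularSystem
    basis: str
    params: dict = field(default_factory=dict)


def make_fixture(name: str, **params) -> Fixture:
    """Build a named fixture.

    H           — hydrogen atom, doublet (single-electron limit).
    H2          — R in Angstrom (default 0.74), atoms at (0, 0, +-R/2).
    H4_chain    — 4 collinear H at spacing R (default 1.8, statically
                  correlated stretched chain).
    LiH         — R default 1.595.
    H2O         — fixed experimental-like geometry; default basis 6-31g so
                  that every electron pair can carry a weak partner.
    """
    basis = params.pop("basis", None)
    if name == "H":
        system = build_system([("H", (0.0, 0.0, 0.0))], 0, 2)
        basis = basis or "sto-3g"
    elif name == "H2":
        R = float(params.pop("R", 0.74))
        mult = int(params.pop("multiplicity", 1))
        system = build_system([("H", (0.0, 0.0, -R / 2)), ("H", (0.0, 0.0, R / 2))], 0, mult)
        basis = basis or "sto-3g"
        params["R"] = R
    elif name == "H4_chain":
        R = float(params.pop("R", 1.8))
        system = build_system([("H", (0.0, 0.0, i * R)) for i in range(4)], 0, 1)
        basis = basis or "sto-3g"
        params["R"] = R
    elif name == "LiH":
        R = float(params.pop("R", 1.595))
        system = build_system([("Li", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, R))], 0, 1)
        basis = basis or "sto-3g"
        params["R"] = R
    elif name == "H2O":
        system = build_system([("O", (0.0, 0.0, 0.1173)),
                               ("H", (0.0, 0.7572, -0.4692)),
                               ("H", (0.0, -0.7572, -0.4692))], 0, 1)
        basis = basis or "6-31g"
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return Fixture(name=name, system=system, basis=basis, params=params)


def fci_oracle(fixture: Fixture, n_max_det: int = 20_000) -> FCIResult:
    """Exact ground state of a fixture by full diagonalization.

    Runs in the mean-field MO basis of the fixture's own basis set; refuses
    determinant spaces beyond ``n_max_det``.
    """
    system = fixture.system
    ao = compute_ao_integrals(system, fixture.basis)
    scf = run_scf(system, ao)
    C = scf.C
    h = C.T @ ao.Hcore @ C
    eri = np.einsum("ijkl,ip,jq,kr,ls->pqrs", ao.eri, C, C, C, C, optimize=True)
    n_beta = system.N_II // 2
    n_alpha = n_beta + system.N_I
    return fci_ground_state(h, eri, n_alpha, n_beta, ao.E_nuc, n_max_det=n_max_det)


def fragment_populations(state) -> np.ndarray:
    """Mulliken electron populations per atom from the NOF 1RDM."""
    D = (state.C * (2.0 * state.occ.n)) @ state.C.T
    PS = D @ state.ao.S
    pops = np.zeros(len(state.system.atoms))
    off = 0
    for sh in state.ao.shells:
        for _ in range(sh.n_sph):
            pops[sh.atom] += PS[off, off]
            off += 1
    return pops


def dissociation_scan(name: str, R_grid, functional: str = "PNOF5",
                      coupling="perfect", basis: str | None = None,
                      options: sv.SolverOptions | None = None) -> dict:
    """Scan a bond-length grid with warm starts along the grid.

    Returns {"R": ..., "E": ..., "converged": ..., "fragment_populations":
    per-atom electron counts at the largest R}.  Non-converged points are
    flagged and the scan continues.
    """
    R_grid = np.sort(np.asarray(R_grid, dtype=float))
    energies, conv = [], []
    prev = None
    last_state = None
    for R in R_grid:
        fx = make_fixture(name, R=R, **({"basis": basis} if basis else {}))
        ao = compute_ao_integrals(fx.system, fx.basis)
        scheme = build_pairing(fx.system, ao.N_B, coupling)
        start = "hf_guess" if prev is None else prev
        try:
            st = sv.solve(fx.system, ao, scheme, functional, start=start, options=options)
        except Exception as exc:  # keep scanning
            warnings.warn(f"scan point R={R} failed: {exc}")
            energies.append(np.nan)
            conv.append(False)
            continue
        energies.append(st.energy.E_total)
        conv.append(st.converged)
        prev, last_state = st, st
    return {
        "R": R_grid,
        "E": np.array(energies),
        "converged": np.array(conv, dtype=bool),
        "fragment_populations": fragment_populations(last_state) if last_state else None,
    }


# ---------------------------------------------------------------------------
# geometry files
# ---------------------------------------------------------------------------

def load_xyz(path) -> list:
    """Read an XYZ file (with or without the 2-line header), Angstrom."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    start = 0
    if lines and lines[0].split()[0].isdigit():
        start = 2 if len(lines) > 1 else 1
    geom = []
    for ln in lines[start:]:
        t = ln.split()
        if len(t) < 4:
            raise ValueError(f"malformed XYZ line: {ln!r}")
        atomic_number(t[0])  # validates the symbol
        geom.append((t[0], (float(t[1]), float(t[2]), float(t[3]))))
    return geom

# printed Fe-N distances of the reference iron(II)-porphyrin structures (Angstrom)
FEP_FE_N = {1: 1.979, 3: 1.976, 5: 2.053}


def load_external_geometry(path, kind: str | None = None,
                           multiplicity: int | None = None) -> list:
    """Load a user-supplied geometry; sanity-check FeP structures.

    With ``kind="FeP"`` the geometry is checked against the iron(II)
    porphyrin fingerprints (37 atoms, 186 electrons for the neutral
    molecule, and the per-multiplicity Fe-N distance +-0.01 A); failures
    warn rather than raise.
    """
    geom = load_xyz(path)
    if kind == "FeP":
        syms = [s for s, _ in geom]
        if len(geom) != 37:
            warnings.warn(f"FeP check: expected 37 atoms, found {len(geom)}")
        n_elec = sum(atomic_number(s) for s in syms)
        if n_elec != 186:
            warnings.warn(f"FeP check: expected 186 electrons, found {n_elec}")
        if "Fe" in syms and multiplicity in FEP_FE_N:
            fe = np.array(next(x for s, x in geom if s == "Fe"))
            d_fe_n = sorted(np.linalg.norm(np.array(x) - fe)
                            for s, x in geom if s == "N")[:4]
            ref = FEP_FE_N[multiplicity]
            if d_fe_n and abs(np.mean(d_fe_n) - ref) > 0.01:
                warnings.warn(
                    f"FeP check: mean Fe-N distance {np.mean(d_fe_n):.3f} A differs "
                    f"from the reference {ref:.3f} A for multiplicity {multiplicity}")
    return geom
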