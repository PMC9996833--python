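"""Solution characterization: M diagnostic, 1RDM checks, spin-gap tables,
natural-orbital export.

The M diagnostic classifies a converged NOF solution by its extremal
occupations: the least strongly occupied NO (LSONO, the orbital below
N_II/2 with occupation farthest from 1) and the least weakly occupied NO
(LWONO, the orbital above N_Omega with occupation farthest from 0),

    M = (1 - n_LSONO) + n_LWONO        (per-spin occupations)

M = 0 at integer occupations; M = 1.00 for a perfect-pairing diradical
(both extremal occupations 1/2).  Values beyond ~0.1 signal dominant
static correlation; values near zero, dominant dynamic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import eval_shell
from .elements import HARTREE_TO_KCAL
from .functional import OccupationState

__all__ = ["MDiagnosticReport", "m_diagnostic", "gap_table", "trace_check",
           "write_molden", "read_molden", "write_cube"]

STATIC_THRESHOLD = 0.1


@dataclass
class MDiagnosticReport:
    M: float
    lsono_index: int      # 1-based orbital index
    lwono_index: int      # 1-based
    lsono_occ: float
    lwono_occ: float
    regime: str           # "dynamic-dominated" | "static-dominated"
    threshold: float


def m_diagnostic(state_or_occ, threshold: float = STATIC_THRESHOLD) -> MDiagnosticReport:
    """Evaluate the M diagnostic; raises for systems without a paired block."""
    occ: OccupationState = getattr(state_or_occ, "occ", state_or_occ)
    s = occ.scheme
    if s.N_II == 0:
        raise ValueError("M diagnostic undefined: no paired-electron subspaces (N_II = 0)")
    strong = np.arange(0, s.n_pairs)
    above = np.arange(s.N_Omega, s.N_B)
    lson = strong[np.argmin(occ.n[strong])]       # farthest from 1; ties -> lowest index
    lwon = above[np.argmax(occ.n[above])]         # farthest from 0; ties -> lowest index
    m = float((1.0 - occ.n[lson]) + occ.n[lwon])
    regime = "static-dominated" if m >= threshold else "dynamic-dominated"
    return MDiagnosticReport(M=m, lsono_index=int(lson) + 1, lwono_index=int(lwon) + 1,
                             lsono_occ=float(occ.n[lson]), lwono_occ=float(occ.n[lwon]),
                             regime=regime, threshold=threshold)


def gap_table(states, reference_multiplicity: int = 3) -> pd.DataFrame:
    """Adiabatic spin-gap table from one state per multiplicity.

    Gaps are E(multiplicity) - E(reference) in kcal/mol; with the triplet as
    reference, positive ST/QT gaps mean the triplet lies lower.
    """
    by_mult = {}
    for st in states:
        by_mult[st.system.multiplicity] = st
    if reference_multiplicity not in by_mult:
        raise ValueError(f"missing reference state (multiplicity {reference_multiplicity})")
    e_ref = by_mult[reference_multiplicity].energy.E_total
    rows = []
    for mult in sorted(by_mult):
        st = by_mult[mult]
        e = st.energy.E_total
        rows.append({
            "multiplicity": mult,
            "E_total_hartree": e,
            "gap_kcal": (e - e_ref) * HARTREE_TO_KCAL,
            "converged": st.converged,
        })
    return pd.DataFrame(rows).set_index("multiplicity")


def trace_check(state_or_occ, tol: float = 1e-10) -> dict:
    """Verify the 1RDM trace equals the electron count."""
    occ: OccupationState = getattr(state_or_occ, "occ", state_or_occ)
    trace = occ.trace_electrons()
    dev = abs(trace - occ.scheme.N)
    return {"trace": trace, "N": occ.scheme.N, "deviation": dev, "pass": bool(dev < tol)}


# ---------------------------------------------------------------------------
# orbital export
# ---------------------------------------------------------------------------

# our in-memory spherical order is m = -l..l; molden wants these orders
_MOLDEN_ORDER = {0: [0], 1: [2, 0, 1], 2: [2, 3, 1, 4, 0], 3: [3, 4, 2, 5, 1, 6, 0]}
_SHELL_CHAR = {0: "s", 1: "p", 2: "d", 3: "f"}


def _molden_permutation(shells):
    perm = []
    off = 0
    for sh in shells:
        perm.extend(off + np.array(_MOLDEN_ORDER[sh.l]))
        off += sh.n_sph
    return np.array(perm)


def write_molden(path, state, selection="all") -> list[int]:
    """Write natural orbitals with occupations to a molden file.

    ``selection``: "all", "frontier" (the strongly occupied and single
    blocks plus the first weak block), or an explicit list of 1-based
    indices.  Occupations are written spin-summed (2 n_p).  Returns the
    1-based indices written.
    """
    s = state.scheme
    if selection == "all":
        idx = list(range(s.N_B))
    elif selection == "frontier":
        idx = list(range(0, min(s.N_Omega + s.n_pairs, s.N_B)))
    else:
        idx = [int(i) - 1 for i in selection]
    ao = state.ao
    perm = _molden_permutation(ao.shells)
    # coefficients over unit-normalized spherical AOs, molden component order
    C = state.C[perm, :]
    lines = ["[Molden Format]", "[Title]", "nofkit natural orbitals", "[Atoms] Angs"]
    for ia, (sym, xyz) in enumerate(state.system.atoms):
        from .elements import atomic_number
        lines.append(f"{sym} {ia + 1} {atomic_number(sym)} "
                     f"{xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    lines.append("[GTO]")
    by_atom = {}
    for sh in ao.shells:
        by_atom.setdefault(sh.atom, []).append(sh)
    for ia in range(len(state.system.atoms)):
        lines.append(f"{ia + 1} 0")
        for sh in by_atom.get(ia, []):
            lines.append(f"{_SHELL_CHAR[sh.l]} {len(sh.exps)} 1.00")
            for a, c in zip(sh.exps, sh.coefs):
                lines.append(f"  {a: .10e} {c: .10e}")
        lines.append("")
    lines.append("[5D]")
    lines.append("[7F]")
    lines.append("[MO]")
    for p in idx:
        lines.append(" Sym= A")
        lines.append(f" Ene= {0.0:.6f}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {2.0 * state.occ.n[p]:.10f}")
        for mu in range(ao.N_B):
            lines.append(f" {mu + 1:4d} {C[mu, p]: .12e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return [i + 1 for i in idx]


def read_molden(path):
    """Read back a molden file written by :func:`write_molden`.

    Returns (C, occupations_spin_summed) with columns in file order and AO
    rows in nofkit order.
    """
    with open(path) as fh:
        text = fh.read()
    mo_part = text.split("[MO]")[1]
    cols, occs = [], []
    cur = {}
    coeffs = []
    for line in mo_part.splitlines():
        t = line.split()
        if not t:
            continue
        if t[0].startswith("Sym=") or t[0].startswith("Ene=") or t[0].startswith("Spin="):
            continue
        if t[0].startswith("Occup="):
            if coeffs:
                cols.append(coeffs)
                coeffs = []
            occs.append(float(t[-1]))
        else:
            coeffs.append(float(t[1]))
    if coeffs:
        cols.append(coeffs)
    C = np.array(cols).T
    return C, np.array(occs)


def invert_molden_order(C_molden, shells):
    perm = _molden_permutation(shells)
    C = np.empty_like(C_molden)
    C[perm, :] = C_molden
    return C


def write_cube(path, state, orbital: int, n_points: int = 40, margin: float = 4.0):
    """Write one natural orbital (1-based index) on a regular grid as a
    Gaussian cube file; returns the grid integral of |NO|^2."""
    from .elements import ANGSTROM_TO_BOHR, atomic_number
    p = orbital - 1
    coords = state.system.coords_bohr
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    steps = (hi - lo) / (n_points - 1)
    xs = [np.linspace(lo[d], hi[d], n_points) for d in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    ao_vals = []
    for sh in state.ao.shells:
        ao_vals.append(eval_shell(sh, pts))
    A = np.concatenate(ao_vals, axis=1) * state.ao.ao_norms[None, :]
    vals = A @ state.C[:, p]
    with open(path, "w") as fh:
        fh.write("nofkit natural orbital cube\n")
        fh.write(f"orbital {orbital} occupation {2 * state.occ.n[p]:.6f}\n")
        natoms = len(state.system.atoms)
        fh.write(f"{natoms:5d} {lo[0]:12.6f} {lo[1]:12.6f} {lo[2]:12.6f}\n")
        for d in range(3):
            v = [0.0, 0.0, 0.0]
            v[d] = steps[d]
            fh.write(f"{n_points:5d} {v[0]:12.6f} {v[1]:12.6f} {v[2]:12.6f}\n")
        for ia, (sym, _) in enumerate(state.system.atoms):
            z = atomic_number(sym)
            c = coords[ia]
            fh.write(f"{z:5d} {float(z):12.6f} {c[0]:12.6f} {c[1]:12.6f} {c[2]:12.6f}\n")
        grid = vals.reshape(n_points, n_points, n_points)
        for i in range(n_points):
            for j in range(n_points):
                row = grid[i, j]
                for k0 in range(0, n_points, 6):
                    fh.write("".join(f"{v:13.5e}" for v in row[k0:k0 + 6]) + "\n")
    dv = steps.prod()
    return float((vals ** 2).sum() * dv)
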