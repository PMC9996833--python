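"""Spin-restricted mean-field solver used to seed the NOF optimization.

Closed shells get standard RHF; open shells use the spin-averaged
("half-electron") Fock operator, which is adequate for a starting guess —
the NOF solver re-optimizes both orbitals and occupations afterwards.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .integrals import AOIntegrals
from .pairing import MolecularSystem

__all__ = ["run_scf", "SCFResult"]


class SCFResult:
    def __init__(self, C, energies, E, converged, n_iter):
        self.C = C                  # AO->MO coefficients, S-orthonormal columns
        self.orbital_energies = energies
        self.E = E                  # total energy (hartree)
        self.converged = converged
        self.n_iter = n_iter


def _jk(ao: AOIntegrals, D: np.ndarray):
    if ao.ri:
        X = np.einsum("ijP,ij->P", ao.B, D, optimize=True)
        J = np.einsum("ijP,P->ij", ao.B, X, optimize=True)
        half = np.einsum("ikP,kj->ijP", ao.B, D, optimize=True)
        K = np.einsum("ijP,jkP->ik", half, ao.B, optimize=True)
    else:
        J = np.einsum("ijkl,lk->ij", ao.eri, D, optimize=True)
        K = np.einsum("ikjl,lk->ij", ao.eri, D, optimize=True)
    return J, K


def run_scf(system: MolecularSystem, ao: AOIntegrals,
            max_iter: int = 200, conv: float = 1e-10) -> SCFResult:
    """Converge the mean-field problem; returns S-orthonormal orbitals."""
    n_docc = system.N_II // 2
    n_socc = system.N_I
    occ = np.zeros(ao.N_B)
    occ[:n_docc] = 2.0
    occ[n_docc:n_docc + n_socc] = 1.0

    w, U = np.linalg.eigh(ao.S)
    X = U @ np.diag(w ** -0.5) @ U.T  # symmetric orthogonalizer

    n_occ = n_docc + n_socc

    def scf_energy(D):
        J, K = _jk(ao, D)
        return np.einsum("ij,ij->", D, ao.Hcore) \
            + 0.5 * np.einsum("ij,ij->", D, J - 0.5 * K) + ao.E_nuc

    def resolve_degenerate(C, eps):
        """Occupied-virtual degeneracies (e.g. separated fragments) make the
        aufbau choice ambiguous and can trap the iteration in a high-energy
        localized solution; pick the degenerate-pair rotation of lowest
        mean-field energy."""
        for i in range(n_occ):
            for a in range(n_occ, ao.N_B):
                if abs(eps[i] - eps[a]) > 1e-9:
                    continue
                best, best_e = None, np.inf
                for th in (0.0, np.pi / 4, -np.pi / 4):
                    Ct = C.copy()
                    ci, ca = C[:, i].copy(), C[:, a].copy()
                    Ct[:, i] = np.cos(th) * ci + np.sin(th) * ca
                    Ct[:, a] = -np.sin(th) * ci + np.cos(th) * ca
                    e = scf_energy((Ct * occ) @ Ct.T)
                    if e < best_e - 1e-12:
                        best, best_e = Ct, e
                if best is not None:
                    C = best
        return C

    F = ao.Hcore.copy()
    E_old, C = 0.0, None
    diis_F, diis_R = [], []
    converged = False
    for it in range(1, max_iter + 1):
        Fp = X @ F @ X
        eps, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        C = resolve_degenerate(C, eps)
        D = (C * occ) @ C.T
        J, K = _jk(ao, D)
        F = ao.Hcore + J - 0.5 * K
        E = 0.5 * np.einsum("ij,ij->", D, ao.Hcore + F) + ao.E_nuc
        # DIIS on the orthogonalized residual FDS - SDF
        R = X.T @ (F @ D @ ao.S - ao.S @ D @ F) @ X
        diis_F.append(F.copy())
        diis_R.append(R)
        if len(diis_F) > 8:
            diis_F.pop(0), diis_R.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            Bm = -np.ones((m + 1, m + 1)); Bm[-1, -1] = 0.0
            for i in range(m):
                for j in range(m):
                    Bm[i, j] = np.einsum("ij,ij->", diis_R[i], diis_R[j])
            rhs = np.zeros(m + 1); rhs[-1] = -1.0
            c = scipy.linalg.lstsq(Bm, rhs, lapack_driver="gelsd")[0][:m]
            if np.isfinite(c).all():
                F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
        if abs(E - E_old) < conv and np.abs(R).max() < 1e-7:
            converged = True
            break
        E_old = E
    return SCFResult(C=C, energies=eps, E=E, converged=converged, n_iter=it)
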