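"""Determinant full configuration interaction.

Exact diagonalization in a given orthonormal orbital basis, used as the
validation oracle for the pair functionals on few-electron systems.  Dense
Slater-Condon construction; intended for small determinant spaces only
(a few thousand determinants).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.linalg

__all__ = ["fci_ground_state", "FCIResult"]


class FCIResult:
    def __init__(self, E, civec, rdm1, natural_occupations, natural_orbitals, n_det):
        self.E = E                                  # total energy (hartree)
        self.civec = civec
        self.rdm1 = rdm1                            # spin-summed, MO basis
        self.natural_occupations = natural_occupations  # per spatial orbital, sums to N
        self.natural_orbitals = natural_orbitals        # columns, MO->NO
        self.n_det = n_det


def _excitation(det1: tuple, det2: tuple):
    """(degree, holes, particles) between two same-spin determinants."""
    s1, s2 = set(det1), set(det2)
    holes = sorted(s1 - s2)
    parts = sorted(s2 - s1)
    return len(holes), holes, parts


def _perm_sign(det: tuple, removed, added) -> float:
    """Sign of bringing det2 into maximal alignment with det1 (single/double)."""
    det = list(det)
    sign = 1.0
    for h, p in zip(removed, added):
        i = det.index(h)
        det[i] = p
        # count occupied orbitals strictly between h and p
        lo, hi = (h, p) if h < p else (p, h)
        n_between = sum(1 for x in det if lo < x < hi and x != p)
        sign *= (-1.0) ** n_between
    return sign


def fci_ground_state(h: np.ndarray, eri: np.ndarray, n_alpha: int, n_beta: int,
                     e_nuc: float = 0.0, n_max_det: int = 200_000) -> FCIResult:
    """Ground state by exact diagonalization.

    Parameters
    ----------
    h, eri : one-electron matrix and chemists'-notation (pq|rs) tensor in an
        orthonormal spatial-orbital basis.
    n_alpha, n_beta : electrons per spin; the S_z sector is fixed by these.
    """
    n_orb = h.shape[0]
    alphas = list(combinations(range(n_orb), n_alpha))
    betas = list(combinations(range(n_orb), n_beta))
    dets = [(a, b) for a in alphas for b in betas]
    n_det = len(dets)
    if n_det > n_max_det:
        raise ValueError(f"FCI space too large: {n_det} determinants")

    def one_spin_matrix_elem(d1, d2, dother):
        """Same-spin excitation with the other spin string fixed."""
        deg, holes, parts = _excitation(d1, d2)
        if deg > 2:
            return 0.0
        if deg == 0:
            val = sum(h[i, i] for i in d1)
            val += 0.5 * sum(eri[i, i, j, j] - eri[i, j, j, i] for i in d1 for j in d1)
            val += sum(eri[i, i, j, j] for i in d1 for j in dother)
            return val
        if deg == 1:
            (i,), (a,) = holes, parts
            sign = _perm_sign(d1, holes, parts)
            val = h[i, a]
            val += sum(eri[i, a, j, j] - eri[i, j, j, a] for j in d1 if j != i)
            val += sum(eri[i, a, j, j] for j in dother)
            return sign * val
        (i, j), (a, b) = holes, parts
        sign = _perm_sign(d1, holes, parts)
        return sign * (eri[i, a, j, b] - eri[i, b, j, a])

    def opposite_spin_double(da1, da2, db1, db2):
        dega, ha, pa = _excitation(da1, da2)
        degb, hb, pb = _excitation(db1, db2)
        if dega != 1 or degb != 1:
            return 0.0
        sa = _perm_sign(da1, ha, pa)
        sb = _perm_sign(db1, hb, pb)
        return sa * sb * eri[ha[0], pa[0], hb[0], pb[0]]

    H = np.zeros((n_det, n_det))
    for I, (a1, b1) in enumerate(dets):
        for Jd in range(I, n_det):
            a2, b2 = dets[Jd]
            dega = _excitation(a1, a2)[0]
            degb = _excitation(b1, b2)[0]
            if dega + degb > 2:
                continue
            if degb == 0 and dega == 0:
                val = one_spin_matrix_elem(a1, a2, b1)
                # subtract double-counted alpha-beta Coulomb (added in both spin calls)
                val += one_spin_matrix_elem(b1, b2, a1)
                val -= sum(eri[i, i, j, j] for i in a1 for j in b1)
            elif degb == 0:
                val = one_spin_matrix_elem(a1, a2, b1)
            elif dega == 0:
                val = one_spin_matrix_elem(b1, b2, a1)
            else:
                val = opposite_spin_double(a1, a2, b1, b2)
            H[I, Jd] = H[Jd, I] = val

    w, v = scipy.linalg.eigh(H)
    E0 = w[0] + e_nuc
    c0 = v[:, 0]

    # spin-summed one-particle RDM
    rdm = np.zeros((n_orb, n_orb))
    for I, (a1, b1) in enumerate(dets):
        if abs(c0[I]) < 1e-14:
            continue
        for Jd, (a2, b2) in enumerate(dets):
            dega, ha, pa = _excitation(a1, a2)
            degb, hb, pb = _excitation(b1, b2)
            if dega + degb > 1:
                continue
            cc = c0[I] * c0[Jd]
            if dega == 0 and degb == 0:
                for i in a1:
                    rdm[i, i] += cc
                for i in b1:
                    rdm[i, i] += cc
            elif degb == 0:
                rdm[ha[0], pa[0]] += cc * _perm_sign(a1, ha, pa)
            else:
                rdm[hb[0], pb[0]] += cc * _perm_sign(b1, hb, pb)
    rdm = 0.5 * (rdm + rdm.T)
    occ, U = np.linalg.eigh(rdm)
    order = np.argsort(occ)[::-1]
    return FCIResult(E=E0, civec=c0, rdm1=rdm,
                     natural_occupations=occ[order], natural_orbitals=U[:, order],
                     n_det=n_det)
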