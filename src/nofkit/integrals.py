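"""AO integrals, the resolution-of-the-identity path, and NO-basis transforms.

The natural-orbital functionals depend on the one-electron matrix and on
three two-index integral families over natural orbitals p, q:

* Coulomb            J_pq = <pq|pq> = (pp|qq)
* exchange           K_pq = <pq|qp> = (pq|qp)
* exchange-time-inversion  L_pq = <pp|qq> = (pq|pq)

For real orbitals L = K elementwise; the complex-orbital path is typed but
not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .basis import Shell, build_basis, load_basis
from .pairing import MolecularSystem, PairingScheme

__all__ = ["AOIntegrals", "NOIntegrals", "compute_ao_integrals", "transform_to_no_basis",
           "auto_auxiliary"]


@dataclass
class AOIntegrals:
    """AO-basis integrals.  ``eri`` is the full 4-index tensor, or None when
    only the RI factorization ``B`` (N_B, N_B, n_aux; metric included) is kept."""

    S: np.ndarray
    Hcore: np.ndarray
    eri: np.ndarray | None
    B: np.ndarray | None
    N_B: int
    E_nuc: float
    shells: list
    ao_norms: np.ndarray

    @property
    def ri(self) -> bool:
        return self.eri is None

    def eri_tensor(self) -> np.ndarray:
        """Dense 4-index ERI tensor (reconstructed from B on the RI path)."""
        if self.eri is not None:
            return self.eri
        return np.einsum("ijP,klP->ijkl", self.B, self.B, optimize=True)


@dataclass
class NOIntegrals:
    """One-electron matrix and J/K/L integrals in the natural-orbital basis."""

    H: np.ndarray       # full (N_B, N_B) one-electron matrix in the NO basis
    J: np.ndarray       # J_pq = (pp|qq)
    K: np.ndarray       # K_pq = (pq|pq)
    L: np.ndarray       # L == K for real orbitals
    E_nuc: float


def auto_auxiliary(shells: list[Shell], beta: float = 2.0, l_max: int = 3) -> list[Shell]:
    """Even-tempered auxiliary basis generated from the orbital basis.

    For every atom, candidate exponents for angular momentum l span twice
    the primitive-exponent range of the shell pairs that can produce charge
    densities of that angular momentum, on a geometric grid with ratio
    ``beta``.  This is the standard automatic jk-fit construction; accuracy
    is controlled by ``beta``.
    """
    by_atom: dict[int, list[Shell]] = {}
    for sh in shells:
        by_atom.setdefault(sh.atom, []).append(sh)
    lmax_mol = max(sh.l for sh in shells)
    aux: list[Shell] = []
    for atom, ats in by_atom.items():
        lmax_orb = max(sh.l for sh in ats)
        center = ats[0].center
        # one-center products need up to 2*lmax_orb; two-center bond densities
        # on this atom need up to lmax_orb + lmax of the partner's functions
        l_top = min(max(2 * lmax_orb, lmax_orb + lmax_mol) + 1, l_max)
        for laux in range(0, l_top + 1):
            lo, hi = np.inf, 0.0
            for sa in ats:
                for sb in ats:
                    if sa.l + sb.l < laux and laux <= 2 * lmax_orb:
                        continue
                    lo = min(lo, sa.exps.min() + sb.exps.min())
                    hi = max(hi, sa.exps.max() + sb.exps.max())
            if not np.isfinite(lo):
                lo = 2.0 * min(s.exps.min() for s in ats)
                hi = 2.0 * max(s.exps.max() for s in ats)
            lo *= 0.5  # soften the lower edge for diffuse bond densities
            n = max(1, int(np.ceil(np.log(hi / lo) / np.log(beta))) + 1)
            exps = lo * beta ** np.arange(n)
            for a in exps:
                aux.append(Shell(l=laux, exps=np.array([a]), coefs=np.array([1.0]),
                                 center=center, atom=atom))
    return aux


def compute_ao_integrals(
    system: MolecularSystem,
    basis: str = "sto-3g",
    ri: bool = False,
    aux_basis=None,
    ri_beta: float = 2.0,
) -> AOIntegrals:
    """Compute AO integrals for ``system``.

    With ``ri=True`` the two-electron integrals are density-fitted with an
    automatically generated even-tempered auxiliary set (``aux_basis`` may
    supply an explicit list of :class:`Shell`); otherwise the full 4-index
    tensor is stored.  All AOs are normalized to unit self-overlap.
    """
    shells = build_basis(system, basis)
    S = engine.overlap(shells)
    T = engine.kinetic(shells)
    V = engine.nuclear_attraction(shells, system.coords_bohr, system.charges)
    norms = 1.0 / np.sqrt(np.diag(S))
    S = S * np.outer(norms, norms)
    hcore = (T + V) * np.outer(norms, norms)
    eri = None
    B = None
    if ri:
        if aux_basis is None:
            aux = auto_auxiliary(shells, beta=ri_beta)
        elif isinstance(aux_basis, str):
            aux = build_basis(system, load_basis(aux_basis))
        else:
            aux = list(aux_basis)
        P3 = engine.coulomb_3c(shells, aux)
        V2 = engine.coulomb_2c(aux)
        anorm = 1.0 / np.sqrt(np.diag(engine.overlap(aux)))
        P3 = P3 * anorm[None, None, :]
        V2 = V2 * np.outer(anorm, anorm)
        P3 = P3 * norms[:, None, None] * norms[None, :, None]
        # metric^(-1/2) via eigendecomposition; discard near-null directions
        w, U = np.linalg.eigh(V2)
        keep = w > 1e-10 * w.max()
        Vm12 = U[:, keep] * (1.0 / np.sqrt(w[keep]))
        B = P3 @ Vm12
    else:
        eri = engine.eri_full(shells)
        eri = np.einsum("ijkl,i,j,k,l->ijkl", eri, norms, norms, norms, norms, optimize=True)
    return AOIntegrals(S=S, Hcore=hcore, eri=eri, B=B, N_B=S.shape[0],
                       E_nuc=system.E_nuc, shells=shells, ao_norms=norms)


def check_orthonormal(C: np.ndarray, S: np.ndarray, tol: float = 1e-8) -> float:
    dev = np.abs(C.T @ S @ C - np.eye(C.shape[1])).max()
    if dev > tol:
        raise ValueError(f"orbital coefficients not S-orthonormal (max deviation {dev:.2e})")
    return dev


def transform_to_no_basis(ao: AOIntegrals, C: np.ndarray,
                          scheme: PairingScheme | None = None,
                          tol: float = 1e-8) -> NOIntegrals:
    """Transform AO integrals into the (real) natural-orbital basis.

    Returns the full one-electron matrix plus the J/K/L two-index families
    the pairing functionals consume.  ``C`` columns must be S-orthonormal.
    """
    check_orthonormal(C, ao.S, tol)
    H = C.T @ ao.Hcore @ C
    if ao.ri:
        # half-transformed three-index factors (pq|P)
        Bpq = np.einsum("ijP,ip,jq->pqP", ao.B, C, C, optimize=True)
        J = np.einsum("ppP,qqP->pq", Bpq, Bpq, optimize=True)
        K = np.einsum("pqP,pqP->pq", Bpq, Bpq, optimize=True)
    else:
        half = np.einsum("ijkl,ip,jp->pkl", ao.eri, C, C, optimize=True)
        J = np.einsum("pkl,kq,lq->pq", half, C, C, optimize=True)
        mixed = np.einsum("ijkl,ip,jq->pqkl", ao.eri, C, C, optimize=True)
        K = np.einsum("pqkl,kq,lp->pq", mixed, C, C, optimize=True)
    J = 0.5 * (J + J.T)
    K = 0.5 * (K + K.T)
    return NOIntegrals(H=H, J=J, K=K, L=K.copy(), E_nuc=ao.E_nuc)
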