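"""Energy expressions of the electron-pairing natural orbital functionals.

Implements PNOF5, PNOF7s, PNOF7 and GNOF as closed-form functionals of the
natural-orbital occupations ``n_p`` (per spin, in [0, 1]) and the J/K/L
integrals in the current NO basis.  The total electronic energy splits into

* ``E_intra``      — exact intrapair energy of each electron pair plus the
                     one-body energy of the single-electron orbitals;
* ``E_HF_inter``   — mean-field (2J - K) interaction between orbitals in
                     different subspaces, plus the ensemble exchange between
                     single-electron orbitals that fixes the multiplet
                     (two singles interact as J - K in total);
* ``E_sta_inter``  — static interspace correlation, -Phi_q Phi_p L_qp with
                     Phi = sqrt(n h) (PNOF7/GNOF) or Phi = 2 n h (PNOF7s);
* ``E_dyn_inter``  — dynamic interspace correlation built from the dynamic
                     parts n_p^d of the occupations (GNOF only).

Reduction chain: GNOF minus E_dyn_inter is PNOF7; PNOF7 with the 2nh Phi is
PNOF7s; dropping the static term as well gives PNOF5.  All reductions are
bitwise identities at fixed occupations and orbitals, and each excluded
component is reported as exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import NOIntegrals
from .pairing import PairingScheme

__all__ = [
    "FUNCTIONALS", "OccupationState", "EnergyBreakdown", "DynamicOccupationParams",
    "dynamic_occupations", "dynamic_occupation_curve", "phi_values", "pi_intrapair",
    "intrapair_energy", "hf_inter_energy", "static_inter_energy", "dynamic_inter_energy",
    "total_energy", "occupation_gradient", "coefficient_matrices",
]

FUNCTIONALS = ("PNOF5", "PNOF7s", "PNOF7", "GNOF")
_CANON = {f.lower(): f for f in FUNCTIONALS}


def canonical_functional(name: str) -> str:
    try:
        return _CANON[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown functional {name!r}; choose from {FUNCTIONALS}") from None


def _phi_variant(functional: str) -> str | None:
    f = canonical_functional(functional)
    if f == "PNOF5":
        return None
    return "pnof7s" if f == "PNOF7s" else "gnof_pnof7"


@dataclass(frozen=True)
class DynamicOccupationParams:
    """Hole-cutoff constant of the dynamic-occupation damping.

    ``h_c = 0.02*sqrt(2)``: a pairing subspace whose strong-orbital hole h_g
    exceeds a few times 0.01 (Pulay's significance threshold for dynamic
    correlation) is exponentially excluded from the dynamic interspace term.
    ``cap`` is the resulting maximum of the weak-orbital dynamic occupation,
    h_c e^{-1/2}/sqrt(2) ~ 0.012 (diagnostic only).
    """

    h_c: float = 0.02 * np.sqrt(2.0)
    cap: float = 0.02 * np.exp(-0.5)


@dataclass
class OccupationState:
    """Per-spin occupations n_p over all N_B orbitals of a pairing scheme.

    Singles carry exactly 1/2, frozen virtuals exactly 0, and every paired
    subspace sums to 1 (total occupancy 2 with spin), so the 1RDM trace is
    N by construction.
    """

    scheme: PairingScheme
    n: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)

    @property
    def h(self) -> np.ndarray:
        return 1.0 - self.n

    def validate(self, tol: float = 1e-10) -> None:
        s = self.scheme
        if self.n.shape != (s.N_B,):
            raise ValueError("occupation vector has wrong length")
        if (self.n < -tol).any() or (self.n > 1 + tol).any():
            raise ValueError("occupations out of [0, 1]")
        for g in range(s.n_pairs):
            if abs(self.n[s.members(g)].sum() - 1.0) > tol:
                raise ValueError(f"subspace {g} breaks the unit sum rule")
        singles = np.arange(s.n_pairs, s.N_Omega)
        if singles.size and np.abs(self.n[singles] - 0.5).max() > tol:
            raise ValueError("single-electron orbitals must have n = 1/2")
        frozen = np.arange(s.n_coupled, s.N_B)
        if frozen.size and np.abs(self.n[frozen]).max() > tol:
            raise ValueError("frozen virtuals must have n = 0")

    def trace_electrons(self) -> float:
        """Spin-summed 1RDM trace, equal to N for a valid state."""
        return 2.0 * float(self.n.sum())

    @classmethod
    def from_logits(cls, scheme: PairingScheme, theta: np.ndarray) -> "OccupationState":
        """Softmax map from unconstrained per-subspace logits to occupations.

        ``theta`` concatenates one block per paired subspace (strong orbital
        first, then its weak partners); the softmax enforces the unit sum
        rule and open bounds exactly.
        """
        n = np.zeros(scheme.N_B)
        n[scheme.n_pairs:scheme.N_Omega] = 0.5
        off = 0
        for g in range(scheme.n_pairs):
            idx = scheme.members(g)
            t = theta[off:off + idx.size]
            t = t - t.max()
            w = np.exp(t)
            n[idx] = w / w.sum()
            off += idx.size
        return cls(scheme=scheme, n=n)


@dataclass
class EnergyBreakdown:
    """Component energies in hartree; excluded terms are exactly 0."""

    functional: str
    E_intra: float
    E_HF_inter: float
    E_sta_inter: float
    E_dyn_inter: float
    E_nuc: float

    @property
    def E_elec(self) -> float:
        return self.E_intra + self.E_HF_inter + self.E_sta_inter + self.E_dyn_inter

    @property
    def E_total(self) -> float:
        return self.E_elec + self.E_nuc

    def as_dict(self) -> dict:
        return {
            "functional": self.functional,
            "E_intra": self.E_intra,
            "E_HF_inter": self.E_HF_inter,
            "E_sta_inter": self.E_sta_inter,
            "E_dyn_inter": self.E_dyn_inter,
            "E_elec": self.E_elec,
            "E_nuc": self.E_nuc,
            "E_total": self.E_total,
        }


# ---------------------------------------------------------------------------
# masks and couplings
# ---------------------------------------------------------------------------

def _masks(scheme: PairingScheme):
    """Boolean masks over orbital pairs used by the interspace sums."""
    nb = scheme.N_B
    sub = scheme.subspace_of
    coupled = sub >= 0
    strong = np.zeros(nb, bool); strong[:scheme.n_pairs] = True
    single = np.zeros(nb, bool); single[scheme.n_pairs:scheme.N_Omega] = True
    weak = coupled & ~strong & ~single
    inter = (sub[:, None] != sub[None, :]) & coupled[:, None] & coupled[None, :]
    np.fill_diagonal(inter, False)
    return strong, single, weak, inter


def pi_intrapair(occ: OccupationState) -> np.ndarray:
    """Intrapair pair-coupling matrix Pi over all orbitals.

    Within each paired subspace the natural amplitudes are +sqrt(n) for the
    strongly occupied orbital and -sqrt(n) for its weak partners; Pi_qp is
    their product for q != p in the same subspace (diagonal handled by the
    n_p J_pp term), zero elsewhere.
    """
    s = occ.scheme
    c = np.sqrt(np.clip(occ.n, 0.0, None))
    c[s.n_pairs:] *= -1.0  # weak partners (and singles/frozen, which never pair)
    Pi = np.zeros((s.N_B, s.N_B))
    for g in range(s.n_pairs):
        idx = s.members(g)
        blk = np.outer(c[idx], c[idx])
        Pi[np.ix_(idx, idx)] = blk
    np.fill_diagonal(Pi, 0.0)
    return Pi


def phi_values(occ: OccupationState, variant: str = "gnof_pnof7") -> np.ndarray:
    """Static-correlation amplitudes Phi_p.

    ``gnof_pnof7``: Phi = sqrt(n h); ``pnof7s``: Phi = 2 n h.  Both vanish at
    integer occupations and equal 1/2 at n = 1/2.  Frozen virtuals get 0.
    """
    n = occ.n
    h = 1.0 - n
    if variant == "pnof7s":
        phi = 2.0 * n * h
    elif variant == "gnof_pnof7":
        phi = np.sqrt(np.clip(n * h, 0.0, None))
    else:
        raise ValueError(f"unknown Phi variant {variant!r}")
    phi = phi.copy()
    phi[occ.scheme.n_coupled:] = 0.0
    return phi


def dynamic_occupation_curve(n, params: DynamicOccupationParams | None = None):
    """Dynamic part of a weakly occupied orbital's occupation under perfect
    pairing, n^d(n) = n exp(-(n/h_c)^2).

    Under the unit sum rule the subspace hole equals the weak occupation, so
    this single-variable curve is the attainable envelope of n_p^d; its
    maximum h_c e^{-1/2}/sqrt(2) ~ 0.012 matches Pulay's ~0.01 significance
    criterion for dynamic correlation.
    """
    p = params or DynamicOccupationParams()
    n = np.asarray(n, dtype=float)
    return n * np.exp(-((n / p.h_c) ** 2))


def dynamic_occupations(occ: OccupationState,
                        params: DynamicOccupationParams | None = None) -> np.ndarray:
    """Dynamic parts n_p^d = n_p exp(-(h_g/h_c)^2) for paired subspaces.

    h_g is the hole of the subspace's strongly occupied orbital: subspaces
    with significant static character (large h_g) are exponentially excluded
    from the dynamic interspace correlation.  Single-electron orbitals do not
    participate in dynamic correlation and get n^d = 0, as do frozen
    virtuals.
    """
    p = params or DynamicOccupationParams()
    s = occ.scheme
    nd = np.zeros(s.N_B)
    for g in range(s.n_pairs):
        idx = s.members(g)
        h_g = 1.0 - occ.n[g]
        nd[idx] = occ.n[idx] * np.exp(-((h_g / p.h_c) ** 2))
    return nd


# ---------------------------------------------------------------------------
# energy components
# ---------------------------------------------------------------------------

def intrapair_energy(occ: OccupationState, ints: NOIntegrals,
                     Pi: np.ndarray | None = None) -> float:
    """Pair energies of the paired subspaces plus single-electron one-body
    energies: sum_p n_p (2 H_pp + J_pp) within pairs + Pi L coupling, plus
    H_gg per single electron."""
    s = occ.scheme
    n = occ.n
    Hd = np.diag(ints.H)
    Jd = np.diag(ints.J)
    if Pi is None:
        Pi = pi_intrapair(occ)
    e = 0.0
    for g in range(s.n_pairs):
        idx = s.members(g)
        e += float(np.sum(n[idx] * (2.0 * Hd[idx] + Jd[idx])))
        e += float(Pi[np.ix_(idx, idx)].ravel() @ ints.L[np.ix_(idx, idx)].ravel())
    singles = np.arange(s.n_pairs, s.N_Omega)
    e += float(Hd[singles].sum())  # 2 n_g H_gg with n_g = 1/2
    return e


def hf_inter_energy(occ: OccupationState, ints: NOIntegrals) -> float:
    """Mean-field interspace energy sum' n_q n_p (2 J_qp - K_qp), plus the
    multiplet ensemble exchange -L_qp/4 per ordered pair of distinct
    single-electron orbitals (totaling J - K between two singles)."""
    s = occ.scheme
    strong, single, weak, inter = _masks(s)
    n = occ.n
    nn = np.outer(n, n)
    e = float(np.sum(nn * (2.0 * ints.J - ints.K) * inter))
    ss = np.outer(single, single) & inter
    e += float(np.sum(-0.25 * ints.L * ss))
    return e


def static_inter_energy(occ: OccupationState, ints: NOIntegrals,
                        variant: str = "gnof_pnof7") -> float:
    """Static interspace correlation -sum' Phi_q Phi_p L_qp over pairs in
    different subspaces (pairs of two singles belong to the always-on
    multiplet exchange and are excluded here)."""
    s = occ.scheme
    strong, single, weak, inter = _masks(s)
    phi = phi_values(occ, variant)
    mask = inter & ~(np.outer(single, single))
    return float(-np.sum(np.outer(phi, phi) * ints.L * mask))


def dynamic_inter_energy(occ: OccupationState, ints: NOIntegrals,
                         params: DynamicOccupationParams | None = None,
                         return_parts: bool = False):
    """Dynamic interspace correlation built from the dynamic occupations.

    sum' over pairs in different subspaces, excluding single-electron
    orbitals and pairs with both orbitals in the strongly occupied block:
    the pair-coupling part Pi(n^d)_qp L_qp (sign -1 between a strong and a
    weak orbital, +1 between two weak orbitals) plus occupation-product
    terms n_q^d n_p^d (L_qp - K_qp) that cancel identically for real
    orbitals (L = K).  ``return_parts`` additionally returns the product
    part and the Pi part separately.
    """
    s = occ.scheme
    strong, single, weak, inter = _masks(s)
    nd = dynamic_occupations(occ, params)
    sq = np.sqrt(np.clip(nd, 0.0, None))
    sgn = np.zeros((s.N_B, s.N_B))
    sw = np.outer(strong, weak) | np.outer(weak, strong)
    ww = np.outer(weak, weak)
    sgn[sw] = -1.0
    sgn[ww] = 1.0
    allowed = inter & ~(np.outer(strong, strong)) & ~single[:, None] & ~single[None, :]
    pi_part = float(np.sum(sgn * np.outer(sq, sq) * ints.L * allowed))
    prod_part = float(np.sum(np.outer(nd, nd) * (ints.L - ints.K) * allowed))
    if return_parts:
        return pi_part + prod_part, prod_part, pi_part
    return pi_part + prod_part


def total_energy(functional: str, occ: OccupationState, ints: NOIntegrals,
                 params: DynamicOccupationParams | None = None) -> EnergyBreakdown:
    """Assemble the component energies per the functional's reduction rule."""
    f = canonical_functional(functional)
    variant = _phi_variant(f)
    e_intra = intrapair_energy(occ, ints)
    e_hf = hf_inter_energy(occ, ints)
    e_sta = static_inter_energy(occ, ints, variant) if variant else 0.0
    e_dyn = dynamic_inter_energy(occ, ints, params) if f == "GNOF" else 0.0
    return EnergyBreakdown(functional=f, E_intra=e_intra, E_HF_inter=e_hf,
                           E_sta_inter=e_sta, E_dyn_inter=e_dyn, E_nuc=ints.E_nuc)


# ---------------------------------------------------------------------------
# coefficient matrices (solver fast path) and occupation gradient
# ---------------------------------------------------------------------------

def coefficient_matrices(functional: str, occ: OccupationState,
                         params: DynamicOccupationParams | None = None):
    """(CJ, CK, f1) such that E_elec = sum_p 2 f1_p H_pp + sum_{pq} CJ_pq J_pq
    + sum_{pq} CK_pq K_pq (real orbitals, L folded into K).

    This two-index representation drives both the fast energy evaluation and
    the orbital-rotation gradient.
    """
    f = canonical_functional(functional)
    s = occ.scheme
    n = occ.n
    strong, single, weak, inter = _masks(s)
    nb = s.N_B
    CJ = np.zeros((nb, nb))
    CK = np.zeros((nb, nb))
    # intrapair: diagonal n_p J_pp and Pi L within subspaces
    CJ[np.diag_indices(nb)] = n * (strong | weak)
    CK += pi_intrapair(occ)
    # interspace HF + multiplet exchange
    nn = np.outer(n, n) * inter
    CJ += 2.0 * nn
    CK += -nn
    CK += -0.25 * (np.outer(single, single) & inter)
    # static
    variant = _phi_variant(f)
    if variant:
        phi = phi_values(occ, variant)
        mask = inter & ~(np.outer(single, single))
        CK += -np.outer(phi, phi) * mask
    # dynamic (real orbitals: product terms cancel, Pi(n^d) L survives)
    if f == "GNOF":
        nd = dynamic_occupations(occ, params)
        sq = np.sqrt(np.clip(nd, 0.0, None))
        sw = np.outer(strong, weak) | np.outer(weak, strong)
        ww = np.outer(weak, weak)
        allowed = inter & ~np.outer(strong, strong) & ~single[:, None] & ~single[None, :]
        sgn = np.where(sw, -1.0, 0.0) + np.where(ww, 1.0, 0.0)
        CK += sgn * np.outer(sq, sq) * allowed
    f1 = n.copy()
    f1[s.n_coupled:] = 0.0
    return CJ, CK, f1


def energy_from_coefficients(CJ, CK, f1, ints: NOIntegrals) -> float:
    return float(2.0 * f1 @ np.diag(ints.H) + np.sum(CJ * ints.J) + np.sum(CK * ints.K))


def occupation_gradient(functional: str, occ: OccupationState, ints: NOIntegrals,
                        params: DynamicOccupationParams | None = None) -> np.ndarray:
    """Analytic dE/dn_p over all orbitals (zero on singles and frozen)."""
    f = canonical_functional(functional)
    p = params or DynamicOccupationParams()
    s = occ.scheme
    n = occ.n
    strong, single, weak, inter = _masks(s)
    Hd, Jd = np.diag(ints.H), np.diag(ints.J)
    grad = np.zeros(s.N_B)
    paired = strong | weak
    grad[paired] = 2.0 * Hd[paired] + Jd[paired]
    # intrapair Pi coupling: dE/dn_p = sum_q s_qp sqrt(n_q/n_p) L_qp
    c = np.sqrt(np.clip(n, 1e-300, None))
    sgnv = np.ones(s.N_B); sgnv[s.n_pairs:] = -1.0
    for g in range(s.n_pairs):
        idx = s.members(g)
        cg = c[idx] * sgnv[idx]
        Lg = ints.L[np.ix_(idx, idx)].copy()
        np.fill_diagonal(Lg, 0.0)
        grad[idx] += (Lg @ cg) * sgnv[idx] / c[idx]
    # interspace HF
    grad += 2.0 * ((2.0 * ints.J - ints.K) * inter) @ n
    # static
    variant = _phi_variant(f)
    if variant:
        phi = phi_values(occ, variant)
        mask = inter & ~np.outer(single, single)
        if variant == "pnof7s":
            dphi = 2.0 - 4.0 * n
        else:
            nh = np.clip(n * (1.0 - n), 1e-300, None)
            dphi = (1.0 - 2.0 * n) / (2.0 * np.sqrt(nh))
        grad += -2.0 * dphi * ((ints.L * mask) @ phi)
    # dynamic, chained through n^d
    if f == "GNOF":
        nd = dynamic_occupations(occ, p)
        sq = np.sqrt(np.clip(nd, 1e-300, None))
        sw = np.outer(strong, weak) | np.outer(weak, strong)
        ww = np.outer(weak, weak)
        allowed = inter & ~np.outer(strong, strong) & ~single[:, None] & ~single[None, :]
        sgn = np.where(sw, -1.0, 0.0) + np.where(ww, 1.0, 0.0)
        # dE/dn^d_r = sum_q sgn_qr sqrt(n^d_q)/sqrt(n^d_r) L_qr
        dE_dnd = ((sgn * ints.L * allowed) @ sq) / sq
        dE_dnd[~(strong | weak)] = 0.0
        for g in range(s.n_pairs):
            idx = s.members(g)
            h_g = 1.0 - n[g]
            eg = np.exp(-((h_g / p.h_c) ** 2))
            # own-occupation channel
            grad[idx] += dE_dnd[idx] * eg
            # strong-orbital (subspace-hole) channel
            grad[g] += float(np.sum(dE_dnd[idx] * n[idx])) * eg * 2.0 * h_g / p.h_c ** 2
    grad[~paired] = 0.0
    return grad
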