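"""Alternating occupation-number / natural-orbital optimization.

The stationary NOF solution is found by alternating

* BFGS optimization of the occupations in unconstrained softmax logits
  (the per-subspace unit sum rules and open bounds hold exactly at every
  evaluation), to a projected-gradient norm below ``gtol``; and
* a budgeted inner loop (default 30 steps) of orbital rotations along the
  antisymmetrized orbital-Lagrangian gradient, C <- C exp(-a G), with a
  backtracking line search so the energy never increases.

Warm starting copies natural orbitals and occupations from a donor solution
(e.g. PNOF7s as the starting point for GNOF).  Different starts may land on
different stationary points; ``multi_start`` reports all distinct solutions
found, ranked by energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from . import functional as fn
from .integrals import AOIntegrals, NOIntegrals, transform_to_no_basis
from .pairing import MolecularSystem, PairingScheme
from .scf import run_scf

__all__ = ["NOFState", "SolverOptions", "init_state", "optimize_occupations",
           "optimize_orbitals", "solve", "multi_start"]


@dataclass
class SolverOptions:
    """Convergence controls.

    gtol: occupation-gradient tolerance (BFGS, projected/logit space).
    n_inner: orbital-rotation steps per outer iteration.
    etol: outer-iteration energy-change threshold (hartree).
    otol: orbital-gradient max-norm target.
    max_outer: outer-iteration cap; exceeding it flags non-convergence.
    delta: interior perturbation of integer starting occupations.
    """

    gtol: float = 1e-4
    n_inner: int = 30
    etol: float = 1e-8
    otol: float = 1e-4
    max_outer: int = 1000
    delta: float = 1e-2


@dataclass
class NOFState:
    """Orbitals + occupations + energy of one NOF calculation."""

    system: MolecularSystem
    scheme: PairingScheme
    ao: AOIntegrals
    C: np.ndarray
    occ: fn.OccupationState
    functional: str
    params: fn.DynamicOccupationParams = field(default_factory=fn.DynamicOccupationParams)
    energy: fn.EnergyBreakdown | None = None
    history: list = field(default_factory=list)
    converged: bool = False

    def no_integrals(self) -> NOIntegrals:
        return transform_to_no_basis(self.ao, self.C, self.scheme)

    def evaluate(self) -> fn.EnergyBreakdown:
        self.energy = fn.total_energy(self.functional, self.occ, self.no_integrals(),
                                      self.params)
        return self.energy

    def copy_shallow(self) -> "NOFState":
        return NOFState(system=self.system, scheme=self.scheme, ao=self.ao,
                        C=self.C.copy(),
                        occ=fn.OccupationState(self.scheme, self.occ.n.copy()),
                        functional=self.functional, params=self.params,
                        energy=self.energy, history=list(self.history),
                        converged=self.converged)


def _interior_logits(scheme: PairingScheme, delta: float) -> np.ndarray:
    """Logits for n_strong = 1 - delta spread evenly over weak partners."""
    theta = []
    for g in range(scheme.n_pairs):
        m = scheme.members(g).size - 1
        theta.append(np.log(1.0 - delta))
        theta.extend([np.log(delta / m)] * m)
    return np.array(theta)


def _logits_from_occupations(scheme: PairingScheme, n: np.ndarray,
                             floor: float = 1e-12) -> np.ndarray:
    theta = []
    for g in range(scheme.n_pairs):
        idx = scheme.members(g)
        w = np.clip(n[idx], floor, None)
        theta.extend(np.log(w / w.sum()))
    return np.array(theta)


def init_state(system: MolecularSystem, scheme: PairingScheme, ao: AOIntegrals,
               functional: str = "PNOF5", strategy="hf_guess",
               options: SolverOptions | None = None,
               params: fn.DynamicOccupationParams | None = None) -> NOFState:
    """Build a starting state.

    ``strategy`` is ``"hf_guess"`` (converged mean-field orbitals, integer
    occupation pattern perturbed into the feasible interior) or a donor
    :class:`NOFState` whose orbitals and occupations are copied (warm start).
    """
    opts = options or SolverOptions()
    params = params or fn.DynamicOccupationParams()
    functional = fn.canonical_functional(functional)
    if isinstance(strategy, NOFState):
        donor = strategy
        if donor.ao.N_B != ao.N_B or donor.system.N != system.N \
                or donor.system.N_I != system.N_I:
            raise ValueError("warm-start donor has incompatible dimensions")
        theta = _logits_from_occupations(scheme, donor.occ.n)
        occ = fn.OccupationState.from_logits(scheme, theta)
        # donor orbitals are orthonormal under the donor metric; re-orthonormalize
        # symmetrically against this system's overlap (no-op for same geometry)
        C = donor.C.copy()
        M = C.T @ ao.S @ C
        w, U = np.linalg.eigh(M)
        C = C @ (U @ np.diag(w ** -0.5) @ U.T)
        state = NOFState(system=system, scheme=scheme, ao=ao, C=C,
                         occ=occ, functional=functional, params=params)
    elif strategy == "hf_guess":
        scf = run_scf(system, ao)
        occ = fn.OccupationState.from_logits(scheme, _interior_logits(scheme, opts.delta))
        state = NOFState(system=system, scheme=scheme, ao=ao, C=scf.C.copy(),
                         occ=occ, functional=functional, params=params)
    else:
        raise ValueError(f"unknown start strategy {strategy!r}")
    state.evaluate()
    return state


# ---------------------------------------------------------------------------
# occupation optimization
# ---------------------------------------------------------------------------

def _theta_jacobian_apply(scheme: PairingScheme, occ_n, grad_n):
    """Chain dE/dn through the per-subspace softmax to logit space."""
    out = []
    for g in range(scheme.n_pairs):
        idx = scheme.members(g)
        ng = occ_n[idx]
        gg = grad_n[idx]
        out.extend(ng * (gg - float(ng @ gg)))
    return np.array(out)


def optimize_occupations(state: NOFState, functional: str | None = None,
                         gtol: float | None = None,
                         options: SolverOptions | None = None) -> NOFState:
    """BFGS occupation optimization at fixed orbitals.

    Constraints hold exactly through the softmax parametrization; the
    returned state satisfies |logit gradient|_inf < gtol or is flagged
    non-converged.
    """
    opts = options or SolverOptions()
    gtol = gtol if gtol is not None else opts.gtol
    functional = fn.canonical_functional(functional or state.functional)
    ints = state.no_integrals()
    scheme = state.scheme

    def fun(theta):
        occ = fn.OccupationState.from_logits(scheme, theta)
        e = fn.energy_from_coefficients(
            *fn.coefficient_matrices(functional, occ, state.params), ints)
        g = fn.occupation_gradient(functional, occ, ints, state.params)
        return e, _theta_jacobian_apply(scheme, occ.n, g)

    theta0 = _logits_from_occupations(scheme, state.occ.n)
    if theta0.size == 0:
        new = state.copy_shallow()
        new.functional = functional
        new.evaluate()
        return new
    res = scipy.optimize.minimize(fun, theta0, jac=True, method="BFGS",
                                  options={"gtol": gtol, "maxiter": 2000,
                                           "norm": np.inf})
    new = state.copy_shallow()
    new.functional = functional
    new.occ = fn.OccupationState.from_logits(scheme, res.x)
    new.evaluate()
    new.converged = bool(np.abs(res.jac).max() < gtol)
    return new


# ---------------------------------------------------------------------------
# orbital optimization
# ---------------------------------------------------------------------------

def _orbital_gradient(state: NOFState, functional: str, ints: NOIntegrals):
    """Antisymmetrized orbital-Lagrangian gradient G = Lambda - Lambda^T.

    Lambda_qp = 2 n_p H_qp + 2 sum_m [CJ_pm (qp|mm) + CK_pm (qm|pm)];
    at a stationary point Lambda is symmetric.
    """
    CJ, CK, f1 = fn.coefficient_matrices(functional, state.occ, state.params)
    C = state.C
    ao = state.ao
    if ao.ri:
        Bmo = np.einsum("ijP,ip,jq->pqP", ao.B, C, C, optimize=True)
        d = np.einsum("mmP->mP", Bmo)
        G3J = np.einsum("qpP,mP->qpm", Bmo, d, optimize=True)
        G3K = np.einsum("qmP,pmP->qpm", Bmo, Bmo, optimize=True)
    else:
        half = np.einsum("ijkl,km,lm->ijm", ao.eri, C, C, optimize=True)
        G3J = np.einsum("ijm,iq,jp->qpm", half, C, C, optimize=True)
        halfk = np.einsum("ijkl,jm,lm->ikm", ao.eri, C, C, optimize=True)
        G3K = np.einsum("ikm,iq,kp->qpm", halfk, C, C, optimize=True)
    Lam = 4.0 * ints.H * f1[None, :]
    Lam += 4.0 * np.einsum("qpm,pm->qp", G3J, CJ, optimize=True)
    Lam += 4.0 * np.einsum("qpm,pm->qp", G3K, CK, optimize=True)
    return Lam - Lam.T


def optimize_orbitals(state: NOFState, functional: str | None = None,
                      n_inner: int | None = None,
                      options: SolverOptions | None = None) -> NOFState:
    """Up to ``n_inner`` rotation steps with backtracking line search.

    The energy never increases; orthonormality is exact because every step
    multiplies C by an orthogonal exp(-a G) in the S-orthonormal frame.
    """
    opts = options or SolverOptions()
    n_inner = n_inner if n_inner is not None else opts.n_inner
    functional = fn.canonical_functional(functional or state.functional)
    new = state.copy_shallow()
    new.functional = functional
    CJ, CK, f1 = fn.coefficient_matrices(functional, new.occ, new.params)

    def energy_of(C):
        ints = transform_to_no_basis(new.ao, C, new.scheme)
        return fn.energy_from_coefficients(CJ, CK, f1, ints), ints

    e0, ints = energy_of(new.C)
    alpha = 0.1
    G_prev = None
    D = None
    for _ in range(n_inner):
        G = _orbital_gradient(new, functional, ints)
        gmax = np.abs(G).max()
        if gmax < opts.otol:
            break
        # Polak-Ribiere conjugate direction (restart on loss of descent)
        if G_prev is None:
            D = -G
        else:
            beta = max(0.0, float(np.sum(G * (G - G_prev)) / max(np.sum(G_prev * G_prev), 1e-300)))
            D = -G + beta * D
            if np.sum(D * G) > -1e-14 * np.abs(D).max() * gmax:
                D = -G
        G_prev = G
        Dn = D / max(np.abs(D).max(), 1e-300)
        accepted = False
        for _ls in range(30):
            W = scipy.linalg.expm(alpha * Dn)
            C_try = new.C @ W
            e_try, ints_try = energy_of(C_try)
            if e_try < e0 + 1e-14:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            G_prev = None
            continue
        new.C, e0, ints = C_try, e_try, ints_try
        alpha = min(alpha * 1.6, 1.0)
    new.evaluate()
    return new


def solve(system: MolecularSystem, ao: AOIntegrals, scheme: PairingScheme,
          functional: str = "PNOF5", start="hf_guess",
          options: SolverOptions | None = None,
          params: fn.DynamicOccupationParams | None = None,
          verbose: bool = False) -> NOFState:
    """Alternate occupation and orbital optimization to a stationary state.

    Stops when the outer-iteration energy change is below ``etol`` with both
    inner criteria met; returns a state with the full convergence history.
    """
    opts = options or SolverOptions()
    state = init_state(system, scheme, ao, functional, start, opts, params)
    e_prev = state.energy.E_total
    state.history.append({"iter": 0, "E_total": e_prev, "dE": 0.0,
                          "occ_grad": np.inf, "orb_grad": np.inf})
    converged = False
    for it in range(1, opts.max_outer + 1):
        state = optimize_occupations(state, functional, options=opts)
        occ_ok = state.converged
        state = optimize_orbitals(state, functional, options=opts)
        ints = state.no_integrals()
        orb_grad = float(np.abs(_orbital_gradient(state, functional, ints)).max())
        e = state.energy.E_total
        de = e - e_prev
        state.history.append({"iter": it, "E_total": e, "dE": de,
                              "occ_grad": opts.gtol if occ_ok else np.inf,
                              "orb_grad": orb_grad})
        if verbose:
            print(f"outer {it:4d}  E = {e: .10f}  dE = {de: .3e}  |G_orb| = {orb_grad:.3e}")
        if abs(de) < opts.etol and occ_ok and orb_grad < opts.otol:
            converged = True
            break
        e_prev = e
    # final occupation polish at the final orbitals
    state = optimize_occupations(state, functional, options=opts)
    state.converged = converged and state.converged
    return state


def multi_start(system: MolecularSystem, ao: AOIntegrals, scheme: PairingScheme,
                functional: str, starts: list, options: SolverOptions | None = None,
                e_distinct: float = 1e-6) -> list[NOFState]:
    """Run ``solve`` from several starts; return distinct solutions by energy,
    ranked lowest first.  ``starts`` entries are "hf_guess" or donor states."""
    solutions: list[NOFState] = []
    for s in starts:
        st = solve(system, ao, scheme, functional, start=s, options=options)
        if all(abs(st.energy.E_total - o.energy.E_total) > e_distinct for o in solutions):
            solutions.append(st)
    solutions.sort(key=lambda x: x.energy.E_total)
    return solutions
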