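# Methods

## Model

`nofkit` implements natural orbital functional (NOF) theory for electronic
ground states of arbitrary spin.  The energy is a closed-form functional of
the natural orbitals (NOs) and their occupation numbers (ONs), the
eigenvectors and eigenvalues of the one-particle reduced density matrix
(1RDM).  A state of total spin *S* is treated as a spin-restricted ensemble
over all *S_z* components of the highest multiplicity 2S+1: a single set of
spatial orbitals with equal alpha and beta occupancies `n_p` in [0, 1].

Electron-pairing constraints organize the orbital space.  `N_I = 2S`
electrons sit in single-electron subspaces (one orbital each, `n = 1/2`,
total occupancy 1); the remaining `N_II = N - N_I` electrons form
`N_II/2` paired subspaces, each containing one strongly occupied orbital
and `N_g` weakly occupied partners with per-subspace occupancy exactly 2:

    sum_{p in Omega_g} n_p = 1         (per spin, for each paired subspace)

Perfect pairing is `N_g = 1`; extended pairing raises `N_g` uniformly to
the basis-set maximum `floor((N_B - N_Omega) / (N_II/2))` with
`N_Omega = N_II/2 + N_I`.  Orbitals are indexed strongly occupied block
first, then singles, then the weak partners, then frozen (empty, uncoupled)
virtuals.  These constraints make the 1RDM trace equal to N and preserve
the multiplet structure by construction — both are verified, not fitted.

## Energy expressions

With `J_pq = <pq|pq>`, `K_pq = <pq|qp>`, `L_pq = <pp|qq>` (exchange and
time-inversion integrals coincide for the real orbitals used throughout),
`h_p = 1 - n_p`, and primed sums restricted to pairs of orbitals in
*different* subspaces, the GNOF-family energy is assembled from four
components:

* **Intrapair**: for each paired subspace,
  `E_g = sum_p n_p (2H_pp + J_pp) + sum_{q != p} Pi_qp L_qp` with
  `Pi_qp = c_q c_p`, `c_p = +sqrt(n_p)` for the strong orbital and
  `-sqrt(n_p)` for weak partners; single-electron orbitals add `H_gg`.
  This is the exact (Löwdin–Shull) energy of an isolated two-electron
  singlet, so a one-pair system with full coupling reproduces FCI — the
  suite asserts agreement to 1e-6 hartree on H2 at 0.74/1.5/3.0/6.0 Å.

* **Interspace mean field**: `sum' n_q n_p (2J_qp - K_qp)` plus the
  ensemble exchange `-(1/4) L_qp` per ordered pair of distinct singles,
  which makes two single electrons interact with the full multiplet
  `J - K` (the exact high-spin limit; verified against the S_z = 1
  determinant energy of triplet H2).  This ensemble-exchange piece is kept
  in *all* functionals, including PNOF5, as part of the multiplet
  construction rather than the correlation terms: dropping it would break
  the high-spin mean-field limit that published pairing NOFs satisfy.

* **Static interspace**: `-sum' Phi_q Phi_p L_qp` over pairs not both
  single, with `Phi_p = sqrt(n_p h_p)` (PNOF7, GNOF) or `Phi_p = 2 n_p h_p`
  (PNOF7s).  `Phi` vanishes at integer occupations and peaks at 1/2, so
  the term activates only with static correlation.

* **Dynamic interspace** (GNOF): built from the *dynamic parts* of the
  occupations,

      n_p^d = n_p * exp(-(h_g / h_c)^2),   h_c = 0.02 * sqrt(2),

  where `h_g` is the hole of the strong orbital of p's subspace.  Subspaces
  with significant static character (`h_g` beyond a few times Pulay's 0.01
  significance threshold) are exponentially excluded; under the sum rule
  the attainable maximum of a weak orbital's `n_p^d` is
  `h_c e^{-1/2}/sqrt(2) ~ 0.012`.  The term sums
  `Pi(n^d)_qp L_qp` over interspace pairs — sign -1 between a strong and a
  weak orbital, +1 between two weak — excluding single-electron orbitals
  (GNOF carries no dynamic correlation for singles) and pairs of two
  strong orbitals (whose `n^d` is not small; their interaction is already
  mean-field).  Occupation-product terms `n_q^d n_p^d (L - K)` cancel
  identically for real orbitals and are retained only for reporting; the
  suite asserts the product part is below 1% of the pair-coupling part.

Reductions: GNOF minus the dynamic term **is** PNOF7; swapping `Phi` gives
PNOF7s; dropping the static term gives PNOF5.  All four are evaluated from
one component implementation, so these identities hold bitwise and are
asserted as such.

For the solver the total energy is recast as
`E = 2 sum_p f_p H_pp + sum_pq CJ_pq J_pq + sum_pq CK_pq K_pq` with
occupation-dependent coefficient matrices — one uniform two-index
representation driving both fast evaluation and orbital gradients.

## Diagnostics

The M diagnostic locates the least strongly occupied NO (LSONO: occupation
farthest from 1 within the strong block) and the least weakly occupied NO
(LWONO: farthest from 0 above `N_Omega`) and reports

    M = (1 - n_LSONO) + n_LWONO

(per-spin occupations; ties broken by lowest index).  M = 0 at integer
occupations, 1.00 for the perfect-pairing diradical, and values >= 0.1 are
classified static-dominated.  The additive deviation form was chosen over
the geometric mean `2 sqrt(h_LSONO n_LWONO)`; the two coincide in every
guarded limit and whenever the extremal orbitals share a subspace.

Adiabatic spin gaps are differences of per-multiplicity total energies in
kcal/mol (1 hartree = 627.509 kcal/mol), positive when the reference
(triplet-analogue) state lies lower.

## Optimization

The stationary solution alternates two exact-constraint steps:

* **Occupations** — each paired subspace is parametrized by a softmax over
  unconstrained logits, so bounds and unit sum rules hold exactly at every
  evaluation; singles stay pinned at 1/2.  BFGS (scipy) runs on the logits
  with the analytic chain-rule gradient to `|grad|_inf < 1e-4` (default).
  Analytic occupation gradients match central differences to 1e-6 (tested).

* **Orbitals** — up to 30 inner steps (default) of Polak–Ribière conjugate
  gradient on the rotation manifold: `C <- C exp(alpha D)` with the
  antisymmetrized orbital-Lagrangian gradient `G = Lambda - Lambda^T`,
  `Lambda_qp = 4[n_p H_qp + sum_m (CJ_pm (qp|mm) + CK_pm (qm|pm))] / 2`,
  and a backtracking line search, so the energy never increases and
  orthonormality is exact (orthogonal exponentials in the S-orthonormal
  frame).

Outer iterations stop when the energy change falls below 1e-8 hartree with
both inner criteria met (defaults: orbital gradient 1e-4, at most 1000
outer iterations — desk fixtures converge in 2–300).  Integer starting
occupations are perturbed into the interior with delta = 0.01 spread over
the weak partners, keeping `Phi` and `n^d` differentiable from the first
step.  Warm starts copy donor NOs and ONs (re-orthonormalized against the
new overlap when the geometry changed), reproducing the donor energy to
1e-10 under the donor functional; the recommended chain runs PNOF7s before
GNOF.  Because different starts can land on different stationary points,
`multi_start` solves from several starts and reports all distinct
solutions ranked by energy.

The mean-field starting guess is a spin-restricted SCF (DIIS); exact
occupied–virtual degeneracies (separated fragments) make the aufbau choice
ambiguous and can trap the iteration in a high-energy localized solution,
so degenerate pairs are resolved by picking the 45-degree rotation of
lowest mean-field energy.  This, plus warm-started dissociation scans,
yields size-consistent dissociation: E(H2 at 100 Å) − 2 E(H) < 1e-4
hartree with unit electron counts per fragment.

## Integrals

A McMurchie–Davidson Gaussian engine (Hermite expansions, Boys function
via regularized incomplete gamma) supplies overlap, kinetic, nuclear
attraction and two-electron integrals for s/p/d/f shells in real spherical
harmonics; every AO is renormalized to unit self-overlap, making bundled
contraction coefficients convention-independent.  Bundled bases: STO-3G
(H–Ne), 6-31G and 6-31G* (fixture elements), from the published
tabulations.  The engine is pinned by frozen textbook H2/STO-3G reference
integrals and by rotational-invariance checks.

The resolution-of-the-identity path factorizes the two-electron tensor
over an automatically generated even-tempered auxiliary basis: per atom,
exponents spanning twice the relevant primitive range (geometric ratio 2.0)
for angular momenta up to `max(2 l_max, l_max + l_max,mol) + 1 <= 3` —
the extension past the atom's own products is what fits two-center bond
densities (an s-only hydrogen still receives p and d fitting functions).
On H2O/6-31G the fitted tensor reproduces the full one to ~2e-5 (asserted
< 1e-4 elementwise; < 1e-3 on total NOF energies).  The metric inverse
discards eigenvalues below 1e-10 of the largest.

NO-basis transforms keep only the J/K/L two-index families the functionals
consume (plus the full one-electron matrix) and are verified against an
explicit-loop transform to 1e-10 on N_B <= 10.

## Model systems and oracles

Fixtures are generated from internal coordinates: H (one-electron limit),
H2(R) (two-electron exactness, dissociation, diradical M = 1.00), stretched
H4 chains (static correlation; the functional ladder
PNOF5 >= PNOF7s >= PNOF7 >= GNOF at each functional's own optimum), LiH
(two inequivalent pairs, extended pairing), H2O/6-31G (ten electrons,
dynamic-correlation regime, RI checks).  The FCI oracle is an independent
determinant-CI (Slater–Condon rules, dense diagonalization, spin-summed
1RDM and natural occupations) run in the package's own integrals; it is a
cross-check, never part of the production path.  Problem sizes were chosen
so the full suite runs in a few minutes on one CPU: determinant spaces
stay below ~20k and basis dimensions below ~15.

What the fixtures do *not* emulate: transition-metal d-shell near-
degeneracies, large pairing subspaces (hundreds of pairs), basis sets with
core polarization, or scalar-relativistic effects.  Passing tests
establish the correctness of the energy expressions, constraints and
optimizers at desk scale — not the quantitative spin-state energetics of
heme-sized systems, which require a ~465-function double-zeta run of the
same code paths plus externally supplied structures (the XYZ loader
validates iron-porphyrin inputs by atom count, electron count and the
per-multiplicity Fe–N distance).

## Numerical choices and limitations

* hartree internally everywhere; kcal/mol only in reporting (627.509).
* Softmax keeps occupations strictly interior, so the sqrt cusps of `Pi`,
  `Phi` and `Pi(n^d)` at n = 0/1 are never hit; logit-space gradients stay
  bounded.
* Occupation ties in the M diagnostic break to the lowest orbital index.
* Extended coupling with a non-divisible orbital surplus floors `N_g` and
  freezes the leftover virtuals empty.
* The complex-orbital path (L != K) is typed but not implemented.
* PNOF6, perturbative (MP2-type) corrections on top of the NOF reference,
  analytic nuclear gradients and geometry optimization are out of scope.
* GNOF inherits the known limitation that single-electron orbitals carry
  no dynamic correlation; multiplet energies can be correspondingly
  underestimated relative to pair-dominated states.
* The functionals are not variational bounds on FCI (only necessary
  N-representability conditions are imposed); GNOF can dip slightly below
  FCI on small fixtures, and only PNOF5 derives from an explicit
  generating wave function.
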