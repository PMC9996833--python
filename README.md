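# nofkit

Electron-pairing **natural orbital functionals** — PNOF5, PNOF7s, PNOF7 and
GNOF — as a tested Python library and `nof` command line tool.

Natural orbital functional (NOF) theory writes the electronic energy as a
closed-form functional of the natural orbitals and their occupation numbers
(the eigenpairs of the one-particle reduced density matrix), instead of a
wave function.  Fractional occupations capture static (multireference)
correlation at mean-field-like cost, which makes NOFs attractive for
spin-state energetics of systems far beyond the reach of CAS or DMRG — the
motivating application is the singlet/triplet/quintet competition in
iron(II) porphyrin, where a double-zeta treatment correlates 186 electrons
in 465 orbitals.  `nofkit` implements the full desk-scale machinery of this
family: pairing bookkeeping, its own Gaussian integral engine (with a
density-fitting path), the four functionals, the alternating
occupation/orbital optimizer, and the diagnostics used to characterize
solutions.

## The functionals

The orbital space is split into single-electron subspaces (occupation 1/2
per spin, fixing the total spin S of the multiplet ensemble) and
electron-pair subspaces — one strongly occupied orbital coupled to N_g
weakly occupied partners, with per-subspace occupancy exactly 2, so the
1RDM trace is N by construction.  With J, K, L the Coulomb, exchange and
exchange-time-inversion integrals over natural orbitals:

* **PNOF5** = exact intrapair energy (independent electron pairs) + mean
  field between subspaces;
* **PNOF7s** adds static interpair correlation `-Phi_q Phi_p L_qp` with
  `Phi = 2nh`;
* **PNOF7** uses `Phi = sqrt(nh)`;
* **GNOF** adds dynamic interpair correlation built from the dynamic parts
  of the occupations, `n_p^d = n_p exp(-(h_g/h_c)^2)` with
  `h_c = 0.02*sqrt(2)` (maximum ~0.012, Pulay's criterion).

Solutions are classified by the **M diagnostic**,
`M = (1 - n_LSONO) + n_LWONO`: ~0 means dynamic correlation dominates,
beyond 0.1 static; 1.00 under perfect pairing is a diradical signature.
See `docs/methods.md` for the full expressions, solver details and
limitations.

## Worked example

Stretched H4 (collinear, 1.8 Å spacing, minimal basis) is a classic
static-correlation stress test.  Running the functional ladder

```bash
cat > h4.yaml <<EOF
fixture: H4_chain
fixture_params: {R: 1.8}
basis: sto-3g
multiplicity: [1]
reference_multiplicity: 1
functionals: [PNOF5, PNOF7s, PNOF7, GNOF]
output: h4_out
EOF
nof ladder h4.yaml
nof oracle H4_chain
```

prints (total energies in hartree, from `h4_out/summary.json`):

| functional | E_total   | E_sta_inter | E_dyn_inter | M    |
|------------|-----------|-------------|-------------|------|
| PNOF5      | -1.729031 |  0.0        | 0.0         | 0.14 |
| PNOF7s     | -1.855313 | -0.255215   | 0.0         | 0.75 |
| PNOF7      | -1.888550 | -0.237404   | 0.0         | 0.58 |
| GNOF       | -1.888550 | -0.237404   | -0.000000   | 0.58 |

and the exact (FCI) reference `E = -1.924430660 hartree` with natural
occupations `1.638 1.446 0.558 0.358`.  Reading the numbers: the energy
descends along PNOF5 ≥ PNOF7s ≥ PNOF7 ≥ GNOF as interpair correlation is
added; the static term is large and negative (this geometry is strongly
statically correlated, M well above 0.1); and the GNOF dynamic term is
switched off almost completely because every pair's hole is far beyond the
~0.01 dynamic scale — here GNOF correctly reduces to PNOF7.  On a
two-electron system the same machinery is exact: `nof run` on the H2
fixture gives `PNOF5 E_total = -1.137283767 hartree` versus the FCI value
`-1.137283835` (the remaining 7e-8 is the convergence threshold).

The library API mirrors the CLI:

```python
from nofkit import build_system, build_pairing, compute_ao_integrals, solve, m_diagnostic

system = build_system([("H", (0, 0, 0)), ("H", (0, 0, 0.74))], charge=0, multiplicity=1)
ao = compute_ao_integrals(system, "sto-3g")
scheme = build_pairing(system, ao.N_B, "perfect")
state = solve(system, ao, scheme, "GNOF")
print(state.energy.E_total, m_diagnostic(state).M)
```

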