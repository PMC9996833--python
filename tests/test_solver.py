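"""Solver contracts: oracle agreement, descent, determinism, stationarity."""

import numpy as np
import pytest
import scipy.linalg

import nofkit.functional as fn
import nofkit.solver as sv
from nofkit.fci import fci_ground_state
from nofkit.integrals import compute_ao_integrals, transform_to_no_basis
from nofkit.pairing import build_pairing, build_system
from nofkit.scf import run_scf

from conftest import h2_system

# precision-matched tolerances for oracle-agreement tests
TIGHT = sv.SolverOptions(gtol=1e-6, otol=1e-5, etol=1e-11)


def _h2_fci(ao):
    system = h2_system()
    C = run_scf(system, ao).C
    eri = np.einsum("ijkl,ip,jq,kr,ls->pqrs", ao.eri, C, C, C, C, optimize=True)
    return fci_ground_state(C.T @ ao.Hcore @ C, eri, 1, 1, ao.E_nuc)


class TestTwoElectronExactness:
    @pytest.mark.parametrize("R", [0.74, 1.5, 3.0, 6.0])
    def test_h2_pnof5_matches_fci(self, R):
        """The pair functional with full coupling is exact for two-electron
        singlets: optimized energy and occupations match FCI."""
        system = h2_system(R)
        ao = compute_ao_integrals(system, "sto-3g")
        scheme = build_pairing(system, 2, "perfect")
        st = sv.solve(system, ao, scheme, "PNOF5", options=TIGHT)
        C = run_scf(system, ao).C
        eri = np.einsum("ijkl,ip,jq,kr,ls->pqrs", ao.eri, C, C, C, C, optimize=True)
        res = fci_ground_state(C.T @ ao.Hcore @ C, eri, 1, 1, ao.E_nuc)
        assert st.converged
        assert st.energy.E_total == pytest.approx(res.E, abs=1e-6)
        assert np.abs(np.sort(st.occ.n)[::-1]
                      - res.natural_occupations / 2.0).max() < 1e-4

    def test_h2_extended_coupling_matches_fci(self):
        """Split-valence H2 with all three weak partners coupled is still a
        full two-electron treatment."""
        system = h2_system()
        ao = compute_ao_integrals(system, "6-31g")
        scheme = build_pairing(system, ao.N_B, "extended")
        assert scheme.N_g == 3
        st = sv.solve(system, ao, scheme, "PNOF5", options=TIGHT)
        C = run_scf(system, ao).C
        eri = np.einsum("ijkl,ip,jq,kr,ls->pqrs", ao.eri, C, C, C, C, optimize=True)
        res = fci_ground_state(C.T @ ao.Hcore @ C, eri, 1, 1, ao.E_nuc)
        assert st.energy.E_total == pytest.approx(res.E, abs=1e-6)


class TestSizeConsistency:
    def test_h2_dissociates_to_two_h_atoms(self, h_atom_state):
        system = h2_system(100.0)
        ao = compute_ao_integrals(system, "sto-3g")
        st = sv.solve(system, ao, build_pairing(system, 2, "perfect"), "PNOF5")
        assert abs(st.energy.E_total - 2 * h_atom_state.energy.E_total) < 1e-4


class TestStationarity:
    def test_analytic_vs_central_difference_occupation_gradient(self, lih_ao):
        system, ao = lih_ao
        scheme = build_pairing(system, ao.N_B, "extended")
        st = sv.init_state(system, scheme, ao, "GNOF")
        ints = st.no_integrals()
        rng = np.random.default_rng(11)
        size = sum(scheme.members(g).size for g in range(scheme.n_pairs))
        occ = fn.OccupationState.from_logits(scheme, rng.normal(size=size))
        for f in fn.FUNCTIONALS:
            g_an = fn.occupation_gradient(f, occ, ints, st.params)
            g_fd = np.zeros_like(g_an)
            d = 1e-6
            for p in range(scheme.n_coupled):
                if scheme.n_pairs <= p < scheme.N_Omega:
                    continue
                for sgn in (1.0, -1.0):
                    o2 = fn.OccupationState(scheme, occ.n.copy())
                    o2.n[p] += sgn * d
                    g_fd[p] += sgn * fn.total_energy(f, o2, ints, st.params).E_elec / (2 * d)
            assert np.abs(g_an - g_fd).max() < 1e-6

    def test_analytic_vs_central_difference_orbital_gradient(self, lih_ao):
        system, ao = lih_ao
        scheme = build_pairing(system, ao.N_B, "extended")
        st = sv.init_state(system, scheme, ao, "GNOF")
        ints = st.no_integrals()
        G = sv._orbital_gradient(st, "GNOF", ints)
        CJ, CK, f1 = fn.coefficient_matrices("GNOF", st.occ, st.params)
        iu = np.triu_indices(ao.N_B, 1)

        def e_of(x):
            X = np.zeros((ao.N_B, ao.N_B))
            X[iu] = x
            X = X - X.T
            C = st.C @ scipy.linalg.expm(X)
            return fn.energy_from_coefficients(
                CJ, CK, f1, transform_to_no_basis(ao, C, scheme))

        d = 1e-6
        for k in range(len(iu[0])):
            x = np.zeros(len(iu[0]))
            x[k] = d
            gfd = (e_of(x) - e_of(-x)) / (2 * d)
            assert G[iu][k] == pytest.approx(gfd, abs=1e-6)

    def test_occupation_optimization_idempotent(self, h4_states):
        st = h4_states["PNOF7"]
        again = sv.optimize_occupations(st)
        assert again.energy.E_total == pytest.approx(st.energy.E_total, abs=1e-9)
        assert np.abs(again.occ.n - st.occ.n).max() < 1e-4


class TestDescentAndDeterminism:
    def test_outer_iteration_energies_non_increasing(self, h4_states, h2o_gnof_state):
        states = list(h4_states.values()) + [h2o_gnof_state]
        for st in states:
            e = np.array([h["E_total"] for h in st.history])
            assert np.all(np.diff(e) < 1e-8)

    def test_same_inputs_same_trajectory(self, h4_ao):
        system, ao = h4_ao
        scheme = build_pairing(system, ao.N_B, "perfect")
        s1 = sv.solve(system, ao, scheme, "PNOF7s")
        s2 = sv.solve(system, ao, scheme, "PNOF7s")
        e1 = [h["E_total"] for h in s1.history]
        e2 = [h["E_total"] for h in s2.history]
        assert e1 == e2
        assert np.array_equal(s1.C, s2.C)

    def test_orbital_step_never_increases_energy(self, lih_ao):
        system, ao = lih_ao
        scheme = build_pairing(system, ao.N_B, "perfect")
        st = sv.init_state(system, scheme, ao, "PNOF7")
        e0 = st.energy.E_total
        st2 = sv.optimize_orbitals(st)
        assert st2.energy.E_total <= e0 + 1e-12

    def test_orthonormality_maintained(self, h4_states):
        for st in h4_states.values():
            dev = np.abs(st.C.T @ st.ao.S @ st.C - np.eye(st.ao.N_B)).max()
            assert dev < 1e-10


class TestInitAndWarmStart:
    def test_hf_guess_is_interior_and_feasible(self, h2_ao):
        system = h2_system()
        scheme = build_pairing(system, 2, "perfect")
        st = sv.init_state(system, scheme, h2_ao, "PNOF5")
        st.occ.validate(tol=1e-12)
        assert st.occ.n[0] == pytest.approx(0.99, abs=1e-12)
        assert st.occ.n[1] == pytest.approx(0.01, abs=1e-12)

    def test_warm_start_preserves_donor_energy(self, h4_states):
        donor = h4_states["PNOF7s"]
        st = sv.init_state(donor.system, donor.scheme, donor.ao, "PNOF7s",
                           strategy=donor)
        assert st.energy.E_total == pytest.approx(donor.energy.E_total, abs=1e-10)

    def test_warm_start_rejects_incompatible_donor(self, h4_states, h2_ao):
        donor = h4_states["PNOF5"]
        system = h2_system()
        scheme = build_pairing(system, 2, "perfect")
        with pytest.raises(ValueError, match="incompatible"):
            sv.init_state(system, scheme, h2_ao, "PNOF5", strategy=donor)

    def test_multi_start_reports_distinct_solutions_ranked(self, h4_ao, h4_states):
        system, ao = h4_ao
        scheme = build_pairing(system, ao.N_B, "perfect")
        sols = sv.multi_start(system, ao, scheme, "GNOF",
                              starts=["hf_guess", h4_states["PNOF7s"]])
        assert 1 <= len(sols) <= 2
        energies = [s.energy.E_total for s in sols]
        assert energies == sorted(energies)
        assert all(s.converged for s in sols)


class TestOpenShell:
    def test_h_atom_energy_is_one_electron_exact(self, h_atom_state):
        st = h_atom_state
        ints = st.no_integrals()
        assert st.energy.E_total == pytest.approx(ints.H[0, 0], abs=1e-10)

    def test_h_atom_orbital_invariant(self, h_atom_state):
        st2 = sv.optimize_orbitals(h_atom_state)
        assert st2.energy.E_total == pytest.approx(
            h_atom_state.energy.E_total, abs=1e-12)

    def test_high_spin_h2_matches_exact_triplet(self):
        """Multiplet ensemble: two single electrons interact as J - K, so
        the NOF total energy equals the S_z = 1 determinant energy."""
        system = h2_system(0.74, multiplicity=3)
        ao = compute_ao_integrals(system, "sto-3g")
        scheme = build_pairing(system, 2, "perfect")
        st = sv.solve(system, ao, scheme, "PNOF5")
        C = run_scf(system, ao).C
        eri = np.einsum("ijkl,ip,jq,kr,ls->pqrs", ao.eri, C, C, C, C, optimize=True)
        res = fci_ground_state(C.T @ ao.Hcore @ C, eri, 2, 0, ao.E_nuc)
        assert st.energy.E_total == pytest.approx(res.E, abs=1e-8)

    def test_singles_never_drift_from_half(self, h2o_gnof_state):
        """Spin conservation: the fixed n = 1/2 single-electron pattern is
        preserved by construction through the whole optimization."""
        system = build_system([("Li", (0.0, 0.0, 0.0))], 0, 2)
        ao = compute_ao_integrals(system, "sto-3g")
        scheme = build_pairing(system, ao.N_B, "perfect")
        st = sv.solve(system, ao, scheme, "GNOF")
        singles = np.arange(scheme.n_pairs, scheme.N_Omega)
        assert np.all(st.occ.n[singles] == 0.5)
        st.occ.validate(tol=1e-12)

    def test_occupations_move_off_integers(self, h2o_gnof_state):
        """Dynamic correlation populates the weak orbitals (~Pulay scale)."""
        st = h2o_gnof_state
        weak = np.arange(st.scheme.N_Omega, st.scheme.n_coupled)
        assert st.occ.n[weak].max() > 1e-3
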