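"""Functional energy expressions: limits, oracles, and reduction identities.

The *independent transcription oracles* re-implement the static term, the
dynamic term and the dynamic-occupation map as plain double loops, written
directly from the functional definitions, and are compared against the
vectorized package implementations on fixed occupation vectors.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nofkit.functional as fn
from nofkit.integrals import NOIntegrals, transform_to_no_basis
from nofkit.pairing import build_pairing, build_system
from nofkit.scf import run_scf

H_C = 0.02 * np.sqrt(2.0)


def _rand_occ(scheme, seed=0):
    rng = np.random.default_rng(seed)
    size = sum(scheme.members(g).size for g in range(scheme.n_pairs))
    return fn.OccupationState.from_logits(scheme, rng.normal(scale=2.0, size=size))


def _fake_ints(nb, seed=1):
    rng = np.random.default_rng(seed)
    H = rng.normal(size=(nb, nb)); H = 0.5 * (H + H.T)
    A = rng.normal(size=(nb, nb, nb, nb))
    J = np.abs(rng.normal(size=(nb, nb))); J = 0.5 * (J + J.T)
    K = np.abs(rng.normal(size=(nb, nb))) * 0.3; K = 0.5 * (K + K.T)
    np.fill_diagonal(K, np.diag(J))
    return NOIntegrals(H=H, J=J, K=K, L=K.copy(), E_nuc=0.0)


def _scheme(n_pairs, n_single, n_b, n_g=1):
    n = 2 * n_pairs + n_single
    geom = [("H", (0.0, 0.0, float(i))) for i in range(n)]
    s = build_system(geom, 0, n_single + 1)
    return build_pairing(s, n_b, n_g)


class TestPhi:
    def test_pnof7s_at_half(self):
        scheme = _scheme(1, 0, 2)
        occ = fn.OccupationState(scheme, np.array([0.5, 0.5]))
        assert fn.phi_values(occ, "pnof7s")[0] == pytest.approx(0.5)
        assert fn.phi_values(occ, "gnof_pnof7")[0] == pytest.approx(0.5)

    def test_vanishes_at_integer_occupations(self):
        scheme = _scheme(1, 0, 2)
        occ = fn.OccupationState(scheme, np.array([1.0, 0.0]))
        for variant in ("pnof7s", "gnof_pnof7"):
            assert np.abs(fn.phi_values(occ, variant)).max() == 0.0

    @given(n=st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_matches_independent_formulas(self, n):
        scheme = _scheme(1, 0, 2)
        occ = fn.OccupationState(scheme, np.array([n, 1.0 - n]))
        assert fn.phi_values(occ, "gnof_pnof7")[0] == pytest.approx(
            np.sqrt(n * (1 - n)), abs=1e-12)
        assert fn.phi_values(occ, "pnof7s")[0] == pytest.approx(
            2 * n * (1 - n), abs=1e-12)


class TestDynamicOccupations:
    def test_zero_at_zero(self):
        assert fn.dynamic_occupation_curve(0.0) == 0.0

    def test_maximum_near_pulay_scale(self):
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-5)
        m = fn.dynamic_occupation_curve(grid).max()
        assert m == pytest.approx(0.012, abs=0.002)

    def test_curve_matches_independent_transcription(self):
        grid = np.linspace(0, 1, 1001)
        oracle = np.array([x * np.exp(-((x / H_C) ** 2)) for x in grid])
        assert np.abs(fn.dynamic_occupation_curve(grid) - oracle).max() < 1e-14

    def test_state_map_uses_subspace_hole(self):
        """n_p^d = n_p exp(-(h_g/h_c)^2) with h_g the strong orbital's hole;
        singles and frozen orbitals are excluded."""
        scheme = _scheme(2, 1, 8, n_g=2)
        occ = _rand_occ(scheme, seed=3)
        nd = fn.dynamic_occupations(occ)
        for g in range(scheme.n_pairs):
            h_g = 1.0 - occ.n[g]
            for p in scheme.members(g):
                assert nd[p] == pytest.approx(
                    occ.n[p] * np.exp(-((h_g / H_C) ** 2)), abs=1e-14)
        singles = np.arange(scheme.n_pairs, scheme.N_Omega)
        assert np.all(nd[singles] == 0.0)
        assert np.all(nd[scheme.n_coupled:] == 0.0)
        assert np.all(nd <= occ.n + 1e-15)


class TestOccupationState:
    @given(seed=st.integers(0, 1000))
    @settings(max_examples=40, derandomize=True)
    def test_softmax_parametrization_obeys_sum_rules(self, seed):
        scheme = _scheme(3, 2, 12, n_g=2)
        occ = _rand_occ(scheme, seed)
        occ.validate(tol=1e-12)
        assert occ.trace_electrons() == pytest.approx(scheme.N, abs=1e-12)

    def test_validate_rejects_broken_sum_rule(self):
        scheme = _scheme(1, 0, 2)
        with pytest.raises(ValueError, match="sum rule"):
            fn.OccupationState(scheme, np.array([0.9, 0.2])).validate()

    def test_validate_rejects_drifted_singles(self):
        scheme = _scheme(0, 1, 2)
        with pytest.raises(ValueError, match="1/2"):
            fn.OccupationState(scheme, np.array([0.6, 0.0])).validate()


class TestIntrapair:
    def test_closed_pair_limit(self):
        """A fully occupied pair orbital gives 2H_gg + J_gg."""
        scheme = _scheme(1, 0, 2)
        ints = _fake_ints(2)
        occ = fn.OccupationState(scheme, np.array([1.0, 0.0]))
        e = fn.intrapair_energy(occ, ints)
        assert e == pytest.approx(2 * ints.H[0, 0] + ints.J[0, 0], abs=1e-12)

    def test_single_electron_limit(self):
        scheme = _scheme(0, 1, 1)
        ints = _fake_ints(1)
        occ = fn.OccupationState(scheme, np.array([0.5]))
        assert fn.intrapair_energy(occ, ints) == pytest.approx(ints.H[0, 0])
        bd = fn.total_energy("GNOF", occ, ints)
        assert bd.E_elec == pytest.approx(ints.H[0, 0], abs=1e-14)

    def test_h2_at_fci_naturals_is_exact(self, h2_ao):
        """With the FCI natural orbitals and occupations, the pair energy
        reproduces the exact minimal-basis ground state."""
        from nofkit.fci import fci_ground_state
        from conftest import h2_system
        system = h2_system()
        C = run_scf(system, h2_ao).C
        eri_mo = np.einsum("ijkl,ip,jq,kr,ls->pqrs", h2_ao.eri, C, C, C, C,
                           optimize=True)
        res = fci_ground_state(C.T @ h2_ao.Hcore @ C, eri_mo, 1, 1, h2_ao.E_nuc)
        scheme = build_pairing(system, 2, "perfect")
        Cno = C @ res.natural_orbitals
        ints = transform_to_no_basis(h2_ao, Cno, scheme)
        occ = fn.OccupationState(scheme, res.natural_occupations / 2.0)
        e = fn.intrapair_energy(occ, ints) + ints.E_nuc
        assert e == pytest.approx(res.E, abs=1e-6)


class TestHFInter:
    def test_single_subspace_vanishes(self):
        scheme = _scheme(1, 0, 2)
        occ = fn.OccupationState(scheme, np.array([0.7, 0.3]))
        assert fn.hf_inter_energy(occ, _fake_ints(2)) == 0.0

    def test_two_closed_pairs(self):
        """Integer occupations reduce to the standard inter-pair mean-field
        energy 4J_12 - 2K_12 (strong orbitals 0 and 1)."""
        scheme = _scheme(2, 0, 4)
        ints = _fake_ints(4)
        occ = fn.OccupationState(scheme, np.array([1.0, 1.0, 0.0, 0.0]))
        e = fn.hf_inter_energy(occ, ints)
        assert e == pytest.approx(4 * ints.J[0, 1] - 2 * ints.K[0, 1], abs=1e-12)

    def test_invariant_under_subspace_relabeling(self):
        scheme = _scheme(2, 0, 4)
        ints = _fake_ints(4)
        occ = _rand_occ(scheme, seed=5)
        e1 = fn.hf_inter_energy(occ, ints)
        # swap the two subspaces: permute orbitals (0<->1, 2<->3)
        perm = np.array([1, 0, 3, 2])
        ints2 = NOIntegrals(H=ints.H[np.ix_(perm, perm)], J=ints.J[np.ix_(perm, perm)],
                            K=ints.K[np.ix_(perm, perm)], L=ints.L[np.ix_(perm, perm)],
                            E_nuc=0.0)
        occ2 = fn.OccupationState(scheme, occ.n[perm])
        assert fn.hf_inter_energy(occ2, ints2) == pytest.approx(e1, abs=1e-12)

    def test_two_singles_interact_as_j_minus_k(self):
        """The ensemble exchange makes two single electrons interact with the
        full multiplet J - K, the high-spin limit."""
        scheme = _scheme(0, 2, 2)
        ints = _fake_ints(2)
        occ = fn.OccupationState(scheme, np.array([0.5, 0.5]))
        bd = fn.total_energy("PNOF5", occ, ints)
        expected = ints.H[0, 0] + ints.H[1, 1] + ints.J[0, 1] - ints.K[0, 1]
        assert bd.E_elec == pytest.approx(expected, abs=1e-12)


def _static_oracle(occ, ints, variant):
    """Independent loop transcription of the static interspace term."""
    s = occ.scheme
    e = 0.0
    for p in range(s.N_B):
        for q in range(s.N_B):
            if p == q or s.subspace_of[p] < 0 or s.subspace_of[q] < 0:
                continue
            if s.subspace_of[p] == s.subspace_of[q]:
                continue
            sp = s.n_pairs <= p < s.N_Omega
            sq = s.n_pairs <= q < s.N_Omega
            if sp and sq:
                continue  # two singles: multiplet exchange, not the Phi term
            def phi(i):
                n = occ.n[i]
                return 2 * n * (1 - n) if variant == "pnof7s" else np.sqrt(n * (1 - n))
            e -= phi(q) * phi(p) * ints.L[q, p]
    return e


def _dynamic_oracle(occ, ints):
    """Independent loop transcription of the dynamic interspace term
    (real orbitals: occupation-product terms cancel with L = K)."""
    s = occ.scheme
    nd = np.zeros(s.N_B)
    for g in range(s.n_pairs):
        h_g = 1.0 - occ.n[g]
        for p in s.members(g):
            nd[p] = occ.n[p] * np.exp(-((h_g / H_C) ** 2))
    e = 0.0
    for p in range(s.n_coupled):
        for q in range(s.n_coupled):
            if p == q or s.subspace_of[p] == s.subspace_of[q]:
                continue
            rp = "strong" if p < s.n_pairs else ("single" if p < s.N_Omega else "weak")
            rq = "strong" if q < s.n_pairs else ("single" if q < s.N_Omega else "weak")
            if "single" in (rp, rq):
                continue
            if rp == "strong" and rq == "strong":
                continue
            sign = -1.0 if rp != rq else 1.0
            e += sign * np.sqrt(nd[q] * nd[p]) * ints.L[q, p] \
                + nd[q] * nd[p] * (ints.L[q, p] - ints.K[q, p])
    return e


class TestStaticInter:
    def test_vanishes_at_integer_occupations(self):
        scheme = _scheme(2, 0, 4)
        occ = fn.OccupationState(scheme, np.array([1.0, 1.0, 0.0, 0.0]))
        for variant in ("pnof7s", "gnof_pnof7"):
            assert fn.static_inter_energy(occ, _fake_ints(4), variant) == 0.0

    @pytest.mark.parametrize("variant", ["pnof7s", "gnof_pnof7"])
    def test_matches_independent_transcription(self, variant, h4_states):
        st = h4_states["PNOF7"]
        ints = st.no_integrals()
        assert fn.static_inter_energy(st.occ, ints, variant) == pytest.approx(
            _static_oracle(st.occ, ints, variant), abs=1e-12)

    def test_lowers_energy_relative_to_pnof5(self, h4_states):
        """On stretched H4 the static term is negative: at identical
        occupations PNOF7/PNOF7s lie below PNOF5."""
        st = h4_states["PNOF7s"]
        ints = st.no_integrals()
        for variant in ("pnof7s", "gnof_pnof7"):
            assert fn.static_inter_energy(st.occ, ints, variant) < -1e-3


class TestDynamicInter:
    def test_vanishes_without_dynamic_parts(self):
        scheme = _scheme(2, 0, 4)
        occ = fn.OccupationState(scheme, np.array([1.0, 1.0, 0.0, 0.0]))
        assert fn.dynamic_inter_energy(occ, _fake_ints(4)) == 0.0

    def test_matches_independent_transcription(self, h2o_gnof_state):
        st = h2o_gnof_state
        ints = st.no_integrals()
        assert fn.dynamic_inter_energy(st.occ, ints) == pytest.approx(
            _dynamic_oracle(st.occ, ints), abs=1e-12)

    def test_product_terms_negligible_vs_pi_terms(self, h2o_gnof_state):
        """For real orbitals the occupation-product terms cancel (L = K), so
        the pair-coupling Pi part carries the dynamic correlation."""
        st = h2o_gnof_state
        ints = st.no_integrals()
        tot, prod, pi = fn.dynamic_inter_energy(st.occ, ints, return_parts=True)
        assert pi < 0.0
        assert abs(prod) < 0.01 * abs(pi)


class TestTotalEnergy:
    def test_unknown_functional_rejected(self):
        scheme = _scheme(1, 0, 2)
        occ = fn.OccupationState(scheme, np.array([0.9, 0.1]))
        with pytest.raises(ValueError, match="unknown functional"):
            fn.total_energy("PNOF6", occ, _fake_ints(2))

    def test_reduction_identities_bitwise(self, h4_states):
        """At identical occupations/orbitals: GNOF minus its dynamic term is
        PNOF7; PNOF7 minus its static term is PNOF5; the PNOF7s assembly
        differs only through Phi.  Shared components agree bitwise."""
        st = h4_states["GNOF"]
        ints = st.no_integrals()
        bds = {f: fn.total_energy(f, st.occ, ints) for f in fn.FUNCTIONALS}
        for f in ("PNOF5", "PNOF7s", "PNOF7"):
            assert bds[f].E_intra == bds["GNOF"].E_intra
            assert bds[f].E_HF_inter == bds["GNOF"].E_HF_inter
            assert bds[f].E_dyn_inter == 0.0
        assert bds["PNOF5"].E_sta_inter == 0.0
        assert bds["PNOF7"].E_sta_inter == bds["GNOF"].E_sta_inter
        assert bds["GNOF"].E_elec == bds["PNOF7"].E_elec + bds["GNOF"].E_dyn_inter

    def test_reduction_inequality_chain_at_fixed_occupations(self, h4_states):
        """E(PNOF5) >= E(PNOF7s) >= E(PNOF7) at the same point, because the
        static term is nonpositive and Phi_PNOF7 >= Phi_PNOF7s pointwise."""
        st = h4_states["PNOF7s"]
        ints = st.no_integrals()
        e = {f: fn.total_energy(f, st.occ, ints).E_elec for f in fn.FUNCTIONALS}
        assert e["PNOF5"] >= e["PNOF7s"] >= e["PNOF7"]
        assert fn.total_energy("PNOF7", st.occ, ints).E_sta_inter <= 0.0
        assert fn.total_energy("GNOF", st.occ, ints).E_dyn_inter <= 1e-12

    def test_breakdown_matches_coefficient_representation(self, h4_states):
        st = h4_states["GNOF"]
        ints = st.no_integrals()
        for f in fn.FUNCTIONALS:
            bd = fn.total_energy(f, st.occ, ints)
            e = fn.energy_from_coefficients(
                *fn.coefficient_matrices(f, st.occ, st.params), ints)
            assert bd.E_elec == pytest.approx(e, abs=1e-11)
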