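"""Shared fixtures: AO integrals and solved states are expensive enough to
be computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from nofkit import build_pairing, build_system, compute_ao_integrals, make_fixture
from nofkit import solver as sv

BOHR = 1.8897259886


def h2_system(R=0.74, multiplicity=1):
    return build_system([("H", (0.0, 0.0, -R / 2)), ("H", (0.0, 0.0, R / 2))],
                        0, multiplicity)


@pytest.fixture(scope="session")
def h2_ao():
    return compute_ao_integrals(h2_system(), "sto-3g")


@pytest.fixture(scope="session")
def lih_ao():
    fx = make_fixture("LiH")
    return fx.system, compute_ao_integrals(fx.system, "sto-3g")


@pytest.fixture(scope="session")
def h4_ao():
    fx = make_fixture("H4_chain", R=1.8)
    return fx.system, compute_ao_integrals(fx.system, "sto-3g")


@pytest.fixture(scope="session")
def h2o_ao():
    fx = make_fixture("H2O")
    return fx.system, compute_ao_integrals(fx.system, "6-31g")


@pytest.fixture(scope="session")
def h2o_ao_ri():
    fx = make_fixture("H2O")
    return compute_ao_integrals(fx.system, "6-31g", ri=True)


@pytest.fixture(scope="session")
def h4_states(h4_ao):
    """Converged stretched-H4 solutions for all four functionals."""
    system, ao = h4_ao
    scheme = build_pairing(system, ao.N_B, "perfect")
    states = {}
    prev = None
    for f in ("PNOF5", "PNOF7s", "PNOF7", "GNOF"):
        states[f] = sv.solve(system, ao, scheme, f, start="hf_guess")
    return states


@pytest.fixture(scope="session")
def h2o_gnof_state(h2o_ao):
    system, ao = h2o_ao
    scheme = build_pairing(system, ao.N_B, "perfect")
    st7s = sv.solve(system, ao, scheme, "PNOF7s",
                    options=sv.SolverOptions(max_outer=400))
    st = sv.solve(system, ao, scheme, "GNOF", start=st7s,
                  options=sv.SolverOptions(max_outer=400))
    return st


@pytest.fixture(scope="session")
def h_atom_state():
    system = build_system([("H", (0.0, 0.0, 0.0))], 0, 2)
    ao = compute_ao_integrals(system, "sto-3g")
    scheme = build_pairing(system, ao.N_B, "perfect")
    return sv.solve(system, ao, scheme, "PNOF5")
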