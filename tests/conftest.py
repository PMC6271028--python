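"""Shared fixtures: molecules, derived constants and cached eigenfunctions."""

import math

import pytest

import qhmol as q

#: printed reference values for the four fixture molecules:
#: lambda, dimensionless period, period in seconds, frequency in Hz
TABLE1_PRINTED = {
    "H2": (16.8403, 0.3845, 8.091e-15, 12360e10),
    "HCl": (25.6722, 0.2496, 11.74e-15, 8522e10),
    "O2": (52.7203, 0.1203, 21.31e-15, 4693e10),
    "N2": (67.2966, 0.09406, 14.24e-15, 7021e10),
}


@pytest.fixture(scope="session")
def molecules():
    return {name: q.load_molecule(name) for name in ("H2", "HCl", "O2", "N2")}


@pytest.fixture(scope="session")
def hcl_constants():
    return q.derive_constants(q.load_molecule("HCl"))


@pytest.fixture(scope="session")
def h2_ground():
    """H2 (n, J, mJ) = (0, 0, 0) eigenfunction."""
    return q.make_eigenfunction("H2", q.QuantumState(0, 0, 0))


@pytest.fixture(scope="session")
def h2_ground_trajectory(h2_ground):
    """One closed radial contour of the H2 ground state, start r_eq + 0.1."""
    pk = h2_ground.pk
    r_eq = q.equilibrium_bond_length(q.QuantumState(0, 0), pk)
    T = q.period_residue(q.QuantumState(0, 0), pk)
    return q.integrate_trajectory(h2_ground, (r_eq + 0.1, math.pi / 2, 0.0), 6.0 * T)
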