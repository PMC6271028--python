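"""Morse rovibrational eigensystem: Pekeris constants, wavefunctions,
eigenvalues and logarithmic derivatives."""

import cmath
import math

import mpmath
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import eigh_tridiagonal

import qhmol as q
from qhmol._legendre import legendre_q_theta


def grid_eigenvalues(c, potential, n_levels=2, lo=0.8, hi=9.0, npts=4000):
    """Brute-force finite-difference eigensolve of -u'' + v(r) u = eps u."""
    r = np.linspace(lo, hi, npts)
    h = r[1] - r[0]
    d = 2.0 / h**2 + potential(r)
    e = -np.ones(npts - 1) / h**2
    return eigh_tridiagonal(d, e, select="i", select_range=(0, n_levels - 1))[0]


class TestMorsePotential:
    def test_minimum_and_dissociation(self, molecules):
        p = molecules["H2"]
        b = p.beta * p.r0
        assert q.morse_potential(b, p) == pytest.approx(-p.E_D, rel=1e-14)
        assert q.morse_potential(b + 40.0, p) == pytest.approx(0.0, abs=1e-17 * p.E_D)

    def test_curvature_at_minimum(self, molecules):
        # d2V/dr2 (dimensional) = 2 E_D beta^2; finite-difference oracle
        p = molecules["O2"]
        b = p.beta * p.r0
        h = 1e-5
        curv_dimless = (q.morse_potential(b + h, p) - 2 * q.morse_potential(b, p)
                        + q.morse_potential(b - h, p)) / h**2
        assert curv_dimless * p.beta**2 == pytest.approx(2 * p.E_D * p.beta**2, rel=1e-5)


class TestQuantumState:
    def test_mj_bound(self):
        with pytest.raises(ValueError, match="mJ"):
            q.QuantumState(0, 1, 2)

    def test_mixed_requires_coefficient(self):
        with pytest.raises(ValueError, match="B1, B2"):
            q.QuantumState(0, 0, 0, branch="mixed", B1=0, B2=0)


class TestPekerisConstants:
    def test_j0_exact_limit(self, hcl_constants):
        pk = q.pekeris_constants(q.QuantumState(0, 0), hcl_constants)
        assert pk.alpha == pytest.approx(2 * hcl_constants.lam - 1, rel=1e-14)
        assert pk.eta == pytest.approx(hcl_constants.lam, rel=1e-14)

    def test_j0_toy_lambda(self):
        c = q.DerivedConstants(lam=2.0, b=3.0, time_scale=1.0, B_bar=1.0, D_bar=1.0)
        pk = q.pekeris_constants(q.QuantumState(0, 0), c)
        assert (pk.alpha, pk.eta) == (pytest.approx(3.0), pytest.approx(2.0))

    def test_z_map_monotone_positive(self, hcl_constants):
        pk = q.pekeris_constants(q.QuantumState(0, 2), hcl_constants)
        r = np.linspace(0.5, 8.0, 50)
        z = pk.z_of_r(r)
        assert np.all(z > 0) and np.all(np.diff(z) < 0)

    def test_unbound_state_rejected(self, hcl_constants):
        with pytest.raises(ValueError, match="unbound|bound"):
            q.pekeris_constants(q.QuantumState(40, 0), hcl_constants)

    @pytest.mark.parametrize("J", [1, 5])
    def test_eigenvalue_vs_grid_solve_of_pekeris_operator(self, hcl_constants, J):
        """The closed-form (alpha, eta) must diagonalize the reduced operator."""
        c = hcl_constants
        pk = q.pekeris_constants(q.QuantumState(0, J), c)
        gamma = J * (J + 1)

        def v(r):
            x = r - c.b
            return pk.Av * np.exp(-2 * x) - pk.Bv * np.exp(-x) + gamma * pk.c0 / c.b**2

        eps = grid_eigenvalues(c, v)
        for n, target in enumerate(eps):
            E = q.eigenenergy(q.QuantumState(n, J), c).E / c.energy_unit
            assert E == pytest.approx(target, rel=2e-5)

    @pytest.mark.parametrize("J", [0, 1, 5])
    def test_eigenvalue_vs_exact_centrifugal_solve(self, hcl_constants, J):
        """Against the unexpanded 1/r^2 operator the Pekeris value is accurate
        to the truncation error of the second-order expansion."""
        c = hcl_constants

        def v(r):
            x = r - c.b
            return c.lam**2 * (np.exp(-2 * x) - 2 * np.exp(-x)) + J * (J + 1) / r**2

        eps = grid_eigenvalues(c, v)
        E0 = q.eigenenergy(q.QuantumState(0, J), c).E / c.energy_unit
        assert E0 == pytest.approx(eps[0], rel=1e-4)


class TestRadialWavefunction:
    def test_n1_node_at_alpha_plus_one(self, hcl_constants):
        state = q.QuantumState(1, 0)
        pk = q.pekeris_constants(state, hcl_constants)
        f = q.radial_wavefunction(state, pk)
        r_node = pk.r_of_z(pk.alpha + 1.0)
        assert abs(f.u(r_node)) < 1e-12 * abs(f.u(pk.r_of_z(pk.alpha + 2.0)))

    def test_node_counts_by_sign_scan(self, hcl_constants):
        # n = 0: no zeros; n = 2: exactly two real-axis nodes in z in (0, 4 eta)
        for n, expected in ((0, 0), (1, 1), (2, 2)):
            state = q.QuantumState(n, 0)
            pk = q.pekeris_constants(state, hcl_constants)
            f = q.radial_wavefunction(state, pk)
            z = np.linspace(1e-3, 4 * pk.eta, 20001)
            vals = np.real(f.u(pk.r_of_z(z)))
            signs = np.sign(vals)
            flips = int(np.sum(signs[:-1] * signs[1:] < 0))
            assert flips == expected

    def test_orthogonality_fixed_J(self, hcl_constants):
        c = hcl_constants
        fs = []
        for n in range(3):
            state = q.QuantumState(n, 1)
            fs.append(q.Eigenfunction(state, q.pekeris_constants(state, c), c))
        for i in range(3):
            for j in range(i + 1, 3):
                val, _ = quad(lambda r: float(np.real(fs[i].radial(r) * fs[j].radial(r))) * r * r,
                              1e-9, c.b + 60.0, limit=200)
                assert abs(val) < 1e-6

    def test_norm_stable_under_domain_extension(self, h2_ground):
        n1 = h2_ground.radial_norm
        val, _ = quad(lambda r: abs(h2_ground.u(r)) ** 2, 1e-9, h2_ground.pk.b + 120.0,
                      limit=400)
        assert 1.0 / math.sqrt(val) == pytest.approx(n1, rel=1e-7)


class TestAngularWavefunction:
    def test_j0_first_kind_is_one(self):
        theta_fn = q.angular_wavefunction(q.QuantumState(0, 0))
        assert theta_fn(0.3 + 2.0j) == pytest.approx(1.0)

    def test_j1_first_kind_is_cos(self):
        theta_fn = q.angular_wavefunction(q.QuantumState(0, 1, 0))
        th = 0.7 - 0.4j
        assert theta_fn(th) == pytest.approx(cmath.cos(th), rel=1e-12)

    def test_q1_matches_mpmath_at_complex_angle(self):
        th = complex(math.pi / 2, 0.5)
        z = cmath.cos(th)
        mine = complex(legendre_q_theta(1, 0, th))
        ref = complex(mpmath.legenq(1, 0, mpmath.mpc(z.real, z.imag), type=3))
        assert mine == pytest.approx(ref, rel=1e-12)

    @pytest.mark.parametrize("J,m,kind", [
        (1, 0, "first_kind"), (2, 1, "first_kind"), (3, 2, "first_kind"),
        (0, 0, "second_kind"), (1, 0, "second_kind"), (2, 1, "second_kind"),
    ])
    def test_legendre_ode_residual_at_random_complex_angles(self, J, m, kind):
        """Both kinds satisfy the associated Legendre equation in theta."""
        from qhmol._legendre import legendre_theta_callables
        fv, fd1, fd2 = legendre_theta_callables(J, m, kind)
        rng = np.random.default_rng(20251002)
        for _ in range(8):
            th = complex(rng.uniform(0.4, math.pi - 0.4), rng.uniform(-2.5, 2.5))
            if abs(th.imag) < 0.2:
                th += 0.5j  # keep clear of the second-kind cut on the real axis
            v, d1, d2 = fv(th), fd1(th), fd2(th)
            ct = cmath.cos(th) / cmath.sin(th)
            residual = d2 + ct * d1 + (J * (J + 1) - m**2 / cmath.sin(th) ** 2) * v
            scale = max(abs(d2), abs(v) * J * (J + 1), 1.0)
            assert abs(residual) / scale < 1e-8

    def test_unit_modulus_azimuthal(self, h2_ground):
        f = q.make_eigenfunction("H2", q.QuantumState(0, 2, 2))
        assert abs(abs(f.azimuthal(1.234)) - 1.0) < 1e-14


class TestEigenEnergy:
    def test_increases_with_n(self, hcl_constants):
        energies = [q.eigenenergy(q.QuantumState(n, 0), hcl_constants).E for n in range(4)]
        assert all(e2 > e1 for e1, e2 in zip(energies, energies[1:]))
        assert all(e < 0 for e in energies)

    def test_j0_centrifugal_correction_vanishes(self, hcl_constants):
        e = q.eigenenergy(q.QuantumState(0, 0), hcl_constants)
        assert e.E_rot == 0.0 and e.E_rot_rigid == 0.0

    def test_level_spacing_matches_vibration_period(self, hcl_constants):
        """E_{n+1} - E_n ~ 2 pi hbar / T within the Morse anharmonicity."""
        c = hcl_constants
        dE = (q.eigenenergy(q.QuantumState(1, 0), c).E
              - q.eigenenergy(q.QuantumState(0, 0), c).E)
        T = q.period_residue(q.QuantumState(0, 0), q.pekeris_constants(q.QuantumState(0, 0), c))
        omega = 2 * math.pi / (T * c.time_scale)
        assert dE == pytest.approx(q.CODATA.hbar * omega, rel=1.2 / (2 * c.lam - 1))

    def test_rotational_difference_near_nonrigid_model(self, hcl_constants):
        """The J=0->1 eigenvalue difference agrees with the distorted-rotor
        closed form at the few-percent level (it additionally carries the
        vibration-rotation coupling, so exact agreement is not expected)."""
        c = hcl_constants
        dE = (q.eigenenergy(q.QuantumState(0, 1), c).E
              - q.eigenenergy(q.QuantumState(0, 0), c).E)
        nu = dE / (q.CODATA.h * q.CODATA.c)
        assert nu == pytest.approx(q.nonrigid_spectrum(c, 0)[0], rel=0.02)


class TestLogDerivatives:
    def test_ground_state_closed_form(self, h2_ground):
        """d ln(rR)/dr = (z - alpha)/2 for n = 0, checked against numerical
        differentiation of the wavefunction itself."""
        pk = h2_ground.pk
        for r in (1.3, 1.6 + 0.2j, 2.1 - 0.4j):
            z = pk.z_of_r(r)
            assert h2_ground.dln_u(r) == pytest.approx((z - pk.alpha) / 2.0, rel=1e-12)
            h = 1e-6
            fd = (np.log(h2_ground.u(r + h)) - np.log(h2_ground.u(r - h))) / (2 * h)
            assert h2_ground.dln_u(r) == pytest.approx(fd, rel=1e-8)

    def test_second_log_derivative_vs_finite_difference(self, hcl_constants):
        state = q.QuantumState(1, 1)
        pk = q.pekeris_constants(state, hcl_constants)
        f = q.Eigenfunction(state, pk, hcl_constants)
        r = 2.2 + 0.1j
        h = 1e-5
        fd = (np.log(f.u(r + h)) - 2 * np.log(f.u(r)) + np.log(f.u(r - h))) / h**2
        assert f.d2ln_u(r) == pytest.approx(fd, rel=1e-5)

    def test_angular_and_azimuthal_components(self):
        f = q.make_eigenfunction("H2", q.QuantumState(0, 0, 0))
        dr, dth, dph = q.log_derivatives(f, 1.5, 0.8 + 0.5j, 0.1)
        assert dth == 0.0 and dph == 0.0
        f2 = q.make_eigenfunction("H2", q.QuantumState(0, 2, 2))
        _, _, dph2 = q.log_derivatives(f2, 1.5, 0.8 + 0.5j, 0.1)
        assert dph2 == pytest.approx(2j)

    def test_node_raises_singularity_error(self, hcl_constants):
        state = q.QuantumState(1, 0)
        pk = q.pekeris_constants(state, hcl_constants)
        f = q.radial_wavefunction(state, pk)
        r_node = pk.r_of_z(pk.alpha + 1.0)
        with pytest.raises(q.SingularityError, match="coordinate: r"):
            f.dln_u(r_node)
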