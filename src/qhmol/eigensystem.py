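"""Analytic rovibrational eigensystem of the rotating Morse oscillator.

The radial Schroedinger equation for a Morse bond with rotation is made
analytically solvable by the Pekeris reduction: the centrifugal term
``Gamma / r_tilde**2`` (``Gamma = J(J+1)``) is expanded to second order in
``exp(-(r_tilde - b))`` about the potential minimum ``b``.  Collecting the
exponentials gives an effective Morse-type problem

    u'' + [eps + Bv * e^{-x} - Av * e^{-2x}] u = 0,      x = r_tilde - b,

with ``Av = lam**2 + Gamma c2 / b**2``, ``Bv = 2 lam**2 - Gamma c1 / b**2``
and Pekeris coefficients ``c0 = 1 - 3/b + 3/b**2``, ``c1 = 4/b - 6/b**2``,
``c2 = 3/b**2 - 1/b``.  In the variable ``z = 2 eta e^{-x}`` with
``eta = sqrt(Av)`` the bound solutions are

    u_{n,J}(z) = e^{-z/2} z^{alpha/2} L_n^{alpha}(z),
    alpha = Bv / sqrt(Av) - 2n - 1,

with generalized Laguerre polynomials ``L_n^alpha``, and eigenvalues

    E_{n,J} = (hbar^2 beta^2 / 2M) [ Gamma c0 / b**2 - (alpha / 2)**2 ].

At ``J = 0`` this is the exact Morse solution with ``alpha = 2 lam - 2n - 1``
and ``eta = lam``.  The full eigenfunction factorizes as
``Psi = R_{n,J}(r) Theta_{J,mJ}(theta) Phi_{mJ}(phi)`` with ``R = u / r_tilde``,
``Theta`` an associated Legendre function of either kind (or a mixture) and
``Phi = exp(i mJ phi)``.

Everything the dynamics needs is expressed through ``z``, which is an entire,
never-vanishing function of complex ``r_tilde``, so the logarithmic
derivatives used by the equations of motion are single-valued rational
functions of ``z`` — no branch choice is ever made during integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.integrate import quad
from scipy.special import genlaguerre

from .constants import CODATA
from .molecule import DerivedConstants, MoleculeParams, derive_constants

__all__ = [
    "SingularityError",
    "QuantumState",
    "PekerisConstants",
    "EigenEnergy",
    "Eigenfunction",
    "morse_potential",
    "pekeris_constants",
    "radial_wavefunction",
    "angular_wavefunction",
    "eigenenergy",
    "log_derivatives",
]

_BRANCHES = ("first_kind", "second_kind", "mixed")


class SingularityError(ValueError):
    """Raised when a quantity is evaluated at a node or coordinate singularity."""

    def __init__(self, message: str, coordinate: str):
        super().__init__(f"{message} (coordinate: {coordinate})")
        self.coordinate = coordinate


@dataclass(frozen=True)
class QuantumState:
    """Quantum numbers ``(n, J, mJ)`` plus the angular-branch selector.

    ``branch`` chooses the polar solution: ``"first_kind"`` (associated
    Legendre P — the square-integrable textbook choice), ``"second_kind"``
    (Legendre Q — the anti-spin branch) or ``"mixed"`` with complex
    coefficients ``(B1, B2)`` multiplying P and Q.
    """

    n: int
    J: int
    mJ: int = 0
    branch: str = "first_kind"
    B1: complex = 1.0
    B2: complex = 0.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.J < 0:
            raise ValueError("n and J must be nonnegative integers")
        if abs(self.mJ) > self.J:
            raise ValueError(f"|mJ| = {abs(self.mJ)} exceeds J = {self.J}")
        if self.branch not in _BRANCHES:
            raise ValueError(f"branch must be one of {_BRANCHES}, got {self.branch!r}")
        if self.branch == "mixed" and self.B1 == 0 and self.B2 == 0:
            raise ValueError("mixed branch requires (B1, B2) != (0, 0)")

    @property
    def coefficients(self) -> tuple[complex, complex]:
        """Effective (B1, B2) for the polar factor."""
        if self.branch == "first_kind":
            return (1.0, 0.0)
        if self.branch == "second_kind":
            return (0.0, 1.0)
        return (complex(self.B1), complex(self.B2))


@dataclass(frozen=True)
class PekerisConstants:
    """Constants of the Pekeris-reduced radial problem for one ``(n, J)``.

    ``alpha`` and ``eta`` define the radial solution through
    ``z = 2 eta exp(-(r_tilde - b))``; ``c0, c1, c2`` are the expansion
    coefficients of the centrifugal term; ``Av, Bv`` the collected
    exponential coefficients.  At ``J = 0``: ``alpha = 2 lam - 2n - 1`` and
    ``eta = lam`` exactly.
    """

    alpha: float
    eta: float
    n: int
    J: int
    lam: float
    b: float
    c0: float
    c1: float
    c2: float
    Av: float
    Bv: float

    def z_of_r(self, r_tilde):
        """Map ``z = 2 eta exp(-(r_tilde - b))`` (entire, never zero)."""
        return 2.0 * self.eta * np.exp(-(np.asarray(r_tilde) - self.b)) if np.ndim(r_tilde) \
            else 2.0 * self.eta * np.exp(-(r_tilde - self.b))

    def r_of_z(self, z):
        """Inverse map on the principal branch."""
        return self.b - np.log(z / (2.0 * self.eta))


def morse_potential(r_tilde, p: MoleculeParams):
    """Morse potential in J at dimensionless distance, minimum ``-E_D`` at ``b``.

    ``V = E_D (e^{-2x} - 2 e^{-x})`` with ``x = r_tilde - beta r0``; the
    dissociation limit is 0.  Accepts real or complex ``r_tilde``.
    """
    x = np.asarray(r_tilde) - p.beta * p.r0 if np.ndim(r_tilde) else r_tilde - p.beta * p.r0
    return p.E_D * (np.exp(-2.0 * x) - 2.0 * np.exp(-x))


def pekeris_constants(state: QuantumState, c: DerivedConstants) -> PekerisConstants:
    """Pekeris constants ``(alpha, eta)`` for a bound state.

    Raises a domain error if the state lies outside the bound regime
    (``alpha <= 0`` means the Laguerre ladder has run out of bound states).
    """
    lam, b = c.lam, c.b
    gamma = state.J * (state.J + 1)
    c0 = 1.0 - 3.0 / b + 3.0 / b**2
    c1 = 4.0 / b - 6.0 / b**2
    c2 = 3.0 / b**2 - 1.0 / b
    Av = lam**2 + gamma * c2 / b**2
    Bv = 2.0 * lam**2 - gamma * c1 / b**2
    if Av <= 0 or Bv <= 0:
        raise ValueError(f"state (n={state.n}, J={state.J}) outside the bound regime: "
                         f"effective well coefficients Av={Av:.3g}, Bv={Bv:.3g}")
    eta = math.sqrt(Av)
    alpha = Bv / eta - 2 * state.n - 1
    if alpha <= 0:
        raise ValueError(f"state (n={state.n}, J={state.J}) is unbound: alpha = {alpha:.4g} <= 0")
    return PekerisConstants(alpha=alpha, eta=eta, n=state.n, J=state.J, lam=lam, b=b,
                            c0=c0, c1=c1, c2=c2, Av=Av, Bv=Bv)


@dataclass(frozen=True)
class EigenEnergy:
    """Eigenvalue ``E_{n,J}`` (J) and its rovibrational decomposition.

    ``E_vib`` is the ``J = 0`` ladder value, ``E_rot = E - E_vib`` the full
    rotational component, ``E_rot_rigid = h c B_bar J(J+1)`` the rigid-rotor
    estimate, and ``E_rot_centrifugal`` the remainder (bond-stretch
    correction).  All in J; energies are negative for bound states with the
    dissociation limit at 0.
    """

    E: float
    n: int
    J: int
    E_vib: float
    E_rot: float
    E_rot_rigid: float
    E_rot_centrifugal: float


def eigenenergy(state: QuantumState, c: DerivedConstants) -> EigenEnergy:
    """Bound-state eigenvalue and rotational decomposition."""
    pk = pekeris_constants(state, c)
    Eu = c.energy_unit
    gamma = state.J * (state.J + 1)
    E = Eu * (gamma * pk.c0 / pk.b**2 - (pk.alpha / 2.0) ** 2)
    pk0 = pekeris_constants(QuantumState(state.n, 0), c)
    E_vib = Eu * (-(pk0.alpha / 2.0) ** 2)
    E_rot = E - E_vib
    E_rigid = CODATA.h * CODATA.c * c.B_bar * gamma
    return EigenEnergy(E=E, n=state.n, J=state.J, E_vib=E_vib, E_rot=E_rot,
                       E_rot_rigid=E_rigid, E_rot_centrifugal=E_rot - E_rigid)


class Eigenfunction:
    """Evaluable eigenfunction ``Psi = R_{n,J} Theta_{J,mJ} Phi_{mJ}`` with
    closed-form logarithmic derivatives.

    All radial quantities are routed through ``z`` so they are single-valued
    for complex ``r_tilde``; the radial *value* uses the principal branch of
    ``z**(alpha/2)`` (no cut is crossed for ``|Im r_tilde| < pi``).
    """

    #: relative proximity to a node that triggers a singularity error
    node_rtol = 1e-12

    def __init__(self, state: QuantumState, pk: PekerisConstants,
                 constants: DerivedConstants, params: MoleculeParams | None = None):
        self.state = state
        self.pk = pk
        self.constants = constants
        self.params = params
        n, alpha = state.n, pk.alpha
        # Laguerre polynomial and derivatives as coefficient arrays in z
        lag = genlaguerre(n, alpha)
        self._L = npoly.Polynomial(lag.coefficients[::-1])
        self._dL = self._L.deriv() if n >= 1 else npoly.Polynomial([0.0])
        self._d2L = self._dL.deriv() if n >= 2 else npoly.Polynomial([0.0])
        from ._legendre import legendre_theta_callables
        B1, B2 = state.coefficients
        self._ang = []
        if B1 != 0:
            self._ang.append((B1, legendre_theta_callables(state.J, abs(state.mJ), "first_kind")))
        if B2 != 0:
            self._ang.append((B2, legendre_theta_callables(state.J, abs(state.mJ), "second_kind")))

    # -- radial ---------------------------------------------------------------

    def z(self, r_tilde):
        return self.pk.z_of_r(r_tilde)

    def _laguerre_ratio(self, z):
        """(L'/L, L''/L) with a node guard for n >= 1."""
        L = self._L(z)
        if self.state.n >= 1:
            scale = np.max(np.abs(self._L.coef)) * (1.0 + np.max(np.abs(np.atleast_1d(z))))
            if np.any(np.abs(L) < self.node_rtol * scale):
                raise SingularityError("radial wavefunction node (Laguerre zero)", "r")
        return self._dL(z) / L, self._d2L(z) / L

    def u(self, r_tilde):
        """Unnormalized ``u = r_tilde * R = e^{-z/2} z^{alpha/2} L_n^alpha(z)``."""
        z = self.z(r_tilde)
        return np.exp(-z / 2.0) * np.power(z, self.pk.alpha / 2.0) * self._L(z)

    @cached_property
    def radial_norm(self) -> float:
        """Normalization ``N`` with ``integral_0^inf (N u)^2 dr_tilde = 1``."""
        peak = self.pk.b  # u is O(1)-scaled by its value near the well
        uref = abs(self.u(peak)) or 1.0
        val, _ = quad(lambda r: (abs(self.u(r)) / uref) ** 2, 1e-9, self.pk.b + 60.0,
                      limit=200)
        return 1.0 / (uref * math.sqrt(val))

    def radial(self, r_tilde):
        """Normalized radial wavefunction ``R_{n,J}(r_tilde)``."""
        return self.radial_norm * self.u(r_tilde) / r_tilde

    def dln_u(self, r_tilde):
        """``d ln u / d r_tilde`` — rational in z: ``(z - alpha)/2 - z L'/L``."""
        z = self.z(r_tilde)
        ratio, _ = self._laguerre_ratio(z)
        # equals -z * s(z) with s = -1/2 + alpha/(2z) + L'/L
        return (z - self.pk.alpha) / 2.0 - z * ratio

    def d2ln_u(self, r_tilde):
        """``d^2 ln u / d r_tilde^2`` (closed form, d/dr_tilde = -z d/dz)."""
        z = self.z(r_tilde)
        r1, r2 = self._laguerre_ratio(z)
        s = -0.5 + self.pk.alpha / (2.0 * z) + r1
        sp = -self.pk.alpha / (2.0 * z**2) + (r2 - r1**2)
        return z * s + z**2 * sp

    def d3ln_u(self, r_tilde):
        """Third radial log-derivative (used by analytic force gradients)."""
        z = self.z(r_tilde)
        r1, r2 = self._laguerre_ratio(z)
        L = self._L(z)
        r3 = (self._d2L.deriv()(z) / L) if self.state.n >= 3 else 0.0 * z
        s = -0.5 + self.pk.alpha / (2.0 * z) + r1
        sp = -self.pk.alpha / (2.0 * z**2) + (r2 - r1**2)
        spp = self.pk.alpha / z**3 + (r3 - 3.0 * r1 * r2 + 2.0 * r1**3)
        # d/dr (z s + z^2 s') with d/dr = -z d/dz
        return -(z * s + 3.0 * z**2 * sp + z**3 * spp)

    def dlnR(self, r_tilde):
        """``d ln R / d r_tilde = d ln u / d r_tilde - 1 / r_tilde``."""
        return self.dln_u(r_tilde) - 1.0 / r_tilde

    # -- angular --------------------------------------------------------------

    def _theta_sum(self, theta):
        """(Theta, Theta', Theta'') summed over branches with coefficients."""
        v = d1 = d2 = 0.0
        for coeff, (fv, fd1, fd2) in self._ang:
            v = v + coeff * fv(theta)
            d1 = d1 + coeff * fd1(theta)
            d2 = d2 + coeff * fd2(theta)
        return v, d1, d2

    def angular(self, theta):
        """Polar factor ``Theta_{J,mJ}(theta)`` (complex theta supported)."""
        return self._theta_sum(theta)[0]

    def dln_theta(self, theta):
        v, d1, _ = self._theta_sum(theta)
        self._check_theta(v, theta)
        return d1 / v

    def d2ln_theta(self, theta):
        """``d^2 ln Theta / d theta^2`` from independently compiled derivatives."""
        v, d1, d2 = self._theta_sum(theta)
        self._check_theta(v, theta)
        return d2 / v - (d1 / v) ** 2

    def theta_second_ratio(self, theta):
        """``Theta'' / Theta`` (independent of the Legendre ODE identity)."""
        v, _, d2 = self._theta_sum(theta)
        self._check_theta(v, theta)
        return d2 / v

    def _check_theta(self, value, theta):
        scale = sum(abs(c) for c, _ in self._ang) or 1.0
        if np.any(np.abs(value) < self.node_rtol * scale):
            raise SingularityError("polar wavefunction node", "theta")
        if np.any(np.abs(np.sin(np.asarray(theta, dtype=complex))) < 1e-12):
            raise SingularityError("polar axis theta in {0, pi}", "theta")

    def azimuthal(self, phi):
        """``Phi = exp(i mJ phi)`` — unit modulus on the real axis."""
        return np.exp(1j * self.state.mJ * np.asarray(phi, dtype=complex)) if np.ndim(phi) \
            else np.exp(1j * self.state.mJ * complex(phi))

    def psi(self, r_tilde, theta, phi):
        """Full (normalized-radial) eigenfunction value."""
        return self.radial(r_tilde) * self.angular(theta) * self.azimuthal(phi)


def radial_wavefunction(state: QuantumState, pk: PekerisConstants,
                        constants: DerivedConstants | None = None) -> Eigenfunction:
    """Build the evaluable eigenfunction for ``state`` (radial-centric entry).

    ``constants`` may be omitted when ``pk`` carries ``lam`` and ``b`` (it
    always does); it is then reconstructed minimally for dimensionless work.
    """
    if constants is None:
        constants = DerivedConstants(lam=pk.lam, b=pk.b, time_scale=1.0, B_bar=1.0, D_bar=1.0)
    return Eigenfunction(state, pk, constants)


def angular_wavefunction(state: QuantumState):
    """Standalone polar factor ``Theta_{J,mJ}`` as a callable of complex theta."""
    from ._legendre import legendre_theta_callables
    B1, B2 = state.coefficients
    parts = []
    if B1 != 0:
        parts.append((B1, legendre_theta_callables(state.J, abs(state.mJ), "first_kind")[0]))
    if B2 != 0:
        parts.append((B2, legendre_theta_callables(state.J, abs(state.mJ), "second_kind")[0]))

    def theta_fn(theta):
        return sum(c * f(theta) for c, f in parts)

    return theta_fn


def log_derivatives(f: Eigenfunction, r_tilde, theta, phi):
    """Complex gradient of ``ln Psi`` at a phase-space point.

    Returns ``(d ln Psi/d r_tilde, d ln Psi/d theta, d ln Psi/d phi)``; raises
    :class:`SingularityError` at wavefunction nodes, identifying the
    offending coordinate.
    """
    dr = f.dlnR(r_tilde)
    if f.state.J == 0 and f.state.branch == "first_kind":
        dth = 0.0 * np.asarray(theta, dtype=complex) if np.ndim(theta) else 0.0
    else:
        dth = f.dln_theta(theta)
    dph = 1j * f.state.mJ
    return dr, dth, dph


def make_eigenfunction(source: str | MoleculeParams, state: QuantumState) -> Eigenfunction:
    """Convenience constructor: molecule fixture/params + state -> Eigenfunction."""
    from .molecule import load_molecule
    p = load_molecule(source)
    c = derive_constants(p)
    pk = pekeris_constants(state, c)
    ef = Eigenfunction(state, pk, c, params=p)
    return ef
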