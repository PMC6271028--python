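"""State-dependent vibrational observables: equilibria, periods, force
constants and the multi-shell structure of the total potential.

Three independent routes to the vibration period are provided and must
agree:

* ``period_from_trajectory`` — Poincare-section returns of an integrated
  closed contour in the complex radial plane;
* ``period_residue`` — the residue theorem applied to the radial velocity
  field (all contours enclose the single zero at ``z = alpha``), giving
  ``T = 2 pi / |dL_r/dr|`` at the equilibrium and the closed form
  ``T = 4 pi / (2 lam - 1)`` for the rovibrational ground state;
* ``force_constant`` — the curvature of the total potential at equilibrium
  and the classical relation ``T = 2 pi sqrt(M / K)``.

For excited vibrational states (n >= 1) the radial dynamics has ``n + 1``
stable equilibria separated by the ``n`` nodes of the Laguerre factor, where
the total potential has infinite barriers: the bond is trapped in one of
``n + 1`` shells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dynamics import ComplexTrajectory, integrate_trajectory, total_potential
from .eigensystem import Eigenfunction, PekerisConstants, QuantumState, pekeris_constants
from .molecule import DerivedConstants, MoleculeParams, derive_constants

__all__ = [
    "EquilibriumSet",
    "PeriodReport",
    "CoincidenceReport",
    "equilibrium_bond_length",
    "find_equilibria",
    "coincidence_check",
    "period_from_trajectory",
    "period_residue",
    "force_constant",
    "frequency_report",
]


@dataclass(frozen=True)
class EquilibriumSet:
    """Finite equilibria of the radial dynamics, with shell assignment.

    ``z_values`` are the roots of ``dr/dtau = 0`` in the Morse variable ``z``
    (descending z = ascending bond length ``r_values``); ``nodes`` are the
    Laguerre zeros, where the total potential has infinite barriers.
    ``shell_index[i]`` counts how many nodes lie at larger z than the
    equilibrium (0 = innermost... in r; shells ordered by increasing r).
    """

    z_values: tuple[float, ...]
    r_values: tuple[float, ...]
    stability: tuple[str, ...]
    shell_index: tuple[int, ...]
    nodes: tuple[float, ...]


@dataclass(frozen=True)
class PeriodReport:
    """Vibration period by three routes plus dimensional frequency data."""

    T_trajectory: float | None
    T_residue: float
    T_force_constant: float
    T_dimensional: float
    f: float
    K: float
    f_exp: float | None = None
    rel_error: float | None = None


@dataclass(frozen=True)
class CoincidenceReport:
    """Per-shell coincidence of four independently located positions."""

    shell: int
    r_min_total_potential: float
    r_zero_force: float
    r_zero_velocity: float
    r_max_probability: float

    @property
    def spread(self) -> float:
        vals = (self.r_min_total_potential, self.r_zero_force,
                self.r_zero_velocity, self.r_max_probability)
        return max(vals) - min(vals)


def equilibrium_bond_length(state: QuantumState, pk: PekerisConstants) -> float:
    """Ground-vibrational equilibrium bond length ``r_eq = b - ln(alpha/2 eta)``
    (dimensionless).  Increases monotonically with J."""
    if state.n != 0:
        raise ValueError("closed form only for n = 0; use find_equilibria for excited states")
    ratio = pk.alpha / (2.0 * pk.eta)
    r_eq = pk.b - math.log(ratio)
    if r_eq <= 0:
        raise ValueError(f"unphysical equilibrium bond length {r_eq:.4g} <= 0")
    return r_eq


def _equilibrium_polynomial(f: Eigenfunction):
    """Polynomial in z whose positive roots are the radial equilibria.

    ``d ln u / dr = (z - alpha)/2 - z L'/L = 0``  <=>
    ``(z - alpha) L / 2 - z L' = 0``; degree n + 1.
    """
    from numpy.polynomial import polynomial as npoly
    L = f._L
    dL = f._dL
    zpoly = npoly.Polynomial([0.0, 1.0])
    return (zpoly - f.pk.alpha) * L / 2.0 - zpoly * dL


def find_equilibria(state: QuantumState, pk: PekerisConstants) -> EquilibriumSet:
    """All finite equilibria of the radial flow, classified, with shell nodes.

    For n = 0 the single root is ``z = alpha``; for n = 1 the two roots of
    ``z^2 - (2 alpha + 3) z + alpha (alpha + 1)``, one on each side of the
    node ``z = alpha + 1``.
    """
    from .eigensystem import radial_wavefunction
    f = radial_wavefunction(state, pk)
    poly = _equilibrium_polynomial(f)
    roots = poly.roots()
    z_eq = sorted(float(z.real) for z in roots
                  if abs(z.imag) < 1e-9 * max(1.0, abs(z)) and z.real > 1e-12)
    node_roots = f._L.roots() if state.n >= 1 else np.array([])
    nodes = sorted(float(z.real) for z in node_roots if abs(z.imag) < 1e-9)
    # order by increasing bond length r  <=>  decreasing z
    z_eq = z_eq[::-1]
    stability = []
    for z in z_eq:
        # flow dr/dtau = -i L_r(r); a simple real zero of L_r is a center
        slope = float(np.real(f.d2ln_u(complex(pk.r_of_z(z)))))
        stability.append("stable" if abs(slope) > 1e-12 else "degenerate")
    shell = [sum(1 for nd in nodes if nd > z) for z in z_eq]
    r_vals = tuple(float(pk.r_of_z(z)) for z in z_eq)
    return EquilibriumSet(z_values=tuple(z_eq), r_values=r_vals,
                          stability=tuple(stability), shell_index=tuple(shell),
                          nodes=tuple(sorted(nodes)))


def _shell_brackets(f: Eigenfunction, eq: EquilibriumSet):
    """Radial brackets (r_lo, r_hi) isolating each shell's equilibrium."""
    pk = f.pk
    brackets = []
    # shell boundaries in z: +inf (small r) ... nodes ... 0 (large r)
    for z, shell in zip(eq.z_values, eq.shell_index):
        upper_nodes = [nd for nd in eq.nodes if nd > z]
        lower_nodes = [nd for nd in eq.nodes if nd < z]
        z_hi = min(upper_nodes) if upper_nodes else 4.0 * z + 10.0
        z_lo = max(lower_nodes) if lower_nodes else z / 50.0
        # stay clear of the node singularities
        if upper_nodes:
            z_hi = z + 0.98 * (z_hi - z)
        if lower_nodes:
            z_lo = z - 0.98 * (z - z_lo)
        brackets.append((float(pk.r_of_z(z_hi)), float(pk.r_of_z(z_lo))))
    return brackets


def coincidence_check(state: QuantumState, pk: PekerisConstants,
                      constants: DerivedConstants | None = None) -> list[CoincidenceReport]:
    """Locate, per shell, four positions by independent numerical routes:

    1. the minimum of the total potential (finite-difference slope root),
    2. the zero of the analytic radial force,
    3. the zero of the complex radial velocity,
    4. the maximum of the radial probability ``r^2 R^2`` (finite-difference
       slope root of ``u^2``),

    and report them; they agree to root-finder accuracy (well within 1e-8).
    """
    from .dynamics import lagrange_forces
    from .eigensystem import radial_wavefunction
    if constants is None:
        f = radial_wavefunction(state, pk)
    else:
        f = Eigenfunction(state, pk, constants)
    eq = find_equilibria(state, pk)
    reports = []
    h = 1e-6

    def v_total(r):
        return float(np.real(total_potential(f, complex(r))))

    def prob(r):
        return abs(f.u(complex(r))) ** 2

    for (r_lo, r_hi), shell, z in zip(_shell_brackets(f, eq), eq.shell_index, eq.z_values):
        r_vel = brentq(lambda r: float(np.real(f.dln_u(complex(r)))), r_lo, r_hi, xtol=1e-14)
        r_force = brentq(lambda r: float(np.real(lagrange_forces(f, complex(r))[0])),
                         r_lo, r_hi, xtol=1e-14)
        r_vmin = brentq(lambda r: (v_total(r + h) - v_total(r - h)) / (2 * h),
                        r_lo + 2 * h, r_hi - 2 * h, xtol=1e-14)
        r_pmax = brentq(lambda r: (prob(r + h) - prob(r - h)) / (2 * h),
                        r_lo + 2 * h, r_hi - 2 * h, xtol=1e-14)
        reports.append(CoincidenceReport(shell=shell,
                                         r_min_total_potential=r_vmin,
                                         r_zero_force=r_force,
                                         r_zero_velocity=r_vel,
                                         r_max_probability=r_pmax))
    return reports


def period_residue(state: QuantumState, pk: PekerisConstants) -> float:
    """Dimensionless vibration period from the residue theorem.

    Every closed radial contour encloses exactly one zero of the velocity
    field, so the period is ``2 pi i / v'(r_eq) = 2 pi / |dL_r/dr (r_eq)|``.
    For n = 0 this is ``4 pi / alpha`` (``4 pi / (2 lam - 1)`` at J = 0).
    """
    if state.n == 0:
        return 4.0 * math.pi / pk.alpha
    from .eigensystem import radial_wavefunction
    f = radial_wavefunction(state, pk)
    eq = find_equilibria(state, pk)
    # innermost-r shell by default; excited states have one period per shell
    periods = []
    for r_eq in eq.r_values:
        slope = float(np.real(f.d2ln_u(complex(r_eq))))
        periods.append(2.0 * math.pi / abs(slope))
    return periods[0] if len(periods) == 1 else periods  # type: ignore[return-value]


def period_from_trajectory(traj: ComplexTrajectory, r_eq: float | None = None,
                           n_cycles: tuple[int, int] = (1, 4)) -> float:
    """Measure the period from Poincare-section returns of a closed contour.

    The section is ``Im(r) = 0`` crossed upward with ``Re(r) > r_eq``;
    crossing times are refined by bisection on the dense solution and the
    period is the mean gap over cycles ``n_cycles[0]+1 .. n_cycles[1]``
    (the first cycle is discarded against start-up bias).
    """
    if traj.dense is None:
        raise ValueError("trajectory was integrated without dense output")
    f = traj.eigenfunction
    if r_eq is None:
        eq = find_equilibria(f.state, f.pk)
        candidates = np.asarray(eq.r_values)
        r_eq = float(candidates[np.argmin(np.abs(candidates - traj.r[0].real))])

    def im_r(t):
        return traj.dense(t)[1]

    # crossings on a fine grid, then refine
    t_grid = np.linspace(traj.tau[0], traj.tau[-1], max(4000, 40 * len(traj.tau)))
    vals = np.array([traj.dense(t)[1] for t in t_grid])
    re_vals = np.array([traj.dense(t)[0] for t in t_grid])
    crossings = []
    for i in range(len(t_grid) - 1):
        if vals[i] < 0.0 <= vals[i + 1] and re_vals[i] > r_eq:
            t_star = brentq(im_r, t_grid[i], t_grid[i + 1], xtol=1e-13)
            crossings.append(t_star)
    lo, hi = n_cycles
    if len(crossings) <= hi:
        raise ValueError(
            f"trajectory not closed or too short: found {len(crossings)} section returns, "
            f"need > {hi} (termination: {traj.termination})")
    gaps = np.diff(crossings)[lo:hi]
    return float(np.mean(gaps))


def force_constant(state: QuantumState, pk: PekerisConstants, p: MoleculeParams,
                   r_eq: float | None = None) -> tuple[float, float]:
    """Quantum force constant ``K = V_Total''(r_eq)`` (N/m) and the period
    ``2 pi sqrt(M/K)`` in dimensionless time.

    ``K = 2 (hbar^2 beta^4 / M) * (dL_r/dr)^2`` at the equilibrium —
    curvature in physical r of the dimensional total potential.
    """
    from .eigensystem import radial_wavefunction
    c = derive_constants(p)
    f = Eigenfunction(state, pk, c, params=p)
    if r_eq is None:
        if state.n == 0:
            r_eq = equilibrium_bond_length(state, pk)
        else:
            r_eq = find_equilibria(state, pk).r_values[0]
    Lr = complex(f.dln_u(complex(r_eq)))
    if abs(Lr) > 1e-8:
        raise ValueError(f"force constant must be evaluated at an equilibrium; "
                         f"|dr/dtau| = {abs(Lr):.3g} at r = {r_eq:.6g}")
    slope = float(np.real(f.d2ln_u(complex(r_eq))))
    Eu = c.energy_unit
    K = 2.0 * Eu * p.beta**2 * slope**2  # J/m^2 = N/m
    T_dimless = 2.0 * math.pi * math.sqrt(p.M / K) / c.time_scale
    return K, T_dimless


def frequency_report(p: MoleculeParams, f_exp: float | None = None,
                     measure_trajectory: bool = False) -> PeriodReport:
    """Ground-state vibration period/frequency by all routes for one molecule.

    ``T_dimensional = T * M / (hbar beta^2)`` and ``f = 1/T_dimensional``;
    if ``f_exp`` (Hz) is given the relative error is reported.
    """
    c = derive_constants(p)
    state = QuantumState(0, 0)
    pk = pekeris_constants(state, c)
    T_res = period_residue(state, pk)
    K, T_fc = force_constant(state, pk, p)
    T_traj = None
    if measure_trajectory:
        f_ef = Eigenfunction(state, pk, c, params=p)
        r_eq = equilibrium_bond_length(state, pk)
        traj = integrate_trajectory(f_ef, (r_eq + 0.1, math.pi / 2, 0.0),
                                    tau_max=6.0 * T_res)
        T_traj = period_from_trajectory(traj, r_eq=r_eq)
    T_dim = T_res * c.time_scale
    freq = 1.0 / T_dim
    rel = None if f_exp is None else abs(f_exp - freq) / f_exp
    return PeriodReport(T_trajectory=T_traj, T_residue=T_res, T_force_constant=T_fc,
                        T_dimensional=T_dim, f=freq, K=K, f_exp=f_exp, rel_error=rel)
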