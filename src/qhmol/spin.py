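"""Angular dynamics and rotational spectra.

Complex polar-angle trajectories fall into three regions: Omega_minus
(``Im theta >> 0``, real part drifting down), Omega_plus (``Im theta << 0``,
drifting up) and Omega_0 (periodic about the real-axis equilibria).  In the
drifting regions the time-averaged theta-direction angular momentum
``<M r^2 dtheta/dt>`` is ``-(J + 1/2) hbar`` and ``+(J + 1/2) hbar``
respectively — the half-integer remnant interpreted as molecular spin — while
in Omega_0 the quantized z-component ``mJ hbar`` is carried by the azimuthal
motion.  The second-kind (Legendre Q) angular branch generates drift of the
opposite sign at the same side of the complex plane: the anti-spin partner.

Three rotational-spectrum models for the ``J -> J+1`` absorption lines:

* rigid rotor:      ``nu = 2 B_bar (J+1)``;
* non-rigid rotor:  ``nu = 2 B_bar (J+1) - 4 D_bar (J+1)^3`` (centrifugal
  distortion);
* trajectory (QHM): classical rotational energy ``E_R = <L>^2 / (2 M r_J^2)``
  with the trajectory-mean angular momentum ``(J + 1/2) hbar`` and the
  J-dependent equilibrium bond length ``r_J``; line position
  ``nu = (E_R(J+1) - E_R(J)) / hc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CODATA
from .dynamics import ComplexTrajectory, integrate_trajectory
from .eigensystem import Eigenfunction, QuantumState, pekeris_constants
from .molecule import DerivedConstants, MoleculeParams, derive_constants
from .vibration import equilibrium_bond_length

__all__ = [
    "SpinClassification",
    "SpectrumLine",
    "AsymptoticTrig",
    "HCL_MEASURED_LINES_CM1",
    "classify_spin",
    "asymptotic_trig",
    "spin_trajectory",
    "compare_spin_branches",
    "rigid_spectrum",
    "nonrigid_spectrum",
    "qhm_spectrum",
    "spectrum_table",
    "fit_rotational_constants",
]

#: Measured far-infrared absorption lines of H-Cl, J -> J+1 for J = 0..8, cm^-1.
HCL_MEASURED_LINES_CM1: tuple[float, ...] = (
    20.88, 41.74, 62.58, 83.32, 104.13, 124.73, 145.37, 165.89, 186.23)


@dataclass(frozen=True)
class SpinClassification:
    """Region label and mean angular momenta of one theta-trajectory.

    ``L_theta_mean`` and ``L_phi_mean`` are in units of hbar; ``region`` is
    ``"Omega-"``, ``"Omega0"`` or ``"Omega+"`` by the sign of the mean real
    polar drift ``mean_dthetaR``.
    """

    region: str
    mean_dthetaR: float
    L_theta_mean: complex
    L_phi_mean: float


@dataclass(frozen=True)
class SpectrumLine:
    """One J -> J+1 transition under the three models (cm^-1)."""

    J: int
    nu_rigid: float
    nu_nonrigid: float
    nu_qhm: float
    nu_exp: float | None = None

    def rel_error(self, model: str) -> float | None:
        if self.nu_exp is None:
            return None
        return abs(getattr(self, f"nu_{model}") - self.nu_exp) / self.nu_exp


@dataclass(frozen=True)
class AsymptoticTrig:
    """Exact complex trig at theta plus large-|Im theta| asymptotic forms.

    For ``theta = thR + i thI`` with ``|thI| >> 0``:
    ``cos theta ~ e^{|thI|} (cos thR -+ i sin thR)/2``,
    ``sin theta ~ e^{|thI|} (sin thR +- i cos thR)/2`` and
    ``cot theta -> -+ i`` (upper sign for thI > 0), with error O(e^{-2|thI|}).
    """

    cos: complex
    sin: complex
    cot: complex
    cos_asymptotic: complex
    sin_asymptotic: complex
    cot_asymptotic: complex
    error_bound: float


def asymptotic_trig(theta: complex) -> AsymptoticTrig:
    """Exact and asymptotic complex trigonometry at a polar angle."""
    th = complex(theta)
    thR, thI = th.real, th.imag
    sign = 1.0 if thI >= 0 else -1.0
    grow = math.exp(abs(thI)) / 2.0
    cos_a = grow * (math.cos(thR) - 1j * sign * math.sin(thR))
    sin_a = grow * (math.sin(thR) + 1j * sign * math.cos(thR))
    cot_a = -1j * sign
    c, s = np.cos(th), np.sin(th)
    return AsymptoticTrig(cos=c, sin=s, cot=c / s,
                          cos_asymptotic=cos_a, sin_asymptotic=sin_a,
                          cot_asymptotic=cot_a,
                          error_bound=math.exp(-2.0 * abs(thI)) if thI else math.inf)


def spin_trajectory(f: Eigenfunction, theta0: complex, tau_max: float,
                    r_start: float | None = None, **kwargs) -> ComplexTrajectory:
    """Integrate the angular dynamics with the bond at its equilibrium length.

    The radial flow vanishes at ``r_eq``, so starting there confines the
    motion to (theta, phi); this is the configuration in which the spin
    regions are defined.
    """
    if r_start is None:
        r_start = equilibrium_bond_length(QuantumState(0, f.state.J), f.pk) \
            if f.state.n == 0 else None
    if r_start is None:
        from .vibration import find_equilibria
        r_start = find_equilibria(f.state, f.pk).r_values[0]
    return integrate_trajectory(f, (r_start, theta0, 0.0), tau_max, **kwargs)


def classify_spin(traj: ComplexTrajectory, discard: float = 0.1,
                  stability_tol: float = 0.01) -> SpinClassification:
    """Classify a theta-trajectory into a spin region and average its momenta.

    The mean theta-direction angular momentum is the time average of
    ``r^2 dtheta/dtau`` (units of hbar) over the window after discarding the
    initial ``discard`` fraction; the average must be stable at the
    ``stability_tol`` level when the window is halved, otherwise the
    trajectory is reported as too short.  The region follows the sign of the
    mean real polar drift; drifts smaller than one radian over the window
    (relative to the oscillation scale) are classed periodic (Omega0).
    """
    from .dynamics import velocities
    n = len(traj.tau)
    i0 = int(discard * n)
    if n - i0 < 16:
        raise ValueError("trajectory too short to classify")
    tau = traj.tau[i0:]
    r = traj.r[i0:]
    th = traj.theta[i0:]

    v_th = np.empty(len(tau), dtype=complex)
    for i in range(len(tau)):
        v_th[i] = velocities(traj.eigenfunction, r[i], th[i], traj.phi[i0 + i])[1]
    L_series = r**2 * v_th

    def window_mean(fraction):
        j = int(len(tau) * (1 - fraction))
        t, series = tau[j:], L_series[j:]
        return np.trapezoid(series, t) / (t[-1] - t[0])

    full, half = window_mean(1.0), window_mean(0.5)
    scale = max(abs(full), 0.5)
    if abs(full - half) / scale > stability_tol:
        raise ValueError(
            f"angular average not converged: window mean moved by "
            f"{abs(full - half) / scale:.2%} on halving; integrate longer")

    dthR = (th[-1].real - th[0].real) / (tau[-1] - tau[0])
    total_drift = th[-1].real - th[0].real
    if abs(total_drift) < max(1.0, 0.1 * np.ptp(th.real)):
        region = "Omega0"
    else:
        region = "Omega+" if total_drift > 0 else "Omega-"
    return SpinClassification(region=region, mean_dthetaR=float(dthR),
                              L_theta_mean=complex(full),
                              L_phi_mean=float(traj.eigenfunction.state.mJ))


def compare_spin_branches(source, n: int = 0, J: int = 0, mJ: int = 0,
                          theta0: complex = math.pi / 2 + 3j,
                          tau_max: float = 250.0) -> dict:
    """Integrate the P- and Q-branch angular dynamics from the same start.

    Returns the two classifications; the mean real polar velocities are
    anti-parallel — the second-kind branch is the anti-spin partner.
    """
    from .eigensystem import make_eigenfunction
    out = {}
    for branch in ("first_kind", "second_kind"):
        f = make_eigenfunction(source, QuantumState(n, J, mJ, branch=branch))
        traj = spin_trajectory(f, theta0, tau_max)
        out[branch] = classify_spin(traj)
    return out


# ---------------------------------------------------------------------------
# rotational spectra
# ---------------------------------------------------------------------------

def rigid_spectrum(c: DerivedConstants, J_max: int) -> np.ndarray:
    """Rigid-rotor lines ``nu(J -> J+1) = 2 B_bar (J+1)``, J = 0..J_max, cm^-1."""
    J = np.arange(J_max + 1)
    return 2.0 * c.B_bar * (J + 1)


def nonrigid_spectrum(c: DerivedConstants, J_max: int) -> np.ndarray:
    """Centrifugally distorted lines ``2 B_bar (J+1) - 4 D_bar (J+1)^3``, cm^-1."""
    J = np.arange(J_max + 1)
    return 2.0 * c.B_bar * (J + 1) - 4.0 * c.D_bar * (J + 1) ** 3


def _rotational_energy_qhm(p: MoleculeParams, c: DerivedConstants, J: int) -> float:
    """Classical rotational energy with trajectory-mean momentum, J (joule).

    ``E_R = ((J + 1/2) hbar)^2 / (2 M r_J^2)`` with the J-dependent
    equilibrium bond length from the ground-vibrational radial dynamics.
    """
    pk = pekeris_constants(QuantumState(0, J), c)
    r_J = equilibrium_bond_length(QuantumState(0, J), pk) / p.beta  # metres
    L = (J + 0.5) * CODATA.hbar
    return L**2 / (2.0 * p.M * r_J**2)


def qhm_spectrum(p: MoleculeParams, c: DerivedConstants, J_max: int) -> np.ndarray:
    """Trajectory-model lines ``(E_R(J+1) - E_R(J)) / hc``, J = 0..J_max, cm^-1."""
    E = np.array([_rotational_energy_qhm(p, c, J) for J in range(J_max + 2)])
    return np.diff(E) / (CODATA.h * CODATA.c)


def fit_rotational_constants(nu_measured, J_lower=None) -> tuple[float, float]:
    """Least-squares ``(B_bar*, D_bar*)`` from measured lines.

    Ordinary least squares of ``nu`` on the design functions ``2 (J+1)`` and
    ``-4 (J+1)^3`` of the distorted-rotor model.
    """
    nu = np.asarray(nu_measured, dtype=float)
    J = np.arange(len(nu)) if J_lower is None else np.asarray(J_lower)
    X = np.column_stack([2.0 * (J + 1), -4.0 * (J + 1.0) ** 3])
    coef, *_ = np.linalg.lstsq(X, nu, rcond=None)
    return float(coef[0]), float(coef[1])


def spectrum_table(p: MoleculeParams, measured=None, J_max: int | None = None,
                   c: DerivedConstants | None = None) -> pd.DataFrame:
    """Side-by-side model comparison table for the J -> J+1 lines.

    Columns: ``J_lower, nu_rigid_cm1, nu_nonrigid_cm1, nu_qhm_cm1`` plus,
    when measured lines are supplied, ``nu_exp_cm1``, per-model relative
    errors, and the least-squares refit column ``nu_fit_cm1``.
    """
    if c is None:
        c = derive_constants(p)
    if measured is not None:
        measured = list(measured)
        if J_max is None:
            J_max = len(measured) - 1
    elif J_max is None:
        J_max = 8
    J = np.arange(J_max + 1)
    df = pd.DataFrame({
        "J_lower": J,
        "nu_rigid_cm1": rigid_spectrum(c, J_max),
        "nu_nonrigid_cm1": nonrigid_spectrum(c, J_max),
        "nu_qhm_cm1": qhm_spectrum(p, c, J_max),
    })
    if measured is not None:
        df["nu_exp_cm1"] = measured
        B_fit, D_fit = fit_rotational_constants(measured, J)
        df["nu_fit_cm1"] = 2.0 * B_fit * (J + 1) - 4.0 * D_fit * (J + 1.0) ** 3
        for model in ("rigid", "nonrigid", "qhm", "fit"):
            df[f"rel_error_{model}"] = np.abs(df[f"nu_{model}_cm1"] - df["nu_exp_cm1"]) \
                / df["nu_exp_cm1"]
        df.attrs["B_fit_cm1"] = B_fit
        df.attrs["D_fit_cm1"] = D_fit
    return df
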