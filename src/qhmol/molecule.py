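"""Diatomic molecule parameters, dimensionless scaling and derived constants.

A diatomic bond is modelled by a Morse potential with equilibrium length
``r0``, width parameter ``beta`` and dissociation energy ``E_D``, felt by a
single effective particle of reduced mass ``M``.  All of the internal
dynamics in this package is carried out in the dimensionless variables

    r_tilde = beta * r          (dimensionless internuclear distance)
    tau     = t * hbar * beta**2 / M   (dimensionless time)

so that the natural energy unit is ``hbar**2 * beta**2 / (2 M) = E_D / lam**2``
with ``lam = sqrt(2 M E_D) / (hbar beta)`` the dimensionless Morse depth
(the number of bound states is roughly ``lam - 1/2``).

Four reference molecules (H2, HCl, O2, N2) ship as built-in fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .constants import CODATA, PhysicalConstants

__all__ = [
    "MoleculeParams",
    "DerivedConstants",
    "FIXTURES",
    "EXPERIMENTAL_FREQ_HZ",
    "load_molecule",
    "derive_constants",
    "to_dimensionless",
    "from_dimensionless",
]


@dataclass(frozen=True)
class MoleculeParams:
    """Physical parameters of one diatomic molecule (SI units).

    Attributes
    ----------
    name : str
        Label, e.g. ``"HCl"``.
    r0 : float
        Equilibrium bond length of the Morse potential, metres.
    M : float
        Reduced mass ``M_A M_B / (M_A + M_B)``, kg.
    beta : float
        Morse width parameter, 1/m.
    E_D : float
        Dissociation energy (Morse well depth), J.
    """

    name: str
    r0: float
    M: float
    beta: float
    E_D: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("molecule name must be nonempty")
        for field in ("r0", "M", "beta", "E_D"):
            value = getattr(self, field)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"parameter {field!r} must be a finite number")
            if value <= 0:
                raise ValueError(f"parameter {field!r} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DerivedConstants:
    """Dimensionless groups and spectroscopic constants derived from a molecule.

    Attributes
    ----------
    lam : float
        Dimensionless Morse depth ``sqrt(2 M E_D) / (hbar beta)``.
    b : float
        Dimensionless equilibrium position ``beta * r0``.
    time_scale : float
        Seconds per dimensionless time unit, ``M / (hbar beta**2)``.
    B_bar : float
        Rigid-rotor rotational constant ``hbar**2 / (2 h c M r0**2)``, cm^-1.
    D_bar : float
        Centrifugal distortion constant
        ``(hbar**2 / (4 b I0))**2 / (h c E_D)`` with ``I0 = M r0**2 / 2``, cm^-1.
    """

    lam: float
    b: float
    time_scale: float
    B_bar: float
    D_bar: float

    def __post_init__(self) -> None:
        if self.lam <= 0.5:
            raise ValueError(f"lam = {self.lam} <= 1/2: the well supports no bound state")
        for field in ("b", "time_scale", "B_bar", "D_bar"):
            if getattr(self, field) <= 0:
                raise ValueError(f"derived constant {field!r} must be positive")

    @property
    def energy_unit(self) -> float:
        """Energy per dimensionless unit, ``hbar**2 beta**2 / (2 M)`` in J."""
        return CODATA.hbar / (2.0 * self.time_scale)


#: Built-in molecule fixtures.  Values are the conventional parameter sets for
#: the four homo/heteronuclear test molecules (bond length, reduced mass,
#: Morse width and well depth).
FIXTURES: dict[str, MoleculeParams] = {
    "H2": MoleculeParams("H2", r0=74e-12, M=0.837e-27, beta=1.94e10, E_D=7.11e-19),
    "HCl": MoleculeParams("HCl", r0=127.5e-12, M=1.628e-27, beta=1.81e10, E_D=7.39e-19),
    "O2": MoleculeParams("O2", r0=148e-12, M=13.28e-27, beta=2.67e10, E_D=8.28e-19),
    "N2": MoleculeParams("N2", r0=145e-12, M=11.63e-27, beta=2.70e10, E_D=15.77e-19),
}

#: Measured ground-state vibration frequencies, Hz, for the fixture molecules.
EXPERIMENTAL_FREQ_HZ: dict[str, float] = {
    "H2": 12470e10,
    "HCl": 8652e10,
    "O2": 4666e10,
    "N2": 6987e10,
}

_CONFIG_KEYS = {
    "r0_m": "r0",
    "reduced_mass_kg": "M",
    "beta_per_m": "beta",
    "E_D_J": "E_D",
}


def load_molecule(source: str | Path | MoleculeParams) -> MoleculeParams:
    """Resolve a molecule from a fixture name or a YAML-style config file.

    Parameters
    ----------
    source
        One of the fixture names (``"H2"``, ``"HCl"``, ``"O2"``, ``"N2"``),
        a path to a config file with keys ``name, r0_m, reduced_mass_kg,
        beta_per_m, E_D_J`` (SI units), or an already-built
        :class:`MoleculeParams` (returned unchanged).
    """
    if isinstance(source, MoleculeParams):
        return source
    if isinstance(source, str) and source in FIXTURES:
        return FIXTURES[source]
    path = Path(source)
    if not path.exists():
        raise ValueError(
            f"unknown molecule {source!r}: not a fixture ({', '.join(sorted(FIXTURES))}) "
            "and no such config file"
        )
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping of parameter keys to values")
    kwargs: dict[str, float | str] = {}
    for key, field in _CONFIG_KEYS.items():
        if key not in raw:
            raise ValueError(f"config {path} is missing required key {key!r}")
        kwargs[field] = float(raw[key])
    kwargs["name"] = str(raw.get("name", path.stem))
    return MoleculeParams(**kwargs)  # type: ignore[arg-type]


def derive_constants(p: MoleculeParams, const: PhysicalConstants = CODATA) -> DerivedConstants:
    """Compute the dimensionless groups and spectroscopic constants.

    ``lam = sqrt(2 M E_D)/(hbar beta)`` sets the well depth in units of the
    natural energy scale; ``B_bar`` and ``D_bar`` are the rigid-rotor and
    centrifugal-distortion constants in cm^-1, computed with the moment of
    inertia ``I0 = M r0**2 / 2`` convention (so ``B_bar = hbar**2/(4 h c I0)``).
    """
    lam = math.sqrt(2.0 * p.M * p.E_D) / (const.hbar * p.beta)
    b = p.beta * p.r0
    time_scale = p.M / (const.hbar * p.beta**2)
    I0 = p.M * p.r0**2 / 2.0
    B_bar = const.hbar**2 / (4.0 * const.h * const.c * I0)
    D_bar = (const.hbar**2 / (4.0 * b * I0)) ** 2 / (const.h * const.c * p.E_D)
    return DerivedConstants(lam=lam, b=b, time_scale=time_scale, B_bar=B_bar, D_bar=D_bar)


def to_dimensionless(p: MoleculeParams, r_m=None, t_s=None, const: PhysicalConstants = CODATA):
    """Map physical ``(r [m], t [s])`` to dimensionless ``(r_tilde, tau)``.

    Either argument may be omitted; complex values are accepted (complex
    trajectories live at complex internuclear distance).  Returns a tuple with
    ``None`` in the position of any omitted argument.
    """
    r_tilde = None if r_m is None else p.beta * r_m
    tau = None if t_s is None else t_s * const.hbar * p.beta**2 / p.M
    return r_tilde, tau


def from_dimensionless(p: MoleculeParams, r_tilde=None, tau=None, const: PhysicalConstants = CODATA):
    """Inverse of :func:`to_dimensionless`."""
    r_m = None if r_tilde is None else r_tilde / p.beta
    t_s = None if tau is None else tau * p.M / (const.hbar * p.beta**2)
    return r_m, t_s
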