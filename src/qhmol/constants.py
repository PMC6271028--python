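"""Physical constants (CODATA 2018, exact SI where defined)."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used throughout, in SI with c in cm/s.

    The speed of light is kept in cm/s because rotational spectroscopy
    reports line positions as wavenumbers in cm^-1 (E / hc).
    """

    hbar: float = 1.054571817e-34  # J s
    h: float = 6.62607015e-34      # J s
    c: float = 2.99792458e10       # cm/s


CODATA = PhysicalConstants()
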