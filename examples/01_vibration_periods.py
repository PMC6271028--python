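"""Ground-state vibration periods and frequencies for four diatomics.

For each molecule the dimensionless Morse depth lambda is computed from
(M, beta, E_D), then the vibration period by the residue closed form
T = 4 pi / (2 lambda - 1) and by the force-constant relation 2 pi sqrt(M/K);
the dimensional frequency f = 1/(T * M / (hbar beta^2)) is compared with the
measured fundamental.  A ~1% discrepancy with experiment reflects the
second-order (Pekeris) radial solution, not the trajectory method.
"""

import qhmol as q

for name in ("H2", "HCl", "O2", "N2"):
    p = q.load_molecule(name)
    c = q.derive_constants(p)
    rep = q.frequency_report(p, f_exp=q.EXPERIMENTAL_FREQ_HZ[name])
    print(f"{name:4s} lambda={c.lam:9.4f}  T={rep.T_residue:.4f} "
          f"(force-constant route {rep.T_force_constant:.4f})  "
          f"T={rep.T_dimensional*1e15:6.3f} fs  f={rep.f:.4g} Hz  "
          f"vs exp {rep.f_exp:.4g} Hz ({rep.rel_error:.2%})")
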