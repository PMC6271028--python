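"""Shell structure of the state-dependent total potential.

For vibrational quantum number n the total potential V_Total = V_Morse + Q
splits into n + 1 shells separated by infinite barriers at the wavefunction
nodes; each shell bottoms out exactly at the eigenvalue E_nJ, at the shell's
equilibrium bond length.  Writes a CSV of V_Total(r) curves for n = 0, 1, 2.
"""

import numpy as np
import pandas as pd

import qhmol as q

p = q.load_molecule("HCl")
c = q.derive_constants(p)
rows = {}
r = np.linspace(1.6, 3.4, 600)
for n in (0, 1, 2):
    state = q.QuantumState(n, 0)
    pk = q.pekeris_constants(state, c)
    f = q.Eigenfunction(state, pk, c, params=p)
    eq = q.find_equilibria(state, pk)
    E = q.eigenenergy(state, c).E
    v = np.array([np.real(q.total_potential(f, ri)) for ri in r])
    rows[f"V_total_n{n}_J"] = v
    print(f"n={n}: {len(eq.z_values)} shells, nodes at z = "
          f"{[round(z, 2) for z in eq.nodes]}, "
          f"equilibria r = {[round(x, 4) for x in eq.r_values]} "
          f"(shell minima = E_nJ = {E:.4e} J)")

df = pd.DataFrame({"r_dimensionless": r, **rows})
df.to_csv("total_potential_shells.csv", index=False)
print("wrote total_potential_shells.csv", df.shape)
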