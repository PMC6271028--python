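"""Quantization laws along complex trajectories.

Along any trajectory of an eigenstate the energy, squared angular momentum
and z-component angular momentum are constant and quantized: H = E_nJ,
L^2 = J(J+1) hbar^2, L_z = mJ hbar — here verified on a radial contour of
the ground state and an angular trajectory of (n,J,mJ) = (0,1,0).
"""

import math

import numpy as np

import qhmol as q

hbar = q.CODATA.hbar

for state, kind in [(q.QuantumState(0, 0, 0), "radial"), (q.QuantumState(0, 1, 0), "angular")]:
    f = q.make_eigenfunction("H2", state)
    if kind == "radial":
        r_eq = q.equilibrium_bond_length(state, f.pk)
        traj = q.integrate_trajectory(f, (r_eq + 0.1, math.pi / 2, 0.0), 2.0)
    else:
        traj = q.spin_trajectory(f, math.pi / 2 - 2j, 30.0)
    cq = q.conserved_quantities(f, traj)
    E = q.eigenenergy(state, f.constants).E
    print(f"(n,J,mJ)=({state.n},{state.J},{state.mJ}) {kind} trajectory:")
    print(f"  H   = {np.mean(cq.H.real):.6e} J  (E_nJ = {E:.6e}; drift {cq.H_drift:.1e})")
    print(f"  L^2 = {np.mean(cq.L2.real)/hbar**2:.6f} hbar^2  "
          f"(J(J+1) = {state.J*(state.J+1)}; drift {cq.L2_drift:.1e})")
    print(f"  L_z = {np.mean(cq.Lz.real)/hbar:.6f} hbar  (mJ = {state.mJ})")
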