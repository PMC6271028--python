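"""Closed complex radial contours and the trajectory-route period.

The H2 ground-state bond coordinate, integrated under the state-dependent
equations of motion from three different starting offsets, circulates on
closed contours around the equilibrium bond length.  The Poincare-section
period is the same for every contour (the velocity field has a single
enclosed zero, so the contour integral is fixed by its residue) and matches
the closed form 4 pi / (2 lambda - 1).
"""

import math

import qhmol as q

state = q.QuantumState(0, 0, 0)
f = q.make_eigenfunction("H2", state)
r_eq = q.equilibrium_bond_length(state, f.pk)
T_res = q.period_residue(state, f.pk)
print(f"equilibrium bond length r_eq = {r_eq:.4f} (dimensionless), "
      f"residue period T = {T_res:.6f}")

for delta in (0.05, 0.1, 0.2):
    traj = q.integrate_trajectory(f, (r_eq + delta, math.pi / 2, 0.0), 6 * T_res)
    T = q.period_from_trajectory(traj, r_eq=r_eq)
    width = traj.r.real.max() - traj.r.real.min()
    height = traj.r.imag.max() - traj.r.imag.min()
    print(f"  start r_eq+{delta:4.2f}: contour {width:.3f} x {height:.3f}, "
          f"period {T:.6f} ({traj.termination}, {len(traj.tau)} steps)")
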