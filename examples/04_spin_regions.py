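"""Spin from the remnant angular motion of a J = 0 state.

With J = mJ = 0 the orbital angular momentum vanishes, yet the complex
polar-angle dynamics retains three regimes: drifting trajectories in the
upper/lower half-planes carrying mean angular momentum -/+ hbar/2 (spin
down/up), and periodic spinless motion near the real axis.  The second-kind
(Legendre Q) angular branch reverses the drift: the anti-spin partner
sub-state.  For J = 1 the drift carries (J + 1/2) hbar = 3/2 hbar.
"""

import math

import qhmol as q

f = q.make_eigenfunction("H2", q.QuantumState(0, 0, 0))
for theta0, label in [(math.pi / 2 + 3j, "Im theta = +3"),
                      (math.pi / 2 - 3j, "Im theta = -3"),
                      (math.pi / 2 + 0.3, "real start   ")]:
    cls = q.classify_spin(q.spin_trajectory(f, theta0, 250.0))
    print(f"(0,0,0) {label}: {cls.region:7s} <L_theta> = {cls.L_theta_mean.real:+.4f} hbar")

f1 = q.make_eigenfunction("H2", q.QuantumState(0, 1, 0))
cls = q.classify_spin(q.spin_trajectory(f1, math.pi / 2 - 3j, 150.0))
print(f"(0,1,0) Im theta = -3: {cls.region:7s} <L_theta> = {cls.L_theta_mean.real:+.4f} hbar "
      "(orbital hbar + spin hbar/2)")

branches = q.compare_spin_branches("H2", 0, 0, 0, theta0=math.pi / 2 + 3j, tau_max=250.0)
print("P vs Q branch mean polar drift:",
      f"{branches['first_kind'].mean_dthetaR:+.4f}",
      f"{branches['second_kind'].mean_dthetaR:+.4f}  (anti-parallel)")
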