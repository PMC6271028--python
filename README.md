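# qhmol

Complex quantum trajectories for diatomic molecules: state-dependent
vibration, rotation and spin from quantum Hamilton mechanics.

## The problem

Trajectory pictures of molecular motion are the bridge between molecular
mechanics and quantum mechanics, but the standard (real-valued) Bohmian
velocity field vanishes in every stationary state with zero angular momentum
— the molecule "stands still", and no vibration period, bond-length
distribution or spin can be read off a trajectory.  `qhmol` implements the
complex-trajectory alternative: writing the action as `S = -iħ ln Ψ` makes
the canonical momenta

```
p_q = ∂S/∂q = -iħ ∂(ln Ψ)/∂q,        q = (r, θ, φ),
```

complex, and Hamilton's equations `dq/dt = ∂H_Ψ/∂p` generate a non-trivial
velocity field on every eigenstate.  For a diatomic bond modelled by a Morse
potential (depth `E_D`, width `β`, equilibrium length `r₀`, reduced mass
`M`), the rovibrational eigenfunctions `Ψ_{nJm} = R_{nJ}(r) Θ_{Jm}(θ) e^{imφ}`
are analytic (Pekeris reduction of the centrifugal term), so the whole
dynamics is closed-form:

- the bond coordinate circulates on **closed contours** in the complex
  `r`-plane around the equilibrium bond length
  `r_eq = b - ln(α/2η)` (dimensionless, `b = βr₀`), with a period fixed by
  the residue theorem — `T = 4π/(2λ-1)` for the ground state, where
  `λ = √(2ME_D)/(ħβ)` is the dimensionless Morse depth;
- along any trajectory `H = E_{nJ}`, `L² = J(J+1)ħ²`, `L_z = m_Jħ` — the
  quantization laws hold dynamically, not just spectrally;
- with `J = m_J = 0` a remnant complex polar motion survives, carrying mean
  angular momentum `±ħ/2`: a trajectory-level picture of spin, with the
  second-kind (Legendre Q) angular branch as the anti-spin partner and
  `(J + 1/2)ħ` in rotating states;
- the `J`-dependent bond stretch `r_J` plus the trajectory-mean angular
  momentum give a rotational spectrum
  `ν(J→J+1) = [E_R(J+1) - E_R(J)]/hc`, `E_R = ((J+½)ħ)²/(2Mr_J²)`, that
  tracks the measured HCl far-infrared lines more closely than the
  centrifugally distorted rotor `ν = 2B̄(J+1) - 4D̄(J+1)³` built from the
  same parameters.

The intended audience is anyone studying trajectory formulations of quantum
mechanics (complex Bohmian dynamics, quantum Hamilton–Jacobi methods) or
teaching rovibrational spectroscopy with an explicit dynamical model.

## Worked example

```python
import math, qhmol as q

state = q.QuantumState(0, 0, 0)              # ground rovibrational state
f = q.make_eigenfunction("H2", state)        # analytic eigenfunction layer
r_eq = q.equilibrium_bond_length(state, f.pk)
traj = q.integrate_trajectory(f, (r_eq + 0.1, math.pi/2, 0.0), tau_max=2.4)
print(q.period_from_trajectory(traj, r_eq=r_eq))   # 0.38398755375531685
print(q.frequency_report(q.load_molecule("H2")).f) # 123491485518876.81

cls = q.classify_spin(q.spin_trajectory(f, math.pi/2 + 3j, 250.0))
print(cls.region, cls.L_theta_mean.real)  # Omega- -0.5000195428387487

p = q.load_molecule("HCl")
print(q.qhm_spectrum(p, q.derive_constants(p), 8)[[0, 8]])
# [ 20.79370129 183.94082309]   cm^-1  (measured: 20.88, 186.23)
```

The printed period `0.38399` is the dimensionless vibration period of H₂
(about 8.10 fs, i.e. a 123.5 THz fundamental, within 1% of the measured
124.7 THz); `Omega-` with `⟨L_θ⟩ = -ħ/2` is the spin-down region of the
complex polar dynamics; the two wavenumbers are the first and last lines of
the HCl rotational series under the trajectory model.

Longer narrative scripts live in `examples/` (one per capability), and a
thin CLI exposes the same computations from a shell:

```
qhmol table1            # vibration table for the four fixture molecules
qhmol table2            # HCl spectrum under all models vs measured lines
qhmol period H2         # three-route period cross-check
qhmol spin H2 --theta-im 3
qhmol equilibria HCl -n 1
```

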