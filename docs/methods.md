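# Methods

## Model

A diatomic molecule is reduced to a single effective particle of reduced
mass `M = M_A M_B/(M_A+M_B)` moving in a Morse potential
`V(r) = E_D (e^{-2β(r-r₀)} - 2 e^{-β(r-r₀)})` (minimum `-E_D` at `r₀`,
dissociation limit 0; spectra are energy differences, so the offset is
unobservable).  Internally everything is dimensionless: `r̃ = βr`,
`τ = t ħβ²/M`, energy unit `E_u = ħ²β²/2M = E_D/λ²`, with
`λ = √(2ME_D)/(ħβ)` the Morse depth and `b = βr₀`.  Physical units appear
only at the I/O boundary.

### Eigensystem (Pekeris reduction)

The radial equation with the centrifugal term `Γ/r̃²` (`Γ = J(J+1)`) is made
analytic by expanding `1/r̃²` to second order in `e^{-(r̃-b)}` about the well:
`1/r̃² ≈ (c₀ + c₁e^{-x} + c₂e^{-2x})/b²` with `c₀ = 1 - 3/b + 3/b²`,
`c₁ = 4/b - 6/b²`, `c₂ = 3/b² - 1/b`, `x = r̃ - b`.  Collecting exponentials
gives an effective Morse problem with
`A = λ² + Γc₂/b²`, `B = 2λ² - Γc₁/b²`, and in `z = 2η e^{-x}`, `η = √A`:

```
u_{nJ}(z) = e^{-z/2} z^{α/2} L_n^α(z),    α = B/√A - 2n - 1,
E_{nJ}    = E_u [ Γc₀/b² - (α/2)² ].
```

At `J = 0` this is the exact Morse solution (`α = 2λ-2n-1`, `η = λ`).  The
closed-form eigenvalues were cross-checked against finite-difference
eigensolves of both the reduced operator (agreement ~1e-7, grid-limited) and
the exact `1/r̃²` operator (~1e-7 at `J ≤ 1`, ~5e-7 at `J = 5` for HCl —
the truncation error of the expansion).  Accuracy degrades with growing `J`
as the centrifugal expansion is stretched; this is inherited by every
`J`-dependent observable and is the known, expected error source of the
whole scheme.

The angular factor is `Θ = B₁P_J^m(cos θ) + B₂Q_J^m(cos θ)`.  Because the
dynamics needs `Θ` at complex `θ` and no installed library evaluates
second-kind associated Legendre functions off the real axis, closed forms
are generated symbolically (sympy) once per `(J, m, kind)` and compiled to
numpy callables, including first and second `θ`-derivatives.

**Branch choice for Q.**  `Q_J` is taken on the complex plane cut along
`[-1, 1]` — the branch decaying like `z^{-(J+1)}` — via
`Q₀ = ½ log((z+1)/(z-1))` with the principal logarithm.  As a function of
`θ` this is analytic in each half-plane `Im θ ≷ 0` and discontinuous only
across the real axis.  This choice is what makes the second-kind branch the
*anti-spin* partner: with it, the drifting polar trajectories carry mean
angular momentum `∓(J+½)ħ` with the sign opposite to the first-kind branch
at the same side of the complex plane.  The naive analytic continuation in
`θ` of the real-axis Ferrers function instead reduces asymptotically to
first-kind behaviour and produces no anti-parallel dynamics; it is not used.
(On real `θ` the principal-branch limit differs from the Ferrers `Q` by an
additive multiple of the first-kind solution — still an angular solution,
and immaterial off the axis where the spin regions live.)  For `m > 0` the
Hobson prefactor `(z²-1)^{m/2}` uses the principal power; its logarithmic
derivative is rational and single-valued, so the dynamics never sees a cut.

### Dynamics

Canonical momenta are `p_q = -i ∂(ln Ψ)/∂q` (dimensionless).  The velocity
field, from `dq/dτ = ∂H_Ψ/∂p` in spherical coordinates:

```
dr̃/dτ = -i d ln(r̃R)/dr̃          (rational in z — branch-free)
dθ/dτ  = -(i/r̃²) (d ln Θ/dθ + cot θ / 2)
dφ/dτ  = m_J / (r̃² sin²θ)
```

All right-hand sides are built from analytic logarithmic derivatives; no
numerical differentiation of `Ψ` anywhere.  The radial log-derivative is a
rational function of `z` (entire and nonvanishing in `r̃`), so integration
never crosses a branch cut; the radial *value* `z^{α/2}` uses the principal
branch, valid for `|Im r̃| < π` — far beyond any contour the dynamics visits.

Diagnostics `H`, `L²`, `L_z` are evaluated pointwise from independently
compiled second derivatives (not from the eigen-ODE identity, which would be
circular).  `H` uses the exact centrifugal term: on the `J = 0` states it
equals `E_{n,0}` to machine precision; for `J > 0` it differs from `E_{nJ}`
by the Pekeris truncation (relative ~1e-9 near equilibrium for HCl/H₂ at
small `J`), which is the honest figure of merit of the eigenfunction.

`V_Total = V_eff + Q` is evaluated as `E_{nJ} - T(q)` with `T` the classical
kinetic energy on the velocity field — the closed form the eigenstate
implies.  Its per-shell minima sit exactly at the trajectory equilibria and
equal `E_{nJ}`; generalized forces are the analytic gradient
`-∂V_Total/∂q`, so the zero-force, zero-velocity, potential-minimum and
probability-maximum points coincide identically (verified numerically to
root-finder accuracy, ~1e-11).

### Integration

`scipy.integrate.solve_ivp` with DOP853 on the real/imaginary split of the
complex system; defaults `rtol = 1e-10`, `atol = 1e-12` (periods resolved to
well past 4 significant figures; halving the tolerance moves the measured
period by <1e-6 relative).  Singularity guards terminate — and flag — a run
when the speed exceeds 1e6 (wavefunction-node or axis approach) or
`|sin θ| < 1e-8`; the partial trajectory is returned with the reason.

Periods are measured on the Poincare section `Im r̃ = 0`, upward crossings
with `Re r̃ > r̃_eq`, refined by bisection on the dense output; the first
cycle is discarded against start-up bias and cycles 2–4 averaged.  Default
contours start at `r̃_eq + δ`, `δ ∈ {0.05, 0.1, 0.2}`; the measured period is
contour-independent to <1e-3 (residue theorem: the field has one enclosed
zero).

### Spin classification and averaging

Polar trajectories run with the bond at its equilibrium length (a fixed
point of the radial flow, so the motion stays angular).  The mean
`θ`-direction angular momentum is the time average of `r̃² dθ/dτ` (units of
`ħ`) after discarding the first 10% of the run; the average must be stable
to 1% when the window is halved, otherwise the run is reported too short.
Regions: `Ω∓` for monotone real-part drift (|Δθ_R| > max(1, 0.1 × span)
over the window), `Ω₀` otherwise.  The sign convention `Ω₊ ↔ s = +½`
follows the geometric assignment (drift up at `Im θ ≪ 0`); it is a
convention, documented rather than derived.  With starts at `|Im θ| = 3`
the asymptotic relations hold to `e^{-2|Im θ|} ≈ 0.25%`, comfortably inside
the 1% assertion band.

### Spectra

- rigid rotor: `ν = 2B̄(J+1)`, `B̄ = ħ²/(2hcMr₀²)`;
- distorted rotor: `ν = 2B̄(J+1) - 4D̄(J+1)³`,
  `D̄ = (ħ²/(4bI₀))²/(hcE_D)`, `I₀ = Mr₀²/2`;
- trajectory model: `E_R(J) = ((J+½)ħ)²/(2Mr_J²)` with `r_J` from the
  ground-vibrational equilibrium at each `J`; `ν = ΔE_R/hc`.

The `(J+½)ħ` entering `E_R` is the closed-form value of the trajectory mean;
the test suite separately confirms integrated trajectories reproduce it to
1%.  A least-squares refit of `(B̄, D̄)` on measured lines (design functions
`2(J+1)`, `-4(J+1)³`) is reported for comparison but never asserted — the
fit procedure is a choice, not a model output.  Note the distorted-rotor
line positions are *not* the eigenvalue differences of the Pekeris
eigensystem: the latter carry the vibration–rotation coupling (an effective
`B₀ < B̄`, ~1.6% for HCl) and land closer to the measured lines; the
distorted rotor is kept as the standard textbook comparator built from
equilibrium constants.

## Parameters and defaults

| parameter | meaning | default / unit |
|---|---|---|
| `r0, M, beta, E_D` | Morse/bond parameters | SI (m, kg, 1/m, J); four fixtures built in |
| `rtol, atol` | integrator tolerances | 1e-10 / 1e-12 |
| `tau_max` | integration span | 6 periods (vibration), 150–250 (spin means) |
| `discard` | transient fraction dropped in averages | 0.1 |
| `node_rtol` | relative node-proximity guard | 1e-12 |
| constants | CODATA 2018 (`ħ = 1.054571817e-34 J·s`) | fixed |

Reference tabulations of `λ` computed with rounded constants differ from the
CODATA recomputation in the 3rd–4th digit; all comparisons against such
printed values use 0.5% relative tolerance.

## Degenerate inputs and edge cases

Nonpositive molecular parameters, `|m_J| > J`, states beyond the bound
ladder (`α ≤ 0`) and the all-zero mixed angular branch are rejected with
named errors.  Evaluation at wavefunction nodes or on the polar axis raises
a singularity error identifying the coordinate.  Trajectories that fail to
close (too-short runs) or whose angular averages have not converged raise
rather than return biased numbers.

## Scope and limitations

- The eigensystem is the second-order Pekeris reduction: no exact
  rotating-Morse solver, no continuum states; accuracy decays with `J`
  (visible as the growing error of the trajectory-model spectrum at high
  `J`).
- Real-axis-only Bohmian propagation is kept as a diagnostic decomposition
  (`Re p = ∂S_B`, `Im p = -∂ ln R_B`), not a production mode.
- One molecule at a time; no many-electron or condensed-phase machinery, no
  line intensities or hyperfine structure, and no claim that the
  spin-region labels correspond to measured spin states beyond the
  half-integer mean momenta the trajectories carry.
- Problem sizes are desk-scale by construction: single ODE trajectories of
  1e2–1e4 steps and 9-line spectra; the full test suite and the acceptance
  script each run in well under a minute of CPU for the dynamics parts.
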