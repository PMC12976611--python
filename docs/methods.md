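# Methods

## Model and assumptions

The solver treats axisymmetric flow of an incompressible Carreau fluid
in the annular gap between a rigid catheter (dimensionless radius
`ε`) and a compliant outer tube carrying a travelling sinusoidal wave,
`r₂ = 1 + φ sin 2π(z − t)`, in the frame moving with the wave.
Assumptions inherited by every downstream quantity:

- **Long wavelength, low Reynolds number.** Axial diffusion, radial
  momentum and all inertial terms are dropped; each `(z, t)` station is
  an independent quasi-static radial problem. No time-stepping exists
  anywhere in the pipeline — `z` and `t` are free section labels, and
  all fields depend on them only through the phase `z − t`.
- **Compliant wall.** The axial pressure gradient is identified with
  the fifth-order elastic-wall operator applied to the wall shape.
  For the travelling sinusoid this has the exact closed form (used
  analytically; finite differences appear only in tests)

      E(z,t) = φ[((2π)⁵e₁ + (2π)³e₂ − (2π)³e₃ + 2π e₅) cos θ
               + (2π)² e₄ sin θ],   θ = 2π(z − t).

  The coefficient assignment follows the operator position: `e₄` is
  viscous damping (`∂²/∂z∂t`), `e₅` spring stiffness (`∂/∂z`).
- **Truncated Reynolds viscosity.** The perturbation path uses
  `M(H) = 1 − αH` exactly; the exponential law `e^(−αH)` is available
  only in the nonlinear oracle (`--law exponential`), where the
  difference is demonstrably `O(α²)`.
- **Carreau stress.** Only the `S_rz` component survives the reduction:
  `S_rz = M(H)(1 + κ We² u₃′²) u₃′`, `κ = (n−1)/2`.

## Closed-form scalar fields

Temperature solves a modified-Helmholtz radial problem; the
implementation uses the real modified-Bessel pair `I₀/K₀` with decay
constant `A = √(Ω/β)`, `β = 1/Pr + 4/(3Rn)`, and the exact log-profile
limit at `Ω = 0` (the two agree to 1e−5 already at `Ω = 1e−8`).
Derivatives are analytic (`I₀′ = A I₁`, `K₀′ = −A K₁`; the second
derivative comes from the ODE itself), because they feed the velocity
forcing and must be smooth. Concentration exploits that `ξ + S₁S₂H` is
radially harmonic, so `ξ = c_log ln r + c_const − S₁S₂ H` with both
constants fixed by the wall values. Correctness is enforced by residual
tests (≤ 1e−8 pointwise) and an independent collocation BVP oracle.

## Velocity: flux-form double perturbation

Substituting `u₃ = (u₃₀₀ + αu₃₀₁) + We²(u₃₁₀ + αu₃₁₁)` into the flux
balance and collecting orders gives first-order (flux) equations for
the shear of each order:

    v₀ = G/r + C₀/r                                   O(1)
    v₁ = H v₀ + C₁/r                                  O(α)
    v₂ = −κ v₀³ + C₂/r                                O(We²)
    v₃ = H v₂ − 3κ v₀² v₁ + κ H v₀³ + C₃/r            O(We² α)

with `G(r) = ∫ε..r s F₀(s) ds`, `F₀ = E − G₁H − G₂ξ`. Each order is a
single cumulative quadrature from the inner wall plus one affine
constant `Cₖ` fixed by the outer-wall condition (`u₃₀₀ = −1`,
corrections zero, at both walls). This avoids discretising second
derivatives entirely: accuracy is set by the composite-Simpson rule on
the radial grid (default N = 257; Richardson tests measure clean 4th
order and ≤ 1e−8 at the default grid). `n = 1` (or `We = 0`) makes the
`We²` content vanish identically; `α = 0` removes the `α` content by
assembly.

## Nonlinear validation oracle

A genuinely independent code path solves the *unexpanded* balance
`r M(H) (u′ + κWe² u′³) = G(r) + C`: at each radius the cubic is
inverted for `u′` by damped Newton restricted to the monotone branch
(`|u′| < 1/√(−3κWe²)` for shear-thinning `n < 1`), starting from the
Newtonian root; the scalar constant `C` is then found by a bracketed
Brent solve of the outer-wall condition (|u(h)+1| ≤ 1e−10). The bracket
is the exact feasibility interval of the cubic branch, computed in
closed form — outside it the constitutive map folds and the solver
raises a multivalued-flux error naming the radius, rather than jumping
branches. The oracle's validity window is the model's operational
bound on `We`; no such bound exists in the expansion itself.

The convergence study sweeps `We ∈ {0.025, 0.05, 0.1}` at `α = 0` and
`α ∈ {0.0125, 0.025, 0.05}` at `We = 0` and fits log–log slopes of the
max-norm gap; measured ≈ 4.03 and ≈ 2.02 against nominal 4 and 2. Both
code paths share only the scalar-field closed forms and the quadrature
grid, so the low-order content cancels exactly and the slope
measurement is clean.

## Reporting stations

The wave phase of a station controls the sign and size of `E`, and with
it the whole character of the profile. Two defaults are deliberate
choices, made once:

- **Profiles: the trough, `z − t = 0.75`.** At the two stationary-width
  stations (crest/trough) the large cos-component of `E` — dominated by
  `(2π)⁵e₁ ≈ 2938 e₁` — vanishes, leaving the moderate damping term
  `±φ(2π)²e₄`. At the crest that term is positive (adverse gradient):
  the lab-frame profile is a *dip*, `w ≤ 0`. At the trough it is
  negative (favourable): the profile is the characteristic single
  downward-concave bump with zeros at both walls, peaking near mid-gap
  (`r ≈ 0.49` under the default set). Away from these stations |E|
  reaches ~450 and the `We²` orders grow to ~10³ — outside the
  expansion's validity.
- **Trend checks: `z − t = 0.375`.** At crest/trough, `e₁, e₂, e₃, e₅`
  have exactly zero effect (their terms multiply cos θ = 0), so
  parameter-sensitivity signs must be probed off-extremum. The quarter
  wave `z − t ∈ (0.25, 0.5)` (cos θ < 0, sin θ > 0) is the unique
  window where all sixteen documented velocity-trend signs are
  simultaneously expressible; its midpoint is used. Trends are measured
  as the sign of the mid-gap lab-frame velocity change between the
  default value and 1.5× that value.

## Trapped-bolus measurement

`ψ(r, z) = ∫ε..r s u₃(s, z) ds` over one wavelength (gauge `ψ = 0` on
the catheter; 64 axial columns by default, each an independent station
solve interpolated onto a shared rectangular mesh, NaN beyond the
wall). Closed contours are extracted by marching squares at 21 levels
evenly spaced strictly between the field extrema; NaN cells break
wall-touching contours, so only genuinely interior loops can close;
areas are shoelace sums.

A property of the model worth stating plainly: under the default
parameter set the elastic forcing drives an axial throughflow with
`|ψ|` up to ~5×10³ that varies strongly with `z` (the per-station
momentum closure does not conserve axial flux), and the ψ field has no
resolvable interior extrema — recirculation is confined to wall slivers
thinner than ~1e−3. The measured closed-contour count and total area
are therefore **zero** for the default set and for all the parameter
variations exercised in the trend tests, and the bolus-trend
inequalities hold degenerately (0 vs 0). The extraction machinery
itself is validated on synthetic fields with known closed cells
(Gaussian vortex: level-set circle areas recovered to ~2%).

## Numerical choices

- Radial grid: uniform, default N = 257 (profiles) / 1025 (oracle and
  convergence studies); composite Simpson for all cumulative integrals.
- Temperature closed form guards: denominator below ~1e3·tiny raises a
  degenerate-geometry error; `Ω < 0` is an unsupported regime.
- Oracle tolerances: constitutive Newton to 1e−13, `C`-iteration by
  Brent to xtol 1e−14, capped at 100 evaluations; flux residual
  asserted ≤ 1e−10.
- Contour ladder: 21 levels, extrema excluded; closed means first and
  last marching-squares vertices coincide.
- Everything is deterministic; identical invocations produce
  byte-identical CSVs (asserted in tests).

## Known limitations

- The per-station closure inherited from the reduction does not
  conserve axial flux across stations; the stream-function field is a
  diagnostic of that model, not of a globally mass-consistent flow.
- The expansion degrades quickly where the wall forcing is dominated by
  the flexural term; the oracle quantifies, but cannot repair, this.
- The location of the velocity maximum under the default set is
  mid-gap (`r ≈ 0.49`), closer to the centre than to the catheter; the
  package reports what the model computes.
- No pressure-rise-per-wavelength or pumping diagnostics (the pressure
  is eliminated by the wall condition and never reconstructed), and no
  dimensional-unit handling.
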