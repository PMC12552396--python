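# Methods

## Physical model and assumptions

`bandgrad` models the solvent column of a band-forming AUC experiment as a
two-component (light/heavy water) mixture in a sector-annulus channel
between the post-overlay meniscus `r_m` and the cell bottom `r_b`. The
light-solvent concentration `c(r, t)` obeys axisymmetric radial diffusion
with a single, composition-independent mutual diffusion coefficient `D` and
zero-flux walls. Assumptions this rests on:

- **No solvent sedimentation.** At band-forming rotor speeds the
  centrifugal field cannot sediment H₂O relative to D₂O on experimental
  time scales, so transport is purely diffusive.
- **Instantaneous overlay.** The initial condition is a sharp step of
  height `c_i` over the overlay layer `[r_m, r_d]` at `t = 0`. Real
  overlays form during rotor acceleration over minutes; a config option
  (`diffusion.time_offset_s`) lets users shift the model clock when
  comparing with such data, but the acceleration phase itself is not
  modelled.
- **Sharp meniscus.** Surface-tension broadening of the meniscus at low
  speed is outside the model.
- **Ideal mixing.** Density and viscosity are linear in the light-solvent
  concentration (volume-fraction mixing), which is accurate for isotopic
  water mixtures but an approximation for other solvent pairs.

## Geometry

All volume/radius conversions use `V(r1, r2) = θ·l·(r2² − r1²)/2`. The
overlay thickness can be computed from the measured meniscus
(`h = √(r_m² + 2V_O/(θl)) − r_m`) or from the planned channel and overlay
volumes; the two are algebraically equivalent when the inputs are
consistent, and the test suite asserts agreement to 10⁻¹² cm on randomized
cells. Both square-root differences are evaluated in rationalized form to
avoid cancellation at small overlay volumes; an overlay below the
machine-representable thickness yields `h = 0` with a warning rather than a
negative root. The meniscus-based route is the recommended one: planned
volumes carry unquantifiable pipetting and reservoir-transfer errors, while
the meniscus position is measured anyway during analysis. Back-calculating
the sector angle from fill volume and meniscus is supported but documented
as fragile — the angle shifts by ≈ 0.01° per 50 µm of meniscus error, which
propagates visibly into the profiles, so a direct angle measurement is
preferred.

Internally all lengths are cm, volumes cm³, angles radians; the
configuration layer converts user units (µL, mm, degrees) exactly once.

## Eigenproblem

Separation of variables gives zero-order Bessel modes. The mode shape is
taken as `R = Y₁(βr_b)J₀(βr) − J₁(βr_b)Y₀(βr)` — the combination whose
derivative vanishes identically at `r_b` and, at eigenvalues of the
cross-product equation, at `r_m`; the boundary conditions are the
non-negotiable physics that fix this sign convention. The norm
`1/N = (π²β²/2)·J₁²(βr_m)/(J₁²(βr_m) − J₁²(βr_b))` follows from the
standard hollow-cylinder result; because printed norm formulae are easy to
mistype, the test suite treats high-order Gauss–Legendre quadrature of
`∫R²r dr` as authoritative and requires the closed form to match it to
1e−8 relative (currently it agrees to ~1e−11).

Roots are found on `(0.01, 5000]` 1/cm by default. Instead of a bare secant
iteration, a vectorized sign-change scan at step `0.4·π/(r_b − r_m)` (well
under half the asymptotic root spacing) brackets every root, and Brent's
method refines each to near machine precision; this cannot skip or
double-count closely spaced roots. The constant mode `β₀ = 0` — whose
amplitude is the equilibrium concentration — is inserted analytically,
since the scan's lower bound excludes it by construction. Eigen systems are
cached per `(r_m, r_b, β_max)`, so profile families at many times reuse one
decomposition.

## Series evaluation

Modes are truncated when their worst-case contribution
`exp(−Dβ²t)·|P/N|·max|R|` (using the Bessel envelope bound for `max|R|`)
drops below `tol·c_i`, with `tol = 1e−8` by default — far below
experimental interference noise at negligible cost; the summed bound of the
dropped tail is reported on the profile. Two numerical guards:

- **t = 0** returns the exact analytic step, never the truncated series,
  which converges only in L² at the discontinuity (Gibbs ringing).
- **Resolvable-time warning:** for times with `D·β_max²·t < 25` the fastest
  retained mode has not decayed below exp(−25) ≈ 1e−11, so truncation
  ringing is possible; such profiles carry an explicit warning.

Mass conservation (`total_moles`) integrates `θ·l·∫c r dr` by Simpson's
rule on the output grid; for the exact step the integral is evaluated in
closed form so the conservation diagnostic is independent of how the grid
samples the jump. Out-of-range concentrations from residual ringing are
clamped to `[0, c_self]` (with a warning reporting the count) before being
mapped to physical properties.

## Finite-volume oracle

The cross-validation solver discretizes the conservative form
`(1/r)∂_r(r D ∂_r c)` with cell-centered finite volumes and face fluxes
`−D·r_face·Δc/Δr`; zero-flux boundary faces make the discrete total
`Σ cᵢrᵢΔr` conserved to round-off by telescoping, independent of the time
step. Time integration is Crank–Nicolson. Because CN is A-stable but not
L-stable, the step initial condition excites slowly damped sawtooth
transients at large steps; the solver therefore starts every march with two
backward-Euler (Rannacher) smoothing steps at `Δt = Δr²/2D`. After the
startup the default stepping grows `Δt` geometrically, capped at 2% of the
elapsed time — a few hundred steps to reach 6 h at accuracy well inside the
1e−3·c_i cross-validation band (measured: ≲ 4e−6·c_i at 2000 cells). A
fixed `Δt` can be requested instead, which the order-of-accuracy test uses
to demonstrate the expected ~4× error reduction when `Δr` and `Δt` are
halved together. Default resolution is 2000 cells.

A closed-form plane-geometry (cosine-series) two-layer solution is included
as a second independent reference: for a narrow annulus far from the
rotation axis the radial solution must converge to it, and does to
~2e−5·c_i at `r_m/width = 2000`.

## Solvent properties

`SolventPair` carries the pure-component densities and viscosities at the
experiment temperature; the shipped preset records 20 °C literature values
for H₂O/D₂O with their source note, and no property parametrization
polynomials are bundled — values are explicit config inputs. The default
normalization constant is the conventional `c_self = 55.56 mol/L`
(ρ = 1.000 g/mL, M = 18.00 g/mol, rounded); the 20 °C-exact value
(55.41 mol/L from ρ = 0.99823, M = 18.015) differs by ~0.3% and can be
derived with `self_concentration` and passed explicitly. The default
follows the rounded convention the mixing rules are normally quoted with;
the discrepancy is documented rather than silently corrected.
`transport_correction_factors` exposes the standard Svedberg-type local
scaling `s ∝ (1 − v̄ρ)/η`, `D ∝ 1/η` for downstream Lamm-equation solvers.

## Reference configuration and problem sizes

The shipped preset `epon_bfe_12mm` encodes a 12 mm-path Epon band-forming
centerpiece: sector angle 2.5° (measured), bottom radius 7.166 cm, channel
top radius 6.163 cm, 10 µL overlay, `D = 1.8e−5 cm²/s` for H₂O/D₂O at
20 °C. Tests and the acceptance script use this cell with the post-overlay
meniscus at 6.5 cm (a typical fill of ~228 µL), an output grid of 2001
radii, eigenvalues to 5000 1/cm (~1060 modes), and a 2000-cell oracle grid
— sizes at which the full acceptance computation completes in about a
second while every tolerance has orders of magnitude of margin.

## What the synthetic conditions do and do not show

All validation is against internal oracles (finite volume, quadrature,
closed forms) on idealized initial conditions. Passing tests demonstrate
that the series solution solves the stated diffusion problem correctly;
they do not validate the instantaneous-overlay idealization, the sharpness
of a real meniscus, the constancy of `D` across the mixing range, or the
fringe-to-concentration conversion of interference optics (not modelled —
any comparison to recorded scans is shape-only via the two-column scan
reader).

## Known limitations

- Single mutual diffusion coefficient; no composition dependence.
- No analyte transport (the gradients are inputs to, not coupled with, a
  Lamm-equation solver).
- No rotor-acceleration dynamics, reservoir/capillary transfer, or
  meniscus-curvature modelling.
- The gravitational stability of the band is assumed, and only warned
  about (heavy-over-light configurations).
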