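# Methods

## Model

The probe is rigid and axisymmetric: a cone of half-opening angle θ
(default 20°) terminated by a spherical cap of radius R. Its profile above
the apex is

- z(ρ) = R − √(R² − ρ²) for ρ ≤ ρ_t = R cos θ,
- z(ρ) = z_t + (ρ − ρ_t)/tan θ for ρ > ρ_t, with z_t = R(1 − sin θ),

C¹-continuous at the tangent point. Contact therefore stays on the
spherical cap for indentations δ ≤ R(1 − sin θ), which is the default upper
bound of the indentation grids (0.658 R at 20°).

The sample is a homogeneous, isotropic, linear-elastic body (defaults
E = 100 MPa, ν = 0.3, values representative of DNA and similar
biomolecules as probed by AFM) with a single-valued top surface h(x, y) ≥ 0
over a rigid substrate at z = 0. Adhesion, friction, viscoelasticity,
cantilever/feedback dynamics and imaging-mode specifics are outside the
model: images are ideal constant-force contours.

## Imaging procedure

For each lateral scan position the **first-contact apex height** is
max_p [h(p) − z_tip(|p − x|)], floored at 0 — a grayscale dilation of the
surface by the reflected tip. The search is pruned to cells within
ρ_boundary, the tip-profile inverse at the tallest sample height; a
brute-force oracle in the test suite verifies the pruning is lossless.
Lowering the apex by δ > 0 and evaluating a contact engine gives the force
volume F(x, y, δ). Constant-force topographies are read off each column
with a shape-preserving (PCHIP) cubic of apex height versus force —
monotone by construction, so images are pointwise nonincreasing in the
setpoint — with optional bicubic lateral refinement. The axis order
(monotone cubic vertically, then lateral interpolation) is a design choice;
oscillation-free column inversion was preferred over a single global
bicubic fit. Columns whose sampled force never reaches the setpoint are
flagged saturated and mapped to the substrate floor (height 0), with a
warning. On compliant flat regions the extracted apex height is legitimately
negative (the apex presses below the undeformed substrate plane); iso-force
images are therefore not clipped at zero, while zero-force images are
nonnegative by construction.

## Contact engines

**Half-space boundary-element engine.** Frictionless normal contact of the
rigid tip on an elastic half-space. Surface deflection from the pressure
field uses the exact Boussinesq integral of uniform pressure on a
rectangular cell (nonsingular self-term), assembled as an FFT convolution
on the uniform grid. The constrained problem — p ≥ 0, deformed gap ≥ 0,
complementarity — is solved by a conjugate-gradient active-set iteration in
the style of Polonsky & Keer, restarted whenever the active set changes,
with negative pressures projected out and newly penetrating cells admitted
each sweep. Convergence: relative complementarity residual < 1e-6
(iteration cap 10 000; the Hertz benchmark converges in ~30 sweeps). At
the default resolutions the solver reproduces the Hertz force and contact
radius to well under 5%, the Hertzian pressure profile to < 10% L2, and
the flat-punch force F = 2 E\* a δ to ~1%.

This engine replaces a full finite-element treatment of the deformable
sample. Two consequences: (i) tangential (frictional) tractions are
neglected — normal-force observables in the small-indentation Hertz regime
are insensitive to this; (ii) the sample is elastically a half-space, so
finite-thickness base compression enters the package only through the
analytic double-contact model, which is the appropriate correction for a
sphere on a point-like support, while wide-based samples (hemisphere,
sinusoid bed) make base compression small in the first place.

**Local-analytic engine.** At the first-contact point the sample's
principal convexities κ₁, κ₂ (analytic for parametric surfaces,
finite-difference Hessian otherwise) are combined with the tip cap,
1/R'_i = 1/R + κ_i, and the equivalent axisymmetric Hertz radius is the
geometric mean √(R'₁R'₂); concave directions that wrap the tip are capped
at a near-flat limit. First contact on the conical flank falls back to the
Sneddon cone law. This engine is exact for on-axis contact with spheres
and flats, and fast; it cannot represent two-sided trough contact or
oblique edge contact, for which the half-space engine is used (these are
precisely the configurations behind the lateral E_AFM orderings).

## Contact laws and fitting

The double-contact relation is implemented as series compliance: the
measured displacement δ(F) = δ_I(F) + δ_C(F) with the tip contact Hertzian
at R\* (1/R\* = 1/R + 1/r) and the sample-substrate contact Hertzian at r
(sphere on a rigid plane). δ(F) is strictly increasing, so F(δ) is obtained
by bracketed Brent root finding on [0, F_Hertz(δ; R\*)] to 1e-12 relative
tolerance; for this compliance split the inverse also has the closed form
F = (4/3) E\* δ^{3/2} (R\*^{-1/3} + r^{-1/3})^{-3/2}, used as an independent
oracle in the tests. Note that with this split the two compliances can
never be exactly equal for finite R (that would need R\* = r, i.e. 1/R = 0);
the series-spring symmetry is checked through the closed form and the
r → ∞ limit instead.

The Sneddon correction factor f(δ) for spherical samples is exposed as a
replaceable callable multiplying the cone law and defaults to f ≡ 1 (the
classical flat-surface law): the correction is an experimentally fitted
function whose published constants are not bundled, and every result in the
package is defined for the pure law.

Modulus fits treat E as the only free parameter (log-parameterized,
trust-region least squares, E₀ = 100 MPa); R, θ, r are fixed by
configuration. Following AFM practice, the Hertz fit substitutes R for R\*
(the local sample curvature is treated as unknown). Curves are clipped to a
dimensionless force ceiling F/(E\* R²) ≤ c (closed interval; default c = 0.1
for maps) before fitting.

## Synthetic samples and the study conditions

- **Hemisphere**: r = 5 nm, closed-form height field, default grid 0.1 nm.
- **Sinusoid**: h(x) = A(1 + cos 2πx/λ)/2 with λ = A = 10 nm (peak-to-trough
  amplitude A, troughs on the substrate, crest at x = 0), width 4λ. Its
  cosine fundamental is A/2; "ideal imaging" means A₁ = A_surface = A/2 and
  A_{n>1} = 0.
- **B-DNA fixture**: a straight duplex from canonical helical parameters
  (rise 3.4 Å, twist 36°/bp, strands offset 140° in azimuth) with one
  sphere per chemical group (P, O, sugar C, base N/C) at B-form radial
  distances, giving a ~20 Å van der Waals envelope with major/minor
  grooves. It is deterministic, has no sequence or conformational detail,
  and stands in for a crystallographic structure only geometrically; a real
  PDB file can be supplied instead. van der Waals radii are half the UFF
  nonbonded distances (H 1.443, C 1.926, N 1.830, O 1.750, P 2.074,
  S 2.018 Å; unknown elements 1.70 Å with a warning).
- **Molecular height fields** are the upper envelope of the atom spheres,
  rested on the substrate, shifted down by a cleave fraction (default 20%,
  emulating partial embedding in the support) and clipped at 0; undercuts
  are discarded, consistent with a vertical-approach model. Default bin
  0.55 nm. The DNA preset scans 8 × 30 = 240 positions over a 5 × 20 nm
  base: a 0.55 nm binning of that base cannot tile into exactly 240 cells,
  so the sample field keeps the 0.55 nm bins while the scan grid carries
  the 240 positions.
- **Point tip**: the ideal-trace limit is R → 0 *and* θ → 0 (a needle).
  R → 0 alone is not sufficient: a cone of half-angle 20° has flank slope
  1/tan 20° ≈ 2.75, below the sinusoid's maximum slope π, and would still
  distort the trace.

What the synthetic samples do **not** emulate: surface roughness,
heterogeneous elasticity, adhesion hysteresis, thermal drift and noise
(except the explicit multiplicative noise used in fit-recovery studies).
Passing tests show the geometry/elasticity pipeline is self-consistent and
matches closed forms — not that any specific experimental image will be
reproduced quantitatively.

## Numerical choices and problem sizes

Default indentation grids are 30 points, geometric from 0 to 0.65 R.
Benchmarks and property tests use grids of order 100 × 100 (half-space
solver) and 0.1–0.25 nm scan steps; modulus-map studies use 5 lateral
positions across the hemisphere and crest/trough positions on the sinusoid
with ~12-point indentation grids. These sizes keep every result
grid-converged at the percent level (halving the cell size moves the Hertz
benchmark force by < 2%) while the full suite runs in well under a minute
per module. Degenerate inputs are handled explicitly: zero approach gives
zero pressure; saturated iso-force columns are flagged; empty grain
footprints return volume 0 with a warning; a cleave fraction that removes
the whole molecule raises.

## Known limitations

- Elastic half-space kinematics in the numerical engine (no finite-depth
  stiffening, no substrate reaction through the sample).
- Frictionless contact; rough/non-slip tangential behaviour not modelled.
- No adhesion (JKR/DMT) and no viscoelasticity.
- Single-valued surfaces only; re-entrant geometry is discarded.
- The coarse-grained B-DNA fixture reproduces envelope dimensions, not
  atomic detail; groove depths are approximate.
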