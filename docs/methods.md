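# Methods

## Membrane model

### Problem and assumptions

The culture membrane is a thin rectangular elastomer plate, clamped on all
four edges (bonded to rigid channel walls: `w = 0`, `∂w/∂n = 0`), loaded by a
uniform transverse pressure. At the working point the centre deflection `w₀`
is ~4× the thickness, so linear plate theory is invalid; the response is in
the Föppl–von Kármán (FvK) large-deflection regime where in-plane membrane
stretching carries most of the load and bending contributes a surface
correction. The model is quasi-static at peak load: the 1 Hz actuation cycle
is far below any structural resonance, and PDMS viscoelasticity is ignored.

Rather than solving the coupled FvK system (deflection + Airy stress
function), the deflection is an **assumed separable clamped shape**

    w(x, y) = w₀ · g(x/a) · S(y/b),      S(ξ) = ½(1 − cos 2πξ),

and the amplitude is **calibrated** to the experimentally measured average
strain. The in-plane displacement field and the Airy stress function are
never solved; strains are evaluated directly from `w`, and the FvK
equilibrium equation enters only through the `pressure_check` diagnostic.

### Long-axis profile

Two choices of `g` are provided:

* `"cosine"` — the classical separable clamped mode `g = S`. This is the
  textbook single-mode ansatz, but at a 6:1 aspect ratio it is a poor model:
  it forces the strain to vary as strongly along the channel as across it,
  producing a culture-region CV of ~65 %, and it is inconsistent with how
  high-aspect membranes actually deform.
* `"plateau"` (default) — flat over the interior with clamped quintic
  smoothstep ramps of length `b/2` at each end. A membrane in the
  large-deflection regime deforms cylindrically away from the short edges
  (the edge-effect zone scales with the channel half-width); the quintic
  ramp keeps curvature continuous (C²) so finite-difference strain fields
  converge at second order. The ramp length only affects the field outside
  the culture region.

The cross-section is the clamped cosine in both cases, so the centre section
`w(a/2, y) = w₀ S(y/b)` is identical under either profile.

### Strain measures

Membrane (arc-length) normal strains support two conventions:

* `"equilibrated"` (default): the arc extension of each cross-section is
  distributed uniformly along it, e.g. `ε_yy(x) = (arc_y(x) − b)/b`. This is
  what in-plane force balance enforces — the stress resultant `N_yy` is
  nearly constant across a section of a membrane, so the strain is too. A
  strong independent check: with a uniform 10 % transverse strain the
  resultant is `N = E t ε/(1 − ν²) ≈ 19.7 N/m`, and the pressure balance
  `N·κ` at the calibrated centre curvature gives ≈ 20 kPa — the applied
  vacuum, recovered with no fitting.
* `"pointwise"`: the local stretch `√(1 + w_x²) − 1`, the kinematic value
  for zero in-plane displacement. Retained as an option and for closed-form
  tests; it violates in-plane equilibrium and reproduces the published
  region statistics much more poorly.

Shear is the von Kármán product term `½ w_x w_y` in both conventions.
Bending strains at the cell-facing surface are `(t/2)|w_xx|`, `(t/2)|w_yy|`,
added with positive sign to the membrane normal components (a conservative
total; `surface="midplane"` omits bending). The von Mises equivalent uses
the plane-stress form `√(ε²ₓₓ − εₓₓε_yy + ε²_yy + 3ε²ₓᵧ)` on the total
tensor. Derivatives are central differences on the stated grid
(second-order one-sided at boundaries).

### Calibration metric

"Average membrane strain" is ambiguous; three metrics are implemented:

1. `membrane_vm_mean` — full-membrane mean of the membrane-component von
   Mises strain;
2. `centerline` (default) — arc-length strain of the width-wise centre
   section, `(arc − chord)/chord`, computed by dense trapezoid quadrature
   (4001 points) of the analytic section slope — this is the quantity a
   line of tracked beads across the channel centre measures;
3. `region_vm_mean` — culture-region mean of the membrane-component von
   Mises strain.

The default is the centerline metric because it is the direct analogue of
the bead-tracking measurement the devices are calibrated with, and it
reproduces the published calibrated deflection (834.5 µm computed vs 839 µm
published, −0.5 %). Metric 1 would require w₀ ≈ 1391 µm to reach 10 % —
irreconcilable with the published deflection.

The calibration root-find uses Brent's method on a bracket `[0, 5t]`
(doubled up to `80t` if needed); the average strain is strictly increasing
in `w₀`, so the root is unique. Tolerance is 1e-9 relative.

### Culture region and uniformity

The culture region is a centred rectangle covering 60 % of the membrane
area, each side scaled by √0.6 (the published description fixes only the
area fraction; preserving the aspect ratio is this package's choice).
Uniformity statistics (mean, population-SD CV, uniformity = 100 − CV, min,
max of the von Mises field) are evaluated over the region's grid nodes.

### Fidelity to the published characterization

Under the default conventions, calibrating to 10 % reproduces the published
deflection (−0.5 %), deflection-to-thickness ratio, region CV (+1.6 %),
uniformity (−0.4 %), region minimum (−1.6 %), and the <2 % grid-independence
bound (0.53 % between 241×81 and 481×161). Two quantities disagree beyond
5 %: the region mean (15.3 % computed vs 14.2 %) and region maximum (19.4 %
vs 17.9 %). These cannot be fixed within this model family: at the published
839 µm deflection, the arc-length strain of the cosine cross-section at
`y = b/4` is already `√(1 + (π w₀/b)²) − 1 = 19.7 %`, above the published
maximum — the published set of {deflection, mean, CV, min, max} is not
jointly attainable by any single-mode clamped profile with standard strain
measures. The conventions here were chosen on mechanical grounds (in-plane
equilibrium, the pressure-balance check above, and the published qualitative
description of the field — highest near the clamped walls, most uniform at
the centre), not fitted per-quantity; the residual ~8 % disagreement on
mean/max is reported as-is by `memstretch replicate`.

### pressure_check

`pressure_check` projects the transverse equilibrium residual
`D∇⁴w − N:∇²w` onto the shape function with `⟨·, φ⟩/⟨φ, φ⟩` weighting
(single-mode Galerkin with the load represented in the mode) and reports the
implied uniform pressure. At the calibrated deflection it gives ~16 kPa
against the applied 20 kPa — an order-of-magnitude consistency check, not a
calibration path (the assumed shape is not the exact equilibrium shape, so
exact agreement is not expected).

## Bead-tracking strain

Detection: local maxima above a threshold (Otsu by default) with a minimum
separation, refined by intensity-weighted centre of mass in a 7×7 window.
Matching: mutual nearest neighbours within a search radius. Because a 10 %
stretch displaces peripheral beads by more than the typical bead spacing,
`BeadTrackingModel` iterates matching with affine compensation: fit, warp
the reference positions by the current estimate, re-match with a radius
tied to the residual RMS, refit. With a correct match set the estimate is a
fixed point, so a few iterations suffice; on synthetic pairs all beads are
recovered and `F` is exact to ~1e-4 at 0.1 px localisation noise.

The affine fit is linear least squares for `x' = F x + c`; Green–Lagrange
strain is `½(FᵀF − I)`, and the reported scalar "average strain" is the mean
of the two principal stretches (singular values of `F`) minus one, matching
the single-number usage of device calibrations. `local_strain_map` repeats
the fit in moving windows, flagging windows with <3 beads as missing (NaN,
never zero). Pure rotations give zero Green strain by construction.

## Fiber orientation

Gradients by derivative-of-Gaussian at `sigma_gradient` (default 1.5 px,
matching fiber-scale detail), tensor smoothing at `sigma_window` (default
6 px, the scale over which orientation is averaged). Fiber axis
`θ = ½ atan2(2Jxy, Jxx − Jyy) + 90°` (mod 180) — the eigenvector of the
*smaller* eigenvalue, i.e. the direction of least intensity variation;
coherence `(λ₁ − λ₂)/(λ₁ + λ₂)`, zero where the tensor trace vanishes.
Pixel convention: x = column, y = row, angles measured from the x-axis
toward the y-axis, so rotating an image by +δ (scipy convention) shifts the
mean axis by −δ.

Statistics are computed on doubled angles (axial data): resultant length
`R`, mean axis = half the resultant angle, circular SD `√(−2 ln R)` reported
in degrees. The doubled-angle SD convention is the default because it
exactly reproduces the published index/SD pairs (R = 0.387 → 78.9°,
R = 0.501 → 67.3°, both within 0.07°); the halved "axial" convention is
available as an option. Pixels are weighted by coherence by default
(uniform optional) and masked to coherence > 0.2 and intensity above the
Otsu threshold — the published analysis states neither, so these are
package defaults, exposed as parameters. Rose histograms use 18 bins of 10°
over [0°, 180°), weights normalised to 1.

The published alignment indices themselves (0.387, 0.501) cannot be
recomputed without the original micrographs; they are used only as inputs
to the circular-SD and relative-change identities.

## Synthetic data

Fiber images: axes sampled by the angle-doubling construction
(`vonMises(2μ, κ)/2`, so the doubled-angle resultant is the Bessel ratio
`I₁(κ)/I₀(κ)`); fibers drawn as anti-aliased segments (default 120 fibers of
length 60 px, width 2 px on a 256² frame) with additive intensity, clipping,
and Gaussian noise (photon-limited Poisson noise is out of scope). Bead
pairs: uniform positions with a minimum separation (default 100 beads,
8 px separation, 20 px margin so deformed beads stay in frame), deformed
about the image centre by a prescribed `F` plus sub-pixel jitter, rendered
as Gaussian spots (σ = 1.5 px). Defaults mirror the reference experiment's
regime: ~10 % stretch, 0.1 px localisation jitter, 1 µm beads at moderate
density. Every generator takes a mandatory seed and returns the ground
truth with the image.

What the generators do *not* emulate: real micrograph texture (crossing,
curved, bundled fibers; nuclei; uneven illumination), out-of-plane membrane
curvature during imaging, and detector noise statistics. Passing tests
therefore demonstrate correctness of the estimators under their stated
models, not performance on arbitrary real images.

## Numerical choices and edge cases

* Degenerate inputs raise `ValueError` with actionable messages (empty bead
  sets, zero matches, collinear configurations, all-zero weights, empty
  masks, unreachable calibration targets).
* A blank image yields an empty `BeadSet`, not an error; windows without
  enough beads yield NaN rows.
* Matching ties are resolved by the mutual-nearest-neighbour requirement;
  detection output is sorted by position for determinism.
* CV uses the population SD convention.
* Replication-report tolerances: ±5 % relative for membrane quantities
  (reflecting the shape-function/metric ambiguity above) and ±0.1 absolute
  (printed precision) for the circular-statistics identities — the exact
  value of `√(−2 ln 0.501)` is 67.363°, so agreement with the printed 67.3°
  is only defined to the printed precision.

## Known limitations

* Single-mode assumed shape: no multi-mode Galerkin expansion, no coupled
  FvK solve; the strain field near the short edges is qualitative.
* Linear-elastic constitutive law; PDMS strain-stiffening is not modelled
  (the 750 kPa modulus is the small-strain value).
* Quasi-static: no cyclic/viscoelastic effects.
* Bead analysis is affine (global or windowed), not full digital image
  correlation; no temporal tracking beyond a single pair, no out-of-plane
  displacement recovery.
* Orientation analysis does not segment cells or trace individual fibers;
  between-condition comparison is descriptive (relative change), with no
  hypothesis testing.
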