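# Methods

## The multi-phase model

The midsagittal section is described in polar coordinates by the outer
surface radius r(θ) (assumed single-valued) and the EGL thickness t(θ).
Four ingredients enter the energy density: a radial restoring term
k_r (r − r₀)² for the glial fibers and pial membrane that tether the surface
to a preferred radius r₀; a growth potential −k_t (t − t₀)² expressing that
the uniformly proliferating EGL gains energy by deviating from its preferred
thickness t₀; a gradient penalty β (dt/dθ)² for the Bergmann-glia fibers
that resist thickness variation; and an incompressible core, imposed as the
constraint ½∮(r−t)² dθ = A₀ with Lagrange multiplier µ. Because the radius
of a circle fixes its perimeter, the radial term also encodes
circumferential tension; the EGL itself is treated as a fluid (cells
rearrange freely on the folding timescale), so no elastic energy is assigned
to it.

Two normalisation choices matter and are fixed as follows:

* **Multiplier convention.** The stationarity condition is
  δ(E − µ∮(r−t)² dθ) = 0, i.e. the multiplier term carries no ½. With this
  convention the radial equation is k_r (r − r₀) = µ (r − t) pointwise and
  ε ≡ µ/k_r is the dimensionless control parameter appearing in the
  solution formulas. Carrying the ½ inside the multiplier term would merely
  rescale µ by 2.
* **Mean thickness.** The mean EGL thickness is pinned at t₀ as a second
  constraint (multiplier ν, entering only the angular mean of the thickness
  equation). Physically the mean thickness is set by the proliferation /
  radial-transit balance and is what is measured on sections; mathematically
  this choice makes t(θ) = A_t sin(qθ+φ) + t₀ — with offset exactly t₀ —
  an exact stationary solution, and keeps the calibrated ratios
  A_t/t₀ = 0.5 and r₀/t₀ = 16 statements about observable quantities.

The Euler–Lagrange system is then a driven harmonic oscillator for t(θ):

    β t'' + k_t (t − t₀) − µ (r − t) + ν = 0,
    k_r (r − r₀) = µ (r − t),

with sinusoidal solutions of wavenumber q satisfying
q² = (k_t/β) ((1−ε) + µ/k_t)/(1−ε). A variant numerator (1 + µ/k_t) is
also implemented behind a `convention` switch (`wavenumber_squared`,
`fold_count_formula`); the two differ by ~40% in k_t/β at ε = 0.3 but agree
in structure, and only the first makes the sampled sinusoid exactly
stationary, which is why internal calibration of β from q uses it. Neither
is preferred in the public API.

Key consequences carried by the solution and asserted by the test-suite:

* thickness and surface height oscillate exactly out of phase for
  0 < ε < 1 (Pearson correlation −1);
* A_r/A_t = ε/(1−ε): order-one surface amplitudes need no stiff film;
* the fold count q is set by material ratios only, not by the EGL thickness
  — in contrast to wrinkling, where n ∝ l/t.

### Parameterisation and time course

The dimensionless calibration (units r₀ = 1) is c = k_r/k_t = 0.06/ε,
A_t/r₀ = ε/9.6, t₀/r₀ = ε/4.8, q = 6, φ = 0. Note µ/k_t = εc = 0.06 is
constant. At ε = 0.3 this gives A_t/t₀ = 0.5 and r₀/t₀ = 16, matching the
E16.5 measurements; ε(T) = 0.3 (T − 15.5) defines the stage series, valid
for T < 18.83 (ε < 1). The ε-linear thickness map degenerates at ε = 0, so
the unfolded (E15.5) reference annulus uses the measured t₀/r₀ = 1/16
instead. Half-domain (semicircular) solutions live on θ ∈ [0, π] with
zero-slope thickness ends, which requires φ = ±π/2; φ = −π/2 is the default
so that the three thickness maxima (the ACs) sit at θ = π/6, π/2, 5π/6.

### The numerical oracle

The growth term makes the *global* constrained minimisation ill-posed: for
k_r < k_t (true under the calibration for ε > 0.06) the energy is unbounded
below along directions where thickness and radius co-grow at fixed core
area. What the variational principle selects are constrained stationary
states. `constrained_minimize_oracle` therefore:

1. projects the stationarity system onto the circle branch and onto each
   single-Fourier-mode branch m = 1..n_modes (rotational symmetry lets any
   single-mode pattern be phased as a pure sine), giving a 4-unknown
   nonlinear system (mean radius, two amplitudes, µ) per branch;
2. solves each by seeded multistart root-finding (`scipy.optimize.root`),
   rejecting solutions that collapse onto the circle;
3. discards branches whose shapes are unphysical (t ≤ 0 or r − t ≤ 0
   anywhere) or whose amplitude cannot meet the area constraint;
4. returns the least-energy survivor (the energy along the stationary
   family increases with µ at rate 2(A₀ − πd²) ≥ 0, so the patterned branch
   always undercuts the circle when a real amplitude exists — this is the
   selection principle, verified numerically in the tests).

For the calibrated parameters at ε ∈ {0.1, 0.3, 0.5} the oracle selects
wavenumber 6 with the analytic amplitude to ≲10⁻⁷ relative, the agreement
the acceptance checks require at 1%.

## Morphometrics

Contours are ordered (x, y) polylines in µm; closed contours are simple and
counterclockwise so convex arcs have positive signed curvature. Differential
quantities are computed after resampling to uniform arc length (keeping the
input point count) and optional Gaussian smoothing over arc length; the
folding index defaults to a 10 µm smoothing scale and a 10⁻⁴ µm⁻¹ curvature
tolerance, both config-exposed, since how "positive curvature" was extracted
from sections is not otherwise pinned down. The folding index is reported in
percent. Thickness is the shortest Euclidean distance from points every
12.5 µm along the inner EGL boundary to the outer boundary polyline; samples
whose nearest point falls on an endpoint of an open outer arc are dropped
and logged. The shape factor divides the outer half-arc length by √(area
enclosed by the arc and its base segment); a 1441-point half-domain grid
reproduces √(2π) for the ε = 0 shape to < 10⁻⁴. The columnar expansion
reference takes the exposed perimeter of a fixed-width rectangle as two
sides plus the distal end, L = 2A/w + w (switchable to distal-end-only).
Sphericity uses π^{1/3}(6V)^{2/3}/A with V from the voxel count and A from
marching cubes on a lightly smoothed (σ = 1.5 voxels) mask — smoothing
removes the voxel staircase, which would otherwise inflate surface area by
~8% at any resolution; the residual bias is ≲1.5% for radii ≥ 20 voxels.
The E18.5-style AC sector construction (`ac_sector_window`) is implemented
as an angular wedge from the section centroid and flagged experimental.

## Cell and fiber quantification

Measuring windows are polygons bounded by arc-length limits on the outer
contour and a fixed 50 µm inward depth, centered at the AC and every 25 µm
out to ±250 µm (21 windows; windows running off an open contour are
truncated and flagged). The proliferation index is EdU⁺/(DAPI⁺;P27⁻) among
cells in the window; an empty denominator reports missing (NaN), not zero.
Cells exactly on a shared boundary are credited to the window with the
nearest centroid, ties broken toward the anterior.

The fiber pipeline fits a 4th/5th-order polynomial to the outer edge,
offsets five scan lines at 12.2 µm intervals beneath it (starting one
spacing below the surface), normalises each plane to its mean, smooths with
a 2-pixel Gaussian, and counts peaks per 50 µm bin of arc length along the
fitted contour. The peak detector uses minimum/maximum filters: a sample is
a peak if it is the neighborhood maximum (7 pixels), exceeds the local
minimum (4× wider support) by 0.2 of the line's dynamic range, and clears an
absolute noise floor — the smoothed plane's 10th percentile plus 6 robust
standard deviations of the background noise, estimated from the lower side
of the raw normalised intensity distribution and attenuated by the known
smoothing (white-noise variance shrinks by 4πσ² under a 2D Gaussian). The
floor is what makes a fiber-free noisy image report zero peaks while leaving
true crossings (≥5σ above background at SNR 5) untouched. These constants
are held fixed across images and were calibrated once on the synthetic
generator.

## Synthetic data and what passing tests show

Generators are pure functions of (params, seed) with JSON ground truth.
Study conditions: r₀ = 480 µm at E16.5 (t₀ = 30 µm), EGL cell density
12 cells/1000 µm², EdU rate 0.35, P27 rate 0.2, fiber width 1.5 µm
(Gaussian cross-profile; SNR = peak amplitude / background noise SD,
default 5), pixel size 0.4 µm, fibers roughly radial (±3° tilt) and roughly
evenly spaced within bins, core area 2.2×10⁵ µm² growing 1.6×/day for
expansion series, with differential mode inflating EGL length 15%/day past
its switch stage.

The generators share the model's geometry and the pipelines' file dialects,
so recovery tests close the loop generate → write → read → measure. They do
not emulate segmentation error, uneven staining, z-stack attenuation, tissue
damage or real fiber morphology (branching, curvature); passing therefore
demonstrates the correctness and internal consistency of the measurement
definitions and the model implementation — not robustness to the full noise
structure of histology. Quantified recovery under the stated conditions:
thickness amplitude/mean within 2% (noise-free boundaries), proliferation
within binomial error, fiber counts with mean absolute error ≤ 1 per bin
across densities 1–8 (undercounting sets in above ~6 fibers per 50 µm bin,
where crossings approach the optical resolution), sphericity within 2%.

## Numerical choices and limitations

* Periodic integrals use the rectangle rule and spectral derivatives
  (exact for trigonometric fields); open domains use trapezoid and
  second-order finite differences.
* The oracle's constraint residual must be < 10⁻⁶ relative at convergence;
  branch root-solves accept ‖F‖ < 10⁻⁹ of the problem scale.
* Boundary jitter in `gen_section` regenerates up to 3 times if the
  boundaries cross, then errors.
* The model cannot produce self-contacting folds or hierarchical folding,
  and nothing here fits k_r, k_t, β to tissue; the AC/flank thickness ratio
  of the stage series drifts toward 1 at late stages because the model's
  mean radius (C₃) grows with ε while the 250 µm flank extent is held at
  the measurement protocol's value.
* Measured-tissue quantities (bulk-modulus ratios, real AC thickness
  ratios, regional proliferation differences) depend on histology that is
  not reproducible at a desk; the pipelines that would measure them are
  exercised on synthetic fixtures instead.
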