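# Methods

This note records the models, conventions, parameter choices, and known
limitations behind `nemaclear`. Units are micrometres, hours, and
cells/mm² throughout; angles are radians measured counterclockwise from +x
in a y-up frame (images are flipped row-wise on load so that
counterclockwise-positive angular velocity is unambiguous).

## Director estimation

The local cell orientation is a nematic director θ ∈ [0, π). It is
estimated with the structure tensor: Gaussian-derivative gradients at scale
`gradient_sigma` (default 2 px), outer products averaged with a Gaussian
window `window_sigma` (default 16 px ≈ one cell width at the default
0.625 μm/px), θ taken as the orientation of the minor eigenvector (the
direction of least intensity variation, i.e. the streak axis), and
coherence defined as (λ₁ − λ₂)/(λ₁ + λ₂). The estimate is invariant under
affine intensity rescaling and equivariant under rotation to within
interpolation error. All angle averaging — interpolation, downsampling —
is done on the nematic tensor (coherence-weighted cos 2θ, sin 2θ), never on
raw angles, so antipodal directors average correctly.

Two estimator artefacts worth knowing: coherence has a finite-sample floor
on isotropic input (roughly 0.15 for a 16 px window, falling with window
size), and a border band of about 3 window widths is unreliable because of
filter padding.

## Defect detection and geometry

The winding number on a closed loop is the sum of successive nematic
differences wrapped into (−π/2, π/2], divided by 2π; it is an exact
multiple of 1/2 by construction. Detection evaluates every 2×2 plaquette,
clusters same-sign candidates within `merge_radius` (3 grid nodes),
re-measures the charge on a sampling ring of `loop_radius` (5 nodes)
around the cluster centroid, and fits the ring's doubled angle
ψ = 2θ to ψ = 2qφ + 2θ0 (unwrapped least squares for q, circular mean for
θ0). Records are sorted row-major; defects closer than two ring radii are
flagged rather than suppressed, and charges that do not resolve to ±1/2
(e.g. full-integer windings) are flagged "unresolved" rather than forced.

Symmetry axes follow from θ(φ) = qφ + θ0: three legs
φ_k = (2/3)(θ0 + kπ) for q = −1/2 (the set is invariant under the nematic
ambiguity θ0 → θ0 + π, so no disambiguation is needed), and a single tail
axis for q = +1/2. Because θ0 is only defined mod π, the tail has a sign
ambiguity between 2θ0 and 2θ0 + π. It is resolved with the defect
polarization p = ∇·Q computed from the coherence-weighted nematic tensor
around the core: the tail is taken along +p, which is the side on which the
director is radial (the straight "comet tail" segment). This convention was
fixed by evaluating p analytically for the planted field θ = φ/2, where
p ∝ +x̂ and the radial side is also at φ = 0, and it is enforced by a test
that checks the director is parallel to the radius on the tail side and
perpendicular on the head side.

Tracking is greedy nearest-neighbour linking between consecutive frames,
same charge only, capped at `max_link`, with ties broken by distance then
row-major order; mean speed is path length over elapsed time.

## Velocity analysis

Velocities come from subset correlation of consecutive frames: 64×64 px
subsets every 16 px (10 μm), zero-normalized cross-correlation computed
with zero padding (linear, not circular) and normalized per lag by the
overlap count, which removes the classic bias of windowed correlation
toward zero displacement. The subpixel peak is located with a full 2-D
quadratic fit (including the cross term) to the 3×3 log-correlation
neighbourhood; on streak-aligned textures the correlation peak is a rotated
ridge, and a separable per-axis fit would be biased by ~0.3 px. Subsets are
masked (not errors) when constant, when the peak coefficient falls below
0.3, or when the peak reaches the edge of the ±16 px search range.
Displacement along the streak direction is inherently ill-conditioned (the
aperture problem); recovered uniform shifts are accurate to ≤ 0.05 px per
subset on short-streak textures and to ≤ 0.2 px in the field mean on
fully streaky ones.

For +1/2 defects the field is resampled into the defect frame (positions
and vectors rotated so the tail points along +x) and averaged in four
rectangular boxes: left/right are 500 μm wide × 750 μm tall with inner
edges 25 μm from the core (50 μm total separation), top/bottom transposed.
For −1/2 defects the radial/angular decomposition is taken about the core
and averaged over six sectors delimited by the legs, excluding r < 250 μm,
r > 1800 μm, and a 45 μm perpendicular-distance band along each leg ray.
Off-leg nodes on the clockwise side of their nearest leg form the A group
(their convergence onto the leg ahead is counterclockwise, v_φ > 0), the
counterclockwise side forms B. On synthetic scenes smaller than the 1800 μm
outer radius the annulus is clipped by the field extent and means are taken
over the available nodes. Control positions reuse the same box geometry at
seeded random defect-free locations.

## Density analysis

Cell counts are photometric: the single-cell intensity is the mean
background-subtracted integrated intensity of 15 randomly selected detected
nuclei (background = image mode, refined as the median of the modal
histogram bin); the count within a circle of radius R is the summed
background-subtracted intensity divided by that calibration; density is the
cumulative count/(πR²) in cells/mm², evaluated for R = 10–350 μm in 20 μm
steps; the density-vs-R slope comes from ordinary least squares with a
t-based 95% CI (units cells/mm² per μm, stamped in the output). Note the
cumulative definition: a local density ρ0 + g·r appears as a profile slope
of (2/3)g. The smallest radii carry essentially Poisson-count noise
(expected counts of order one), so single-profile slopes are noisy even
though they are mean-unbiased; the pipeline pools defects per time point
before regressing. Calibration is reliable on fields of well-isolated
nuclei; at high density, overlapping spots inflate the single-cell estimate
by a few percent, which cancels in slope signs but not in absolute counts.

## Clearance analysis

The spheroid footprint and the cleared region are segmented per frame by
Otsu threshold → largest connected component (≥ `min_object_px`) → hole
filling, with areas in μm²; a user-supplied manual mask can stand in for
the automatic cleared-region segmentation. The clearance rate is the OLS
slope of cleared area versus time over 15 hourly frames; the normalized
rate divides by the initial spheroid area (h⁻¹). Spheroids are classified
by centroid position relative to detected defects within a 750 μm
qualification radius: tail-side of a +1/2 core → `plus_half`; within 45 μm
perpendicular distance of a −1/2 leg ray → `minus_half_on_leg`, else
`minus_half_outside_leg`; otherwise `control`; nearest qualifying core
wins, exact ties going to +1/2. Group comparison is Kruskal–Wallis followed
by pairwise rank-sum tests versus control with Bonferroni correction (the
factor is the number of comparisons actually performed and is recorded).

## Statistics

The tests are implemented directly (SciPy supplies only distribution
functions) so that exact small-sample behaviour is available and every
result is deterministic. Rank-sum uses midranks and, for both groups of
size ≤ 10, an exact two-sided p by enumeration of all rank assignments
(distance from the null mean); larger samples use a tie-corrected normal
approximation with continuity correction, which agrees with enumeration to
within 0.02 at n = 8 per group. Kruskal–Wallis applies the tie correction
and a χ² p-value. One-way ANOVA reports F and pairwise pooled-variance t
tests; with two groups F = t² exactly. Anderson–Darling uses the estimated-
parameter (case 3) statistic with the (1 + 0.75/n + 2.25/n²) correction and
the 0.752 critical value at α = 0.05. Regression CIs are t-based and have
zero width on perfectly collinear data. Two-sided p-values throughout.

## Synthetic scenes

The generator emulates the statistical structure the analysis relies on,
not the cell biology:

- **Director fields.** θ(x) = Σᵢ qᵢ·angle(x − xᵢ) + θ0, mod π (additive
  nematic superposition), with wrapped-Gaussian angle noise of width σ and
  coherence set to the implied order-parameter attenuation exp(−2σ²).
  Cores closer than 20 px are rejected.
- **Textures.** White noise averaged along the local director over a
  streak length (default 20 μm, a cell length) and lightly blurred; the
  2 px minimum streak is the exactly isotropic limit. Structure-tensor
  re-estimation recovers planted orientations to < 5° RMS at zero noise.
- **Defect flows.** Kinematic templates with the observed sign structure,
  not hydrodynamic solutions: +1/2 (defect frame)
  vx = −v0·sign(x)·exp(−r/λ); −1/2 v_φ = −v0·exp(−r/λ)·sin 3δ toward the
  nearest leg plus v_r = +v0·exp(−r/λ) off the leg bands. v0 = 10 μm/h and
  λ = 200 μm were chosen once as typical collective-migration magnitudes;
  the underlying experiments report no numeric flow scale.
- **Nuclei.** Inhomogeneous Poisson points (thinning), Gaussian spots of
  σ = 5 μm whose integral is the planted per-cell intensity. No exclusion
  radius, so spots may overlap.
- **Clearance movies.** Two-channel masks: constant-area spheroid disc and
  a concentric cleared disc with area(t) = rate·t, optionally with
  multiplicative boundary noise (default 5%) emulating manual-tracing
  jitter.

All randomness derives from the single scene seed through independent
numbered streams; a fixed seed reproduces every generator bit for bit.

## Study conditions and problem sizes

The pipeline defaults define the synthetic study: velocity cohorts of 21
+1/2 defects, 9 −1/2 defects, 21 controls (15 used for the angular
control group); density cohorts of 6 +1/2 and 3 −1/2 defects at two time
points 10 h apart; clearance cohorts of 20 spheroids per location class
with planted normalized rates lognormal about 0.25 h⁻¹ (σ_log = 0.5) and a
two-fold suppression on +1/2 cores and −1/2 legs.

The density conditions were fixed by a design-stage power analysis: base
density 2000 cells/mm² with a defect-centered excess of exp(−r/150 μm)
amplitude +0.1 → +1.0 (+1/2, 0 h → 10 h) and −0.5 → −0.25 (−1/2). At much
lower densities or weaker excesses the Poisson noise of the smallest
circles dominates the regression and the slope CI cannot resolve the
planted sign at n = 6 — a limitation of the cumulative-profile method
itself, not of its implementation.

Tests and the README example run reduced cohorts on smaller scenes (e.g.
640–1024 px frames, 1–3 defects) so the whole suite completes in minutes;
the operations are identical, only the sampling is smaller.

## What passing tests do and do not show

Synthetic textures are stationary Gaussian fields; real phase-contrast
images have halos, cell bodies, debris, and illumination gradients, so
real-data director and PIV accuracy will be worse than the planted-scene
figures. The flow templates encode only the observed sign structure;
recovering their signs validates the measurement chain, not any
hydrodynamic model. Planted clearance movies have ideal contrast, so
segmentation accuracy on real fluorescence (bleed-through, uneven staining)
is untested. Defect statistics on real monolayers (densities, speeds,
displacement distributions) are data-dependent quantities this package
measures but does not predict.
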