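# Methods

`octmac` quantifies the optical intensity (mean backscatter gray value, in
arbitrary units on the 16-bit export scale 0–65535) of the eight macular
retinal layers of a 3D OCT scan, per ETDRS sector, and runs the statistics a
normative study needs on top of the per-subject measurements. Because no raw
clinical volumes ship with the package, every stage is validated against a
synthetic phantom and cohort generator that encodes the known structure of
healthy-adult macular scans; the generator is a first-class, tested component,
not a test fixture.

## Phantom model

A phantom is a 6×6 mm macular raster (default 128 columns × 32 B-scans × 256
depth samples; the geometry is parameterized in depth fractions so the same
spec scales to a 512×128 clinical raster). Eleven surfaces bound ten tissue
bands; the reported layers are RNFL, GCL, IPL, INL, OPL, ONL, photoreceptor
(= inner segment + ellipsoid band + outer segment, spanning S7–S10) and RPE.
Voxel ownership in depth is half-open, [S_i, S_{i+1}).

* **Geometry.** Flat stacked bands with nominal thicknesses (fractions of the
  depth axis), a gentle parabolic dome (global curvature), and a foveal pit: a
  radial Gaussian depression (σ = 0.6 mm, depth 35 % of the inner-retina
  stack) applied to S1–S6 with amplitude decaying **linearly in anatomical
  depth offset**, reaching zero at the ONL/photoreceptor boundary. Linear
  decay in depth (rather than in surface index) keeps every inner surface an
  affine interpolant of its neighbours, which is both more physical (the pit
  is a depth-proportional thinning of the inner retina) and what makes
  anatomical-position priors exact on the phantom.
* **Intensities.** Per-band constants at the normative macular profile of
  healthy adults on the Topcon 16-bit scale (RPE 34677 AU down to ONL
  21382 AU; the three photoreceptor sub-bands average, thickness-weighted, to
  the photoreceptor norm of 31760 AU). An optional regional modulation
  multiplies each layer by
  `1 + a_c·exp(−r²/2σ_c²) + s_nt·(nasal offset)`, with the central and
  nasal–temporal amplitudes per layer set from the observed sector profile
  (strong central depression and nasal>temporal for RNFL; central elevation
  and temporal>nasal for RPE; signs per layer as observed). Laterality flips
  the nasal direction.
* **Degradation model.** Axial Gaussian blur (σ = 1 voxel, the optical point
  spread along depth), multiplicative gamma speckle with unit mean (shape
  k = 40, i.e. σ/μ ≈ 16 %, a typical contrast for device-processed SD-OCT
  exports — raw fully developed speckle is far harsher, but exported 16-bit
  intensities are already resampled and filtered by the device), and an
  additive zero-mean noise floor (SD 100 AU). The speckle and floor are
  mean-preserving by construction, so intensity recovery is testable; "
  noiseless" in the tests means all three components off.
* **Re-scan pairs** share one anatomy and differ by fresh speckle, a mean-one
  log-normal intensity gain per scan (SD 1.2 %, chosen so per-layer ICCs over
  a normative cohort land in the observed 0.82–0.94 range) and an integer
  lateral re-centering shift (SD 1 column / 0.3 B-scans). The study this
  emulates reports no between-operator variance components, so these are
  free parameters of the generator.

## Cohort model

Covariates follow the published demographics: ages drawn per decade with the
observed group weights (mean ≈ 46.9 y, SD ≈ 16.9 y, range clipped to
[18, 90]), sex-specific height/weight/axial length, spherical equivalent,
device image quality (58.2 ± 4.4), and optic-disc covariates (disc area,
rim/disc ratio) that carry no true effect. Per-layer intensity is linear:

    y = μ_layer + β_age·σ_layer·z(age) + β_q·σ_layer·z(imageQ) + ε

with standardized coefficients equal to the observed univariate correlations
(age: −0.52…−0.24 from RNFL to photoreceptor, +0.29 for RPE; imageQ:
+0.50…+0.85 for all layers) and residual SD chosen so the total per-layer
variance matches the normative between-subject SD. Covariates are drawn
independently (except the sex-linked anthropometrics), so the generating
standardized β *is* the univariate correlation, making sign-recovery checks
exact. The model is linear in age rather than plateau-then-decline; the
age≥50 Spearman trend tests are therefore conservative restrictions of a
global trend. Residuals can optionally share an equicorrelated component
(global signal strength); the default is independence.

Per-subject phantoms tie the two generators together: each cohort row's layer
intensities are installed into a phantom spec by rescaling that layer's bands
by a common factor (preserving photoreceptor sub-band contrast).

## Denoising

Speckle is reduced by curvature anisotropic diffusion (SimpleITK's
modified-curvature formulation), run per B-scan in 2D — the 512×128 lateral
raster is too anisotropic for 3D diffusion to be meaningful. Intensities are
rescaled to [0, 1] first so the conductance (default 2.0) is expressed on a
fixed gradient scale; time step 0.0625 (the explicit 2D scheme is stable up
to 0.125, checked before any computation), default 5 iterations for the
standalone filter. Two caveats, both measured: curvature flow erodes bright
speckle grains, so the global mean drifts slightly (≈0.5 % at 5 iterations,
≈0.8 % at 10 — the filter is not exactly mean-preserving on multiplicative
noise); and long diffusion times displace *sloped* weak boundaries by a
sub-voxel amount. The denoised volume is used **only** to compute surface
costs; all intensity statistics are computed on raw voxels, so neither effect
touches reported quantities. Whether the original analysis measured raw or
denoised voxels is not stated in its methods; measuring raw is this package's
assumption and is flagged here deliberately.

## Surface detection

Each surface is the exact global minimizer of the summed on-surface cost over
all terrain surfaces z(x, y) satisfying hard smoothness bounds |Δz| ≤ 2
between columns and ≤ 6 between B-scans. The solver is the minimum-closed-set
construction: voxels at-or-above the surface form a closed set in a
vertex-weighted graph whose column weights telescope to the on-surface cost;
intra-column arcs enforce closure, inter-column arcs the smoothness bounds,
and the minimum-weight closed set is a minimum s–t cut (scipy's Dinic
max-flow, int32 capacities). Float costs are quantized by a global affine map
to 32768 integer levels — fine enough to resolve the 24 AU GCL/IPL contrast —
and the optimum is exact for the quantized objective. Per-A-scan depth ranges
are tightened to mutual consistency with the smoothness bounds by separable
1D relaxations before the graph is built; an empty band raises an error
rather than falling back. For speed, production segmentation first runs an
exact per-B-scan dynamic program and solves the 3D graph inside a ±8-voxel
band around it, widening the band whenever the optimum touches a band edge
that is not a user bound; the direct solver remains available and is the one
the brute-force oracle tests exercise.

The cost is the negative signed **backward** axial difference of the denoised
volume, min–max normalized per B-scan, with polarity per surface
(dark-to-bright for the ILM, ELM, IS/OS and inner RPE boundary;
bright-to-dark for RNFL/GCL, IPL/INL, OPL/ONL, OS/RPE and the outer RPE
edge). The backward difference is a deliberate choice: for a step edge —
sharp or symmetrically blurred — the interval [z−1, z] spanning the band
transition gives a unique extremum at the first voxel of the posterior band,
matching the half-open ownership convention, whereas a central difference
ties across two voxels and makes "exact recovery" ill-defined.

Detection is sequential: ILM and outer RPE first on the full depth range,
then each surface inside the band between already-found neighbours minus
1-voxel minimum separations (order: S1, S11, S8, S2, S7, S6, S4, S3, S5,
S10, S9). Surfaces whose gradient contrast is weak carry a quadratic
anatomical-position prior added to the cost, with a flat bottom (no penalty
within 1 voxel of the prior center) so the prior can never override a clean
edge at the true position — that dead zone is what lets the same
configuration achieve exact noiseless recovery *and* sub-voxel speckle
robustness. Prior centers interpolate only between reference surfaces on the
same side of the foveal-pit kink (pit-carrying S2–S6 between pit-zone
surfaces; flat S8–S10 between flat ones; the ELM is anchored to the outer RPE
boundary at a fixed anatomical gap), because interpolating across the kink
biases the center by several voxels at the fovea. The GCL/IPL boundary gets
the strongest prior: its 24 AU mean contrast is genuinely unrecoverable from
gradients under speckle (and its sign regionally flips under the encoded
modulation), which mirrors clinical reality — GCL and IPL are nearly
isoreflective and real pipelines also lean on priors there. The segmentation
default of 3 diffusion iterations (vs the filter's standalone 5) exists
because longer curvature flow moves sloped pit-flank boundaries by ~0.5 voxel
and breaks exact noiseless recovery; it is config-exposed like every other
parameter here.

Known residual imperfection: blur × multiplicative speckle biases
gradient-based boundary location toward the brighter side of an edge by up to
~0.5 voxel (the bright side is noisier, so extreme gradients concentrate
there). All surfaces stay within 1 voxel MAE at generator defaults; the bias
interacts with blur tails to shift adjacent-band means by up to ~2 % (largest
for RNFL at the pit, where its contrast collapses), which is the measured
bound on end-to-end intensity fidelity.

## Quality control

An automated proxy replaces per-B-scan visual inspection: a B-scan is flagged
when any layer's mean thickness leaves [0.2, 3.0]× its nominal anatomical
value (means, so the foveal pinch does not trip them), when a surface jumps
more than 12 voxels between adjacent B-scans, or when the region above the
detected ILM is not substantially darker than the RNFL band (ratio > 0.5 —
this last check catches featureless volumes, which the geometric checks
cannot, because the solver's bands and priors enforce plausible geometry by
construction). The pipeline excludes flagged volumes and logs the reason.

## ETDRS mapping and intensity

The fovea is the deepest point of the (median-presmoothed, 5×3 window) ILM
height map; ties resolve to the centroid of the argmax set, and an argmax set
covering >25 % of the grid is an error (no pit). The grid: rings at 0.5 /
1.5 / 3.0 mm Euclidean mm distance (half-open intervals), quadrants split at
the ±45° diagonals with half-open angular wedges, all computed in mm space
(the raster's pixels are ~4× anisotropic). Orientation convention: x runs
temporal→nasal for OD (mirrored for OS), y superior→inferior; mirroring an OD
grid across the vertical meridian reproduces the OS grid exactly. Charts
clipped by the scan border yield per-sector coverage warnings and zero-count
cells serialize as empty.

Intensity tables accumulate raw-voxel sums, squared sums and counts per
(layer, sector) via per-B-scan cumulative sums along depth, which makes the
fast path bit-identical to a naive triple loop in double precision.
Count-weighted sector means pool exactly to the whole-chart mean (they share
accumulators), and per-cell SDs are population SDs of voxel values — a
per-volume diagnostic, distinct from the across-subject SDs a normative table
reports.

## Statistics

ICC is computed directly from the two-way ANOVA mean squares: ICC(2,1)
(two-way random, absolute agreement, single measures — operators are treated
as a random sample) as the primary estimate, ICC(3,1) alongside, F = MSR/MSE
for significance; zero between-subject variance is reported as degenerate,
not silently. The implementation is cross-checked against
`pingouin.intraclass_corr` in the tests. Stepwise regression is classic
forward selection with removal on z-scored variables (standardized βs):
univariate screen at p < 0.05 chooses candidates, entry at partial-F p < 0.05,
removal at p > 0.10, iterated to a fixed point, with a collinearity guard
(condition number > 1e8 names the offending columns). With both thresholds at
1 it reduces to full OLS. Correlation screens (Pearson/Spearman) report
uncorrected p-values as the primary output — matching the analysis this
package reproduces — with a Holm-adjusted column clearly labelled as an
optional stricter view. Age-decade summaries bin at 20…70+ (under-20 pooled
into the first bin and counted), and the trend statistics mirror the two
reported tests: Spearman r on the age ≥ 50 subset for the declining layers,
all ages for RPE.

## Problem sizes and what the validation shows

The standard validation phantom is 128×32×256 (≈1 M voxels, ≈2.5 s to
segment); the demo cohort is 20 such volumes; statistical simulations use the
study size n = 231 and the reproducibility design n = 44 × 2 × 200
replicates. These sizes were chosen so the whole validation runs on a laptop
in minutes while every check retains clear statistical margins.

Passing tests demonstrate: exactness of the surface solver against exhaustive
oracles; exact noiseless recovery and sub-voxel speckle recovery of
generator-encoded geometry; analytic-accuracy ETDRS rasterization; exact
intensity accounting; calibrated ICC and stepwise machinery; and faithful
end-to-end propagation of the encoded regional and covariate structure
(brightness ordering, nasal–temporal and central patterns, age/imageQ signs).
They do **not** demonstrate performance on real scans: the phantom has no
vasculature or shadowing, no motion artifacts, no pathology, stationary
speckle statistics, and boundaries that are true intensity steps. Two checks
are deliberately statistical rather than literal: the sampled cohort ordering
of GCL vs IPL (true gap 0.09 % against between-subject SDs of ~3 %) is not
identifiable at demo size, so ordering is asserted against the population
profile; and central-pattern agreement for layers whose encoded central
offset is under 1 % is asserted as absolute agreement (±250 AU) rather than
sign, since the sign of a near-zero quantity is noise.
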