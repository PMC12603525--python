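# Methods

This note documents the models, conventions and numerical choices behind
`synmap`, and what its synthetic validation does and does not establish.

## Coordinate and data conventions

All modules share one frame: continuous physical coordinates in
micrometres, origin at the top-left corner of the top-left pixel, x along
columns, y along rows; the centre of pixel (i, j) is at
((j + 0.5)·s, (i + 0.5)·s) with s the pixel pitch (default 68 nm).
Intensities are arbitrary units (a.u.); images are 12-bit data in a
16-bit container, so values are clipped to [0, 4095] and written to TIFF
as uint16. Densities are puncta per 100 µm² of ROI area; ROI area is the
mask pixel count times s², matching the pixel-based detection domain
rather than polygon geometry.

## Synthetic micrograph model

A field is a sum of isotropic 2-D Gaussians A·exp(−r²/2σ²) on a uniform
background, the simplest model of diffraction-limited puncta.

| parameter | default | rationale |
|---|---|---|
| punctum σ | 0.09 µm | PSF width of a 100×/1.45 NA objective at green emission |
| σ jitter | log-normal, shape 0.15 | real terminals show a wide range of sizes; mean preserved |
| amplitude | normal, sd = 0.15·mean, truncated > 0 | intensity heterogeneity without negative draws |
| background | 100 a.u. | mid-range offset typical of 12-bit spinning-disk data |
| read noise | 10 a.u. (Gaussian), after optional Poisson shot noise | standard camera model |
| densities / amplitudes | per-marker values from the bundled survey tables | study-realistic regimes (5–44 / 100 µm²; ~200–520 a.u.) |

With these defaults the field SNR — (mean punctum peak − background
mean)/background sd — is ≈ 16 for the dimmest marker and ≈ 26 for the
brightest, comfortably above the ≥ 10 regime the detector is specified
for. Punctum counts are Poisson with mean ρ·area/100; positions are
uniform. A channel pair (A, B) may carry a paired fraction f: each
paired B punctum is placed on a distinct A punctum within one pixel
(colocalized mode) or displaced by a fixed offset, default 200 nm
(~3 px), in a uniform random direction (juxtaposed mode — the pre/post
separation across a synaptic cleft, chosen so pairs are adjacent but
resolvable; no measured centroid separation was available to calibrate
it). All randomness flows from a single integer seed through one
generator stream, so identical seeds give bit-identical fields.
Rendering evaluates each Gaussian on a ±4σ window (exact to < 10⁻³ of
amplitude); ground truth records everything before noise.

What the generator does *not* emulate: 3-D structure, realistic PSF
shape (Airy rings, asymmetry), chromatic shift between channels, tissue
autofluorescence texture, spatially varying background, or clustering of
synapses along neurites. Passing the recovery tests therefore shows the
pipeline is correct and well calibrated *for fields of isolated
diffraction-limited spots at realistic densities and SNR* — it does not
certify accuracy on tissue artefacts the simulation omits.

## Detection

The response map is a scale-normalised negated Laplacian of Gaussian:
the image is smoothed at σ = radius/√2 (the scale whose normalised
response is maximal for a matched Gaussian blob), the Laplacian is taken
as the exact 5-point second difference, and the result is negated and
multiplied by σ² so bright blobs give positive peaks whose height tracks
amplitude. Using the discrete Laplacian (rather than an analytically
truncated LoG kernel) makes the operator exactly linear and exactly zero
on constant images.

Candidate maxima come from non-maximum suppression with a
(2d+1)-square maximum filter, d = radius in pixels: one detection per
radius-sized neighbourhood, higher response wins, exact plateau ties are
resolved by scan order so reruns are bit-identical. The quality
threshold is absolute, or "auto" = the mean quality of all candidate
maxima (a conservative reading of a "mean quality threshold" knob).
Subpixel refinement fits a per-axis parabola to the response peak
(offsets clamped to ±0.5 px); it reduces localization RMSE from ~20 nm
to ~10 nm on synthetic fields. Border exclusion (margin = radius) avoids
truncated-disc intensity bias and is on by default, but validation
studies disable it because their ground truth covers the whole field.
Punctum intensity is the mean over pixels whose centres lie within the
detection radius of the centroid (disc mean, not peak — the choice is
documented because either reading is defensible; disc mean is less noise
sensitive).

SNR is (mean punctum peak intensity − background mean)/background sd.
If no background mask is given, the lowest-decile pixels serve as a
proxy; note this tail selection underestimates both background mean and
sd, so calibrated SNR work should pass an explicit puncta-free mask
(the test suite does).

## Colocalization

Matching between two channels is one-to-one: among candidate pairs with
centroid distance ≤ d it maximises the number of pairs and, among
maximum-cardinality matchings, minimises total distance. It is computed
exactly by solving a linear assignment problem on each connected
component of the KD-tree feasibility graph; at diffraction-scale cutoffs
components hold a handful of puncta, so dense fields cost barely more
than a greedy pass. A purely greedy ascending-distance matcher was
rejected because it can strand augmentable pairs (A1–B1 = 1, A1–B2 = 2,
A2–B1 = 3: greedy matches one pair where two are feasible); the
implementation is verified against a brute-force maximum-matching oracle
on small instances. One-to-one matching caps the reported percentage at
100 and prevents double counting at high density — which also means
per-subject ratios above 100 % (possible under "any neighbour within d"
counting) are not representable by design.

Distance defaults: 300 nm for colocalization (≈ one punctum radius at
the diffraction limit), 500 nm for juxtaposition; both configurable, and
the mode changes nothing but the default. The reported statistic is
100·n_matched/n_B, the percentage of marker-B puncta containing (or
adjacent to) a reference punctum.

Chance colocalization under spatial independence follows the Poisson
void probability: P(≥ 1 reference punctum within d) =
1 − exp(−(ρ_A/100)·π·d²). The recovery study corrects observed
percentages with a parametric bootstrap instead of this formula:
synthetic B sets with candidate paired fraction f are matched against
the *observed* reference detections and f is solved (secant, two
refinements, 6 replicates per evaluation) so the simulated matched count
reproduces the observed one. The bootstrap captures what the closed form
ignores — occupancy of truly paired reference puncta, border losses, and
the slight inflation of matched counts that maximum-cardinality matching
produces through chain rearrangements (≈ +1 percentage point at the
500 nm cutoff). The analytic formula remains the null model and is
validated directly: with f = 0 the observed matched percentage agrees
with it to within 3 Monte-Carlo standard errors at d ∈ {0.2, 0.3, 0.5} µm.

## Tables and reports

Replicate aggregation is across biological subjects (animals or cases),
never across images within a subject; per-subject values pool all of that
subject's puncta for a region. SEM is sd/√n (ddof = 1); a single
replicate reports SEM 0 with a warning. The cross-region "Mean" column
averages each subject's regional values first, so its SEM is a
between-subject SEM. Display rounding is half away from zero, matching
the printed convention of the source tables; machine-readable outputs
keep full precision. Fraction tables (reference density, summed
denominator, percent) operate column-wise on whatever columns are
supplied: feeding a printed table with its own Mean column reproduces
the printed layout exactly, which is how the bundled mouse tables
round-trip to the published percent rows. (In the human table, the
printed L2, L5 and Mean cells were evidently derived from unrounded
densities upstream of the printed ones — reconstruction from the printed
integers lands within ±1 there, and exactly everywhere else.)

Heatmaps are row-normalised, (x − min)/(max − min) per row, so colours
compare regions within a marker; constant rows carry no contrast and map
to 0.5 with a warning; the transform is idempotent. Cluster ordering is
agglomerative with average linkage on Euclidean distances of the
normalised rows — "similarity" is otherwise underdetermined, so both
linkage and metric are exposed as arguments — and uses the deterministic
dendrogram leaf order.

## Validation study sizes

The density-recovery study simulates one native-size tile (942 × 920 px
≈ 4 000 µm²) per cell of the full 7-marker × 9-region design at the
bundled densities, i.e. ~200–1 600 puncta per cell and ~44 000 overall;
per-marker quality thresholds are 0.12× the marker's mean amplitude
(far above the noise floor, ~2.5× below the dimmest puncta). Typical
results: pooled recall ≈ 0.98, precision ≈ 1.00, worst-cell density
error ≈ 4 %, localization RMSE ≈ 10 nm. Colocalization recovery uses
200 × 200 µm two-channel fields (n_B ≈ 6 400, binomial 95 % CI ≈ ±1.2
percentage points); null calibration uses three 300 × 300 µm fields with
a sparse B channel (ρ_B = 2/100 µm²) so one-to-one competition is
negligible relative to the Monte-Carlo error. These sizes keep the whole
suite and the reproduction script fast while leaving the statistical
tolerances meaningfully tight.

## Known limitations

- 2-D only; no z-stacks or 3-D connectivity.
- Object-based colocalization only; no pixel-correlation coefficients
  (Pearson/Manders), which answer a different question.
- The stitcher assumes overlap-free mosaics (pure abutment); it performs
  no registration and cannot correct stage error or illumination
  gradients.
- Detection assumes roughly isotropic blobs; elongated or merged
  terminals closer than about one punctum radius are detected as one.
- Recovery percentages and CIs assume puncta positions are (conditionally)
  Poisson; strong spatial clustering of real synapses would widen the
  true uncertainty.
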