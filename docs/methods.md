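# Methods

`nucleotopo` quantifies where labeled chromatin loci and nucleoli sit
inside interphase nuclei imaged in 2D, and decides whether two cell
populations differ in that radial organization.  This note records the
models, conventions and numerical choices, what the synthetic benchmark
does and does not emulate, and the limits of what passing tests show.

## Measurement model

A segmented nucleus mask is reduced to a geometric model:

* **circle** (suspension cells such as lymphocytes): center at the mask
  centroid, radius the equivalent-area radius `R = sqrt(Sn / pi)`.  The
  equivalent-area radius is preferred over the bounding circle because
  it is robust to boundary roughness and makes the measured nucleus
  area `Sn` the primary quantity.
* **ellipse** (adherent cells such as MSCs): the moment-equivalent
  ellipse of the mask — semi-axes `a >= b` from the eigenvalues of the
  second central moments (a filled ellipse has variance `a**2/4` along
  its major axis; the per-pixel footprint variance 1/12 is added before
  the eigen-decomposition), orientation `theta` in [0, 180) degrees.
  Masks whose raw moment matrix is singular (collinear pixels) are
  rejected.

Each signal blob contributes its intensity-weighted centroid and pixel
area.  Derived per-signal parameters:

* normalized radius vector `r`: `|p - c| / R` for circles; for ellipses
  the point is rotated by `-theta` about the center and
  `r = sqrt((x'/a)**2 + (y'/b)**2)`.  `r = 0` at the center, `1` on the
  fitted boundary.  Values slightly above 1 (possible on rasterized
  masks) are preserved and flagged rather than clamped; threshold
  splits treat them as peripheral.
* area fraction `S_norm = area_px / Sn`.
* for the two homolog signals: normalized center distance `d_norm`
  (divided by `R`, or by `sqrt(a*b)` for ellipses — the geometric-mean
  radius preserves the circular limit; the normalization is a package
  convention recorded in output metadata) and the central angle
  `alpha` in [0, 180] degrees, undefined (flagged) when a centroid
  coincides with the nucleus center.  Pair metrics are computed only
  when exactly two FISH blobs survive filtering; other nuclei are kept
  and flagged, and excluded from d/alpha statistics only.
* signal-to-nucleolus surface distance: minimum Euclidean distance from
  the FISH centroid to any nucleolus boundary pixel, zero inside a
  nucleolus, reported in px and normalized.

## Segmentation

Schematic-style rasters (dark background, colored nucleus, saturated
signals) are thresholded with Otsu's criterion — on the whole nucleus
channel for the nucleus mask (red for FISH/PI images; inverted
luminance with a 3-class Otsu for bright-field Ag images, whose
histograms are trimodal), and on the within-mask histogram for signal
channels.  A fixed threshold can be forced per channel.  The nucleus is
the largest connected component (holes filled, >= 200 px); masks
touching the image border are flagged and excluded downstream.  Signal
components are 8-connected, components below `min_area` (5 px) are
dropped, and components separated by gaps up to `merge_gap` (2 px) are
reunited, since a single decondensing signal can rasterize into
fragments.  AgNOR polarity is a config field: silver-stained nucleoli
are dark on a light nucleus, PI-saturated nucleoli in FISH images are
detected in the red channel.

## The 3D-to-2D projection null model

Fixed, flattened nuclei are modeled as a unit sphere that is randomly
oriented (isotropic unit-quaternion rotations, exact SO(3) uniformity),
compressed along Z by a factor `c`, and orthogonally projected.  The
placement laws are `surface` (loci on the envelope), `ball` (uniform by
volume) and `shell(ain, aout)` (volume-uniform between two normalized
radii; a radius-uniform density is available as an option).  Planar
radii are normalized by the projected outline radius, so for Z-only
compression the projected-radius law is *independent of c* — the
flattening step is executed and the invariance is asserted by test
(KS D < 0.01 between c=1 and c=0.5 at n=1e5) rather than assumed.
Whether a physical flattening also rescales x,y (volume conservation)
is irrelevant to the normalized radius for the same reason.

For a point at 3D radius `rho`, the projected radius is
`rho * sqrt(1 - u**2)` with `u` uniform on (0, 1), so

    F_rho(x) = 1 - sqrt(1 - (x/rho)**2),  x <= rho.

Integrating over the volume-uniform shell density gives the exact CDF

    F(x) = (G(aout, x) - G(ain, x)) / ((aout**3 - ain**3) / 3),
    G(A, x) = A**3/3 - max(A**2 - x**2, 0)**1.5 / 3,

with the surface (`1 - sqrt(1 - x**2)`; median `sqrt(3)/2 = 0.8660`,
mean `pi/4 = 0.7854`, `P(r > 0.75) = 0.6614`) and ball
(`1 - (1 - x**2)**1.5`; median 0.6083) laws as limits.  A direct
quadrature of the same integral is kept in the package and used as the
independent oracle in the tests (agreement to 1e-6).

`fit_placement` inverts the projection: an exhaustive grid search over
`(ain, aout)` (step 0.05, refined to 0.01 around the coarse optimum)
minimizes the exact KS sup-distance between the observed ECDF and the
shell CDF; ties break toward the narrowest shell, then the smallest
inner bound.  From 2000 observations the bounds of a generating shell
are recovered to within one coarse grid step.

Two-point constellations share one rotation and compression per
projection act but are placed independently — no angular correlation
between homologs is imposed, because none is specified by the model.

## Population statistics

Per-signal metrics are pooled across the nuclei of a population
(signals are the observation unit, as when distributions are built from
hundreds of cells); a per-nucleus-median aggregation is available for
sensitivity analysis, since the choice of sampling unit is a genuine
modeling decision.  Two-sample comparisons report both:

* **Kolmogorov-Smirnov**: `D` is the exact sup of |ECDF difference|
  over the pooled order statistics (checked against a dense-grid
  brute-force oracle and scipy).  Its significance ("KS sig") uses the
  asymptotic Kolmogorov law evaluated at
  `(sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D` with effective size
  `ne = nx*ny/(nx+ny)` — the standard finite-n argument; an exact
  small-sample KS distribution is not implemented.
* **Mann-Whitney U**: reported as `min(Ux, Uy)`; the two-sided p is
  exact by enumeration for tie-free samples with `nx + ny <= 16`
  (delegated to scipy's exact method, which the test suite checks
  against an independent enumeration oracle), otherwise the normal
  approximation with midranks, tie correction and continuity
  correction.

Differences are called significant at p < 0.01.  Under the null at
n=30/30 both tests reject at rates within [0.005, 0.02] over 1e3
simulations; the KS test is mildly conservative (about 0.007) — a
property of the discrete statistic itself, since the exact-distribution
test gives about 0.005 at this sample size.

The **fraction split** partitions signals at `r = 0.75` (ties and
`r > 1` go peripheral — the strict inequalities of the usual
presentation leave the boundary undefined, so the rule is explicit in
output metadata) and compares the `S_norm` distributions of the two
groups; the `median S(r>0.75) / median S(r<0.75)` ratio carries a
seeded bootstrap 95% CI (1000 resamples).  A ratio compatible with 1
means signal size is independent of radial position; a ratio above 1 is
the size-disproportionation signature of activation, where only
small-area loci relocate inward.

## Synthetic populations (what the generator emulates)

The generator produces single-nucleus 8-bit RGB crops (one nucleus per
image; multi-cell fields are out of scope) with exact ground truth:

* round nuclei (radius 60 +- 5 px by default) or elliptical nuclei with
  axis ratio uniform in [1.2, 1.6] at equal equivalent radius;
* two FISH homolog signals per nucleus, each with an area fraction
  uniform on [0.02, 0.08] of the nucleus area (the empirical range for
  this kind of probe), placed in 3D by a placement law and projected
  through the null model into the rendered nucleus;
* one or more nucleoli whose *total* area fraction is drawn per nucleus
  and split across `1 + Poisson(1)` bodies (capped at 5 so the bodies
  can stay disjoint);
* additive Gaussian channel noise (sigma 8 by default on the 0-255
  scale).

Condition presets pin the study conditions: `control` places FISH
signals on the envelope and nucleoli in a central ball of normalized
radius 0.5; `activated` moves signals below the 0.75 area quantile into
the shell [0.40, 0.70] while larger signals stay peripheral
(size-dependent movement — the area quantile itself is a generator
convention, varied in tests, because no measured value exists for it),
and moves nucleoli to the shell [0.5, 0.6] with a 50% larger total
area.  The preset radii follow the reported simulation ranges for
resting (0.4-0.5) and activated (0.5-0.6) nucleoli.

Rendering choices that matter to the benchmark:

* Blobs are filled ellipses of random eccentricity <= 1.5 rendered as
  the `target_px` *in-nucleus* pixels closest to the blob center in the
  blob's elliptical metric.  This conserves the drawn pixel area
  exactly (segmentation can be held to exact-recovery standards) and
  gives peripheral signals the crescent, envelope-hugging shape real
  peripheral heterochromatin shows, instead of cutting them in half at
  the boundary.  Consequence: a finite-area blob's centroid cannot
  reach `r = 1`, so measured control ECDFs sit left of the point-model
  curve near 1 — exactly as finite signals must.
* Two truth layers. The sampling layer records the projected placement
  position, whose distribution matches the placement law's closed form
  exactly (the generator invariant).  The rendered ground-truth table
  records the rasterized blob's centroid and pixel area — the
  *measurable* truth that segmentation is scored against.
* Same-channel blobs are kept disjoint so counts are recoverable:
  first by re-drawing the angular position only (rotation about the
  nucleus center preserves each object's `r` exactly), then, for
  concentric conflicts, by re-placing the whole set (a joint hard-core
  thinning; its bias on the radial law is below the 0.01 CDF test
  tolerance at n=1e5).

Not emulated: point-spread functions, chromatic aberration, uneven
illumination, 3D stacks, touching nuclei, hybridization failures and
probe background.  Passing the recovery tests therefore shows the
measurement chain is correct on well-posed schematic input; it does not
certify segmentation quality on raw microscopy, where thresholds and
merge rules must be revalidated per dataset.

## Pipeline and reproducibility

Stages (`generate`, `segment`, `measure`, `compare`, `report`)
communicate only through CSV/JSON/PNG files, so each is independently
runnable and testable; a stage failure names the stage and the missing
path.  Every random procedure takes an explicit seed; (config, seed)
reproduces byte-identical tables, and each run directory carries one
manifest with config snapshot, seeds, per-stage record counts and
sha256 checksums of the tables.

Default problem sizes (Monte Carlo n=1e5; 300 nuclei per condition at
noise sigma 8 for the end-to-end experiment; 1e3 null replicates for
test calibration; 2000 observations for shell fits) are chosen so every
check resolves its stated tolerance with margin while a full validation
run completes in well under a minute on one core.

## Known limitations

* The ellipse model has no ellipsoidal 3D null counterpart; the
  projection model applies to spherical nuclei only.
* The KS significance is asymptotic; at very small n (< ~10 per group)
  prefer the U test's exact p.
* `d_norm` for ellipses divides by `sqrt(a*b)`; other conventions
  (major axis, perimeter-equivalent radius) would scale results by a
  constant factor.
* No multiple-testing correction across metrics: comparisons are
  reported per metric at p < 0.01, matching the analysis style the
  package reproduces.
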