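# Methods

This note records the models, conventions and numerical choices behind
`rootcarto`, in the order the pipeline runs them.

## Coordinate conventions

Arrays are (z, y, x) with the root axis roughly along x; physical
positions are (x, y, z) vectors in µm (x = column index × dx). All
lengths are converted to µm once, at read time; no stage mixes voxel
and physical units.

## Segmentation and morphometry

Nuclei are detected in the DNA channel by global thresholding, hole
filling, small-object removal and 26-connected labelling. The default
threshold is the **triangle method**: nuclei occupy only a few percent
of a root stack, and in that regime Otsu's criterion places the
threshold inside the dim-nucleus intensity range, fragmenting nuclei
into their bright chromocenters; the triangle rule tracks the large
background mode instead. Otsu and a fixed threshold remain available
(`RunConfig.threshold_method`). Hole filling matters because the
nucleolus is a DNA void: without it a nucleus label would be a hollow
shell. An optional distance-transform watershed seeded at local maxima
(minimum seed separation in µm) splits touching nuclei; it is off by
default because the generator's roots are non-touching by construction.

Feature conventions, chosen to be oracle-checkable by direct per-voxel
summation:

* volume = voxel count × voxel volume;
* surface area by boundary-face counting (each voxel face adjacent to a
  different label or the volume edge contributes its physical area) —
  deterministic, and exact for the axis-aligned shapes the oracle can
  enumerate; it overestimates smooth-surface area by a known metric
  factor, which cancels in the within-study comparisons the pipeline
  makes;
* W/H/D are bounding-box extents along the stack axes; re-expression in
  the root frame happens downstream (see shape factor);
* the asymmetry vector is centroid − DNA centre of mass, with Euclidean
  norm; it is identically zero for intensity fields symmetric about the
  centroid.

Curation replaces the manual removal of fused nuclei and background
noise with an explicit volume window [vmin, vmax] (defaults 5–500 µm³)
plus a removal report.

The nucleolus is measured as the largest connected low-intensity cavity
(below half the nucleus' median DNA intensity) whose every voxel
neighbours only nucleus voxels; cavities touching the nucleus boundary
are surface indentations, not nucleoli, and are excluded.

## Root frame

The axis is fitted to the nucleus centroids: centroids are ordered
along their first principal component (oriented so the cloud lies
shootward of the supplied QC position), binned every 12 µm, and a
weighted cubic polynomial is passed through the per-bin transverse
means (the transverse mean of a radially symmetric cloud is the axis
centre; end bins hold few nuclei and carry azimuthal sampling noise of
several µm, hence the occupancy weighting and the global low-order fit
rather than an interpolating spline). The curve is reparametrized by
arclength, z = 0 at the QC projection, and carries a
parallel-transported normal frame, so φ is continuous along z. The
azimuthal origin is a convention — file indices are stable but
arbitrary up to rotation, and all comparisons are partition-based.

Forward mapping projects a point onto the curve by Newton iteration on
(p − c(s))·c′(s) = 0 started from the nearest dense sample; forward and
inverse share the same interpolants, giving round-trip identity to
< 1e-6 µm. Points projecting onto a curve end are flagged as
extrapolated. The QC position is an input (config or ground truth),
not auto-detected.

Cell fate is purely positional:

* **layer** — radial bins at the layer outer radii (defaults, µm:
  vascular 7, pericycle 11, endodermis 15, cortex 20, epidermis 25.5,
  matching the generator's geometry); a radius exactly on a bin edge
  resolves inward; below the QC small radii are columella and large
  radii lateral root cap (LRC); outside the outermost ring the call is
  LRC while z is within the cap extent, else unassigned;
* **file** — azimuths of one layer are clustered by reading the file
  count k off the circular harmonics (smallest k with |⟨e^{ikφ}⟩| ≥
  0.7; cell files sit at near-regular angles, so the k-th harmonic
  concentrates even when φ is noisy at small radii), members going to
  the nearest of the k phase centres; if no harmonic dominates, the
  fallback cuts the largest circular gaps with the count chosen by the
  largest drop in the sorted-gap sequence;
* **T/AT** — per-file mean inter-nucleus z-spacing in the PD, split at
  the largest jump of the sorted spacing means; the denser class is
  trichoblast. Below a 1.3× between-class contrast all files stay
  "n/a";
* **zones** — per file, the spacing baseline is the median of the first
  third of the gaps; the PD/TD boundary is the last nucleus before the
  first gap exceeding k× baseline (k = 1.5), TD/EZ likewise with
  k₂ = 3; per-file boundaries pool by median. The k-factor rule is this
  package's explicit operationalization of "boundary defined by cell
  size increase".

Intracellular nuclear position samples the wall channel along the
radial ray through the nucleus centroid; L1/L2 are the distances from
the outer/inner nucleus edge to the nearest outward/inward wall-signal
peak (peak prominence ≥ 25% of the line maximum).

## Morphometrics

The **shape factor** is the nucleus' extent along the local root axis
over its extent along the radial direction. Extents along arbitrary
directions are derived from W/H/D by treating the nucleus as the
bbox-inscribed ellipsoid: width along unit u is 2·√(Σ(extᵢ/2·uᵢ)²).
This makes a sphere's factor exactly 1 for any frame orientation and
swaps to the reciprocal when axial and radial extents swap. Whether
"width" is axial or radial is a convention; here the numerator is
axial, held fixed everywhere.

**Relative ploidy**: the calibration cohort is every nucleus with
|z| ≤ 15 µm outside columella/LRC (the initials around the QC carry 2C
without needing lineage identification); the cohort **median** (robust
to a contaminating 4C nucleus) integrated DNA intensity is assigned 2C
and C = 2·I/I₂C. C is reported continuously; nearest-power-of-two
binning is a separate optional step. Estimates are scale-invariant by
construction. The in situ map is a long-format (z, r, φ, layer, C)
table; per-layer summaries give the OLS slope of C vs z with 95% CI and
the step position of a two-level piecewise-constant fit (least total
squared error over all split points). DNA-volume trends per layer are
ordinary least squares with slope CIs; slope equality between layers is
the interaction term of volume ~ z × layer.

## Chromatin

**Hue-range colocalization** composes the two marks as an RGB image
(heterochromatin red, euchromatin green, blue 0) and classifies each
signal pixel by hue on the 0–255 scale: 0–15 exclusive red, 16–58
overlay (equal red+green is yellow ≈ 42), 59–255 exclusive green.
Fractions sum to 1 over the signal pixels and are invariant to uniform
intensity rescaling.

**Peripheral profiles** project the nucleus along z (maximum projection
by default, so the profile is insensitive to ellipsoid chord length and
peripheral foci dominate), take the boundary contour of the 1-px-inset
projected mask, and resample intensity at uniform arc steps from a
canonical start (smallest polar angle). One arc parametrization per
nucleus serves all channels, so profiles correlate point-by-point;
correlation is undefined (NaN) when either profile is constant.

**Configuration codes**: each mark's hemisphere fractions are taken
along the local root axis (code 1 = rootward toward the QC, 2 =
shootward) and along the lateral axis orthogonal to both the root axis
and the radial direction (3/4). Voxels exactly on a splitting plane
count half to each side, which makes the code mapping exactly
antisymmetric under mirroring (1_2 ↔ 2_1). A mark receives the code of
its dominant hemisphere when that holds ≥ 55% of the integrated signal
(marginally above ½ = "visibly polarized"; tunable), else "uniform".
The joint code is euchromatin-first. The rootward polarity of code 1 is
arbitrary but fixed; every downstream statistic is invariant to it.

**Frequencies** over the non-uniform joint codes are tested against the
uniform null (equal probability of all 16 axial/lateral combinations —
the expected outcome of random chromatin rearrangement after mitosis)
with a chi-squared goodness-of-fit test; when any expected count falls
below 1 a Monte-Carlo multinomial p-value replaces the asymptotic one,
flagged in the result. Per-code one-sided binomial enrichment p-values
are Benjamini–Hochberg adjusted (the correction is this package's
choice; no particular scheme is canonical for per-bar annotations).

**Anaphase profiling** bins chromatin-mask voxels by distance from a
supplied division plane (point + normal) into equal-width bins per
daughter side and reports mean channel intensity per bin; for
interphase nuclei the default plane is the transverse plane through
the centroid (recent RAM divisions are overwhelmingly transverse),
while explicit mitotic figures supply their own plane.

## Replication

The EdU **noise floor** is background mean + 3 SD measured outside all
nuclei, making every call invariant to uniform intensity rescaling.
Pattern rules, applied in order: S0 if the in-mask mean is at or below
the floor; S1 if the EdU-positive coverage of the mask is ≥ 0.6 (the
dominance rule — mixed appearances with high coverage resolve to S1,
keeping classes exclusive); else S2 if at least 3 discrete foci are
found. Foci are 26-connected components of positive voxels with ≥ 2
voxels — replication foci are flat-topped, where local-maximum
detection merges or fragments them. A positive nucleus matching
neither rule is called S0 with a `positive_but_unclassified` flag. The
0.6/3 thresholds separate the homogeneous and spotted archetypes and
are exposed in `RunConfig`.

Pattern × time contingency uses the chi-squared test of homogeneity
without continuity correction. EdU×mark overlap is the fraction of
EdU-positive voxels that are mark-positive (mark thresholds use the
same background rule), summarized by pattern with t-based 95% CIs.

**Run-length clustering**: within each (layer, file), nuclei sorted by
z (ties broken by id) form a state sequence; maximal same-state runs
pooled across files give the cluster-size histogram per state group
(default S0 vs S1+S2). Single-nucleus files contribute runs of length
1; zone restriction applies before extraction. Under i.i.d. labeling
with probability p the labeled run length is geometric with success
probability 1 − p — the law the property tests check at n = 10⁴. Two
histograms are compared by a chi-squared homogeneity test after
pooling the tail (longest runs first) until every expected count
reaches 5; a single shared bin is degenerate with p = 1. Fitting a
parametric (e.g. inverse-Gaussian) law to cluster sizes is out of
scope.

## Synthetic root generator

The generator is the package's study condition, not a tuning knob. One
placement plan feeds both `generate_root` (rasterized 5-channel stack +
label volume) and `generate_feature_table` (the same generative model
without rasterization, for fast statistical tests; volumes and
intensities then carry multiplicative measurement noise of 3% and 10%
CV respectively).

Geometry (desk scale, one root tip in a 72×72×128 µm stack at 0.5 µm
voxels): concentric files at radii 3/8.5/13.5/17.5/23 µm
(vascular…epidermis; 3/5/6/6/8 files, azimuthally staggered between
layers), an LRC ring at 27.5 µm over z ∈ [−10, 30] µm, and a small
columella cluster below the QC. Nuclei are oriented ellipsoids with
semi-axes (1.8, 2.0, 2.2) µm (radial, lateral, axial); trichoblast
nuclei are axially flattened ×0.5 and their files spaced 1/1.8 of the
7 µm base spacing; LRC nuclei are axially elongated ×1.6; epidermal
volumes grow 0.8%/µm along z. Axial spacing doubles at the PD→TD
boundary (z = 50 µm) and quadruples in the EZ (z = 85 µm). An optional
quadratic bend displaces the axis laterally. Placements are jittered
(clamped) and repaired so every ellipsoid pair keeps ≥ 0.9 µm clearance
— at least one voxel diagonal, so rasterized masks stay disconnected
under 26-connectivity.

Per nucleus: six peripheral chromocenters (antipodal pairs from the
best of 40 randomly rotated orthogonal templates, maximizing the
minimum anisotropically-scaled separation so speckles stay discrete
even in flattened nuclei) at 0.75 fractional radius, radius 0.6 µm,
2.5× DNA weight; a central nucleolus of 0.3 fractional radius with
zero DNA. The DNA channel is normalized per nucleus so its integral is
exactly C × 50 000 AU before noise (an exact linear C readout); C is 2
everywhere except epidermis/cortex beyond the PD/TD boundary (4C), or
a caller-supplied step profile. The euchromatin channel fills the
nucleus minus nucleolus with integral ∝ C; heterochromatin lives on
the chromocenters; both are polarized into the hemisphere named by the
nucleus' configuration code with enrichment 0.8. The default
configuration distribution holds the opposed "1_2" code at 40%, omits
the fully colocalized orthogonal 3_3/4_4 codes, and spreads the rest
evenly; a uniform-null distribution is provided for calibration tests.
EdU follows the assigned pattern (zone-dependent S0/S1/S2 probabilities
of 60/25/15% in the PD, 40/40/20% in the TD, 30/60/10% in the EZ —
roughly a mid-length incubation; S1 homogeneous at 300 AU, S2 as 0.6 µm
foci on the chromocenters at 800 AU). The wall channel is Gaussian
shells (σ = 0.5 µm) at the layer boundary radii. Gaussian noise
(σ = 1.5 AU) and a background of 3 AU complete the default conditions;
tests that state noise-free conditions set both to zero. The
chromocenter count/size defaults are free parameters of the emulation,
not fitted to measurements.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: optical PSF blur and
axial anisotropy, depth-dependent attenuation, intensity bleed-through
between channels, touching or fused nuclei (segmentation's watershed
splitting is exercised only on constructed cases), mitotic figures in
the raster (the anaphase helper builds an idealized pair), irregular
file topology (file bifurcations, patchy T/AT identity), and
tissue-scale deformation beyond a smooth quadratic bend. Recovery
percentages reported by the acceptance script are upper bounds tied to
these idealizations.

## Problem sizes

The reference root holds ≈380 nuclei (≈310 in the shortened
segmentation-recovery stack); classifier accuracy is measured over two
independent roots (≈760 nuclei); calibration of the two frequency
tests uses 1000 simulated nulls at n = 160 codes and n = 400 nuclei
respectively; the coordinate round-trip uses 10⁴ random interior
points per axis shape; the run-length law is checked at 10⁴ nuclei.
These sizes keep the full test suite and the acceptance script in the
minutes range on a single CPU while leaving every statistical check
comfortably powered.

## Known limitations

* Surface areas are voxel-face areas (≈1.5× a smooth ellipsoid's true
  area at these resolutions); use them comparatively, not absolutely.
* File clustering assumes near-regular azimuthal file placement; highly
  irregular layers fall back to gap cutting, which needs clear gaps.
* The T/AT split needs enough PD nuclei per file (≥3) and a real
  spacing contrast; equal-spacing epidermis yields "n/a", by design.
* Zone boundaries inherit one-cell-spacing quantization from the
  spacing sequence; sub-cell localization is not claimed.
* The hue-range colocalization reproduces a specific composite-image
  protocol; it is not a general colocalization coefficient.
* The configuration-code hemisphere formalization of the pictorial
  orientation nomenclature, and the chi-squared/binomial testing
  scheme, are declared interpretations; how concave/convex mixed
  patterns map to codes is left undefined upstream and they classify
  as "uniform" here whenever no hemisphere dominates.
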