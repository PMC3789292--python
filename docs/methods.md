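# Methods

This note records the models the package implements, the conventions it
fixes where the problem leaves them open, the defaults and why, and what
the synthetic experiments do and do not demonstrate.

## Image model and conventions

All algorithms operate on a single in-memory raster type: a 2D array of
finite non-negative intensities, 0-based (row, col) indexing, origin
top-left, with an optional (row_mm, col_mm) physical pixel spacing and a
declared bit depth (`max_range = 2^bits − 1`).  DICOM MONOCHROME1 images
are inverted on load so higher value always means brighter.  12/16-bit
data stay at native range; only display products (PNG export, enhancement
planes) are rescaled.  Physical measurements refuse when spacing is
absent rather than assuming a detector pitch; non-DICOM sources therefore
never acquire a spacing silently.

Viewer operators: the negative is `max_range − v` (an involution);
brightness is an additive offset and contrast a multiplicative gain
pivoting about mid-range `max_range/2`, chosen so a pure gain change
preserves mean brightness.  Integer images round half-up.  Distances use
per-axis spacing, so anisotropic pixels are handled exactly.

## Fuzzy C-means segmentation

Features are scalar pixel intensities.  The objective uses the squared
Euclidean distance (`norm_power=2`); the unsquared variant is available
behind the same config switch, with the caveat that the weighted-mean
centroid update is then only an approximation of the exact (weighted
median) minimiser.  A sample coinciding with a centroid takes the limit
membership (one-hot).  Defaults: fuzzifier m = 2, ε = 1e−3 intensity
units on the summed centroid displacement, 100 iterations cap.  The fit
is fully deterministic given data and config.

Initialisation is histogram-driven: a 256-bin histogram (exact integer
bins for 8-bit data), smoothed with a width-5 moving average; local
maxima with prominence ≥ 1% of the pixel count become initial centroids,
with the class count clipped to [2, c_max] (the most prominent peaks are
kept when there are too many; a unimodal histogram is supplemented with
the far end of the occupied intensity range).  Constant images are
rejected as degenerate.  Hard segmentation assigns each pixel its
maximum-membership class, ties to the lowest class index.  Contours are
traced with Moore boundary following on 8-connected components and are
returned closed (first point repeated last).

Clustering runs on the raw image by default; noise-robust FCM variants
(spatially regularised objectives) are out of scope.

## Recursive cubic B-spline enhancement

The inverse filter 6/(z + 4 + z⁻¹) factorises over the stable pole
z₁ = −2 + √3.  The cascade is normalised to −6z₁ in the numerator —
equivalently unit DC gain — which the inverse-filter identity test pins:
filtering the computed coefficients with the direct (1,4,1)/6 kernel
reproduces the image to 1e−6 relative error away from a 4-pixel border.
(An alternative printed normalisation of −36z₁ found in the literature
fails that identity by a factor of 6 and is treated as a misprint.)

Boundary handling is whole-sample symmetric (mirror) extension; the
causal recursion is initialised with the truncated mirror sum at
tolerance 1e−8, the anticausal recursion with the standard mirror end
condition z₁/(z₁²−1)·(c[n−1] + z₁·c[n−2]).  The implementation agrees
with an independent banded-system solve and with a second prefilter
implementation to ~1e−7.

Derivatives are the analytic spline derivatives at pixel centres —
(c[k+1] − c[k−1])/2 along the derivative axis seen through the (1,4,1)/6
kernel along the other axis — not plain pixel differences.  Display
planes are min–max rescaled to [0, 255] per plane; a plane whose total
variation is below 1e−6 (e.g. from a constant image) maps to all zeros
instead of amplifying recursion round-off to full scale.  The modulus is
formed from the un-rescaled derivatives and then rescaled, preserving
gradient geometry.  The impulse response of the modulus decays as
|z₁|^d: measured support is 9 px at 1% of peak and 7 px at 2%, which is
what "the enhancement keeps calcium nodes at their original size" means
quantitatively here.

## Adaptive linear-prediction detection

The forward predictor uses a causal quadrant support of
(region_rows × region_cols) past neighbours (default 3×3, i.e. m = n = 2,
8 regressors); the backward predictor uses the mirrored anticausal
support.  Coefficients are fitted per pixel by least squares over a
sliding train_window (default 15×15) — assembled from windowed second
moments and solved through the normal equations with a ridge stabiliser
of `ridge × trace/p` on the diagonal (default ridge = 1e−6).  This
computes the same forward/backward prediction errors that an
order-recursive 2D lattice structure parameterises, without the lattice
recursion itself; the equivalence is at the level of the solved
least-squares problem.

The stationarity score is γ = 1 − (e_f² + e_b²)/(2x²), clamped to [0, 1]:
the squared cosine of the angle between the signal and its projection on
the prediction space, with forward/backward error energies averaged and
normalised by the local signal energy.  Energies are per-pixel by
default; an odd `energy_window` switches to patch-summed energies.  The
per-pixel choice is deliberate: window-summed energies smear the low-γ
footprint of a 1-pixel anomaly across the whole training window, which
makes the ~5-pixel minimum-region rule inoperative — with per-pixel
energies, a modest isolated hot pixel has a footprint of exactly 1 px and
is correctly discarded, while high-contrast lesions flag their
surrounding prediction-dependent ring and exceed the size threshold.
Relative error energies below 1e−10 are snapped to exact stationarity
(γ = 1), absorbing the O(ridge) bias of the stabilised solve; constant
and linear-ramp images therefore score γ ≡ 1 exactly.  Border pixels
without a full support/window are never scored (γ = 1).

Detection thresholds γ at γ₀ (default 0.90), grows 8-connected regions,
discards regions below min_region_px (default 5) and returns ROIs sorted
by area.  The detection mask is monotone non-decreasing in γ₀ and the
size filter can only remove regions.

## Structured reports

The report tree is study → breast (L/R) → projection (CC/MLO) → ordered
findings, with all four image nodes of a regular study always present.
Serialization is a pragmatic Comprehensive-SR content tree
(CONTAINER/CODE/NUM/SCOORD items) on the private coding scheme
`99MAMMOCAD`; no conformance to the Mammography-CAD SR template family is
claimed.  Pixel coordinates are stored 0-based (row, col) with an
explicit descriptor item naming the convention; SCOORD graphic data is
(col, row) per the standard.  Because SCOORD values are single-precision
by VR, each finding also carries a JSON TEXT item with full-precision
coordinates, making the write/read round-trip exact.  Instance UIDs
derive from a content fingerprint, so identical trees serialize to
identical bytes (this underpins pipeline determinism); a JSON sidecar
mirror is always written next to the DICOM file.

## Synthetic phantoms

Phantoms emulate the four BI-RADS density backgrounds as
correlation-length-8px smoothed noise fields on a 12-bit scale, with a
per-tissue calibration table (synthetic, not clinical):

| tissue                | mean | texture sd | clutter rate |
|-----------------------|-----:|-----------:|-------------:|
| predominantly fatty   |   60 |          4 |          0.5 |
| fatty                 |   90 |          7 |          1.5 |
| heterogeneously dense |  140 |         14 |          4.0 |
| dense                 |  180 |         20 |          6.0 |

Mean, texture and clutter all rise with density: dense parenchyma is
brighter and more structured, which is the mechanism behind its higher
false-positive rate.  Clutter spots are 1–2 px blocks at 2.6–4.0× the
background mean — stand-ins for benign/vascular calcifications — and are
never listed in the truth, so every clutter detection is a false
positive.  Masses are plateau discs with a ~1 px shoulder (mean excess
over the truth mask ≈ the requested contrast), optionally with 8–16
decaying radial spicule rays; microcalcifications are square blocks of
the requested side (1–4 px by default).  Additive Gaussian noise
(sd 2.0) tops the image off.  Everything derives from one seed and is
bit-reproducible.  Default size is 256×256 for desk-scale experiments
(the I/O layer is separately exercised at the full 3328×4084 mammogram
frame size).

What the phantoms do **not** model: X-ray physics, scatter, anatomy
(ducts, vasculature, pectoral muscle), compression artefacts, detector
noise statistics.  Passing phantom tests demonstrates the algorithms'
mechanics and the claimed directional behaviours, not clinical
performance on real mammograms.

## Evaluation and the two-pass rule

Matching is greedy one-to-one nearest-centroid within tol_px (default
5 px ≈ lesion radius at phantom scale).  TPD = 100·TP/(TP+FN);
FPD = 100·FP/(TP+FP), a per-detection fraction (the self-consistent
reading of study-style results tables); with zero detections FPD is
reported as 0 and flagged undefined.  When rates are compared across a
set of phantoms, counts are pooled first (study-level rates), which
avoids the bias of averaging per-image ratios with vanishing
denominators.

The two-pass rule shifts γ₀ by ±0.05 by default (configurable): union of
passes (and highlighted findings) for suspected-malignancy studies whose
first pass was empty; pixel-overlap intersection with a stricter pass for
low-risk studies.  The union can only add detections, the intersection
can only remove them, which gives the rule its directional guarantees.
In the seeded experiments, "subtle" lesions are side-3 blocks at contrast
200 over the fatty background (missed at γ₀ = 0.90, recovered at 0.95)
and "obvious" lesions side-3 blocks at contrast 400 (robust to the
stricter 0.85 pass); contrasts sit well inside those regimes rather than
on their boundaries.

## Pipeline

The batch pipeline applies optional preprocessing, the selected
algorithms, and writes per-input artifacts plus a manifest of SHA-256
checksums.  Report timestamps derive from the run seed and SR UIDs from
report content, so a rerun with identical config, inputs and seed is
byte-identical.  Per-file failures are recorded in the manifest without
stopping the batch (CLI exit codes: 0 ok, 1 per-file errors, 2 fatal).

## Known limitations

* The adaptive detector solves dense per-pixel normal equations; memory
  scales as pixels × p², so full-frame mammograms should be processed in
  tiles or with a subsampled stride (not yet built in).
* FCM clusters intensities only; texture- or spatially-regularised
  variants are extension points, not implemented.
* Only the cubic spline degree is supported in the enhancement filter.
* Benign/malignant classification is out of scope; the risk flag only
  gates detection sensitivity.
* The SR reader accepts only documents this package wrote (it names the
  offending concept code when given anything else).
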