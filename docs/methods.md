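# Methods

This note records the models, conventions, and numerical choices behind
`octavd`, and what the synthetic validation does and does not show.

## Coordinate and anatomical conventions

All geometry lives in one raster frame: 0-based pixel-centred
coordinates, x rightward, y downward. Annotation coordinates may lie
outside the raster; in practice the fovea always does, since it sits
roughly 4 mm from the disc centre while the scan spans 2.9 mm. Only the
BMO contour itself must fit on the raster.

Left eyes (OS) are mirrored left-right into a canonical right-eye (OD)
orientation before any computation; sector densities are anatomical
(superior / nasal / inferior / temporal) and therefore mirror-invariant.
In canonical orientation the package takes the fovea to lie image-right
of the disc and superior to be image-up. If a data source uses a
different display convention, the QC overlay (`write_overlay`) makes the
axis and sector placement visible at a glance.

## Sector geometry

The BMO centre (BMOC) is the area (shoelace) centroid of the closed
48-point contour — not the vertex mean, which is biased for irregular
contours. The FoBMOC axis is the ray BMOC → fovea. Sectors are the four
90° quadrants of the axis-aligned frame, half-open
(−π/4, +π/4] for the temporal sector S4 centred on the axis, then S1
superior, S2 nasal (opposite S4), S3 inferior. The angular widths and the
centring of S4 on the axis are a package design decision: the quadrant
layout is the only symmetric four-fold choice, and centring the temporal
sector on the axis is what makes "temporal" mean the same thing in every
eye.

Sector membership is decided by sign tests on dot products with the axis
vector rather than per-pixel `atan2`. Two consequences:

- rotating the scan and annotation by any multiple of 90°, or mirroring
  them, permutes the tests exactly in floating point, so sector labels
  (and hence VD counts) are invariant bit-for-bit;
- values of the test quantities within a 1e−9 relative epsilon of zero
  are snapped to the boundary before the half-open interval rules apply.
  Without this, the float centroid of an exactly symmetric contour
  (a few ulp off the true centre) flips whole boundary rays between
  sectors.

The ONH interior — every pixel whose centre is inside or exactly on the
polygon — is excluded from all counts. The region of interest extends to
the raster edge; an optional outer-radius clip (`--outer-radius-mm`)
supports annulus-style sensitivity analyses but is off by default,
because the anatomical BMO margin, not a synthetic ring, is the point of
the method.

## Vesselness and binarization

The multi-scale Frangi filter uses the fixed parameter set
β₁ = 0.5, β₂ = 15, scales {1, 2, 4, 8} px (geometric ladder from range
[1, 10] with ratio 2; the endpoint 10 is excluded by the ladder but can
be appended with `include_scale_max`). Before filtering, the image is
linearly mapped onto [0, 255]: β₂ only has meaning relative to an
intensity scale, and 0–255 matches the 8-bit-like data the parameter set
was calibrated for. Both the range and the ladder are configurable.

Numerical details that matter:

- second derivatives are Gaussian-derivative convolutions with reflect
  boundary handling (no dark-frame halo at the raster edge), multiplied
  by σ² (γ = 2 normalisation, required for the cross-scale max to be
  comparable);
- kernels are truncated at 8σ. At the conventional 4σ the second
  derivative kernel fails to integrate to zero by ~1e−4, which gives
  constant image regions a spurious Hessian; at 8σ the residual is at
  the 1e−15 level;
- the response is exactly zero where λ₂ ≥ 0 (wrong polarity or no
  structure); elsewhere it lies in [0, 1).

Otsu thresholding operates on a 256-bin histogram over the response's own
[min, max]; candidate thresholds are interior bin edges; vessel means
strictly greater than the threshold. Ties — including cuts separated only
by empty bins, which produce mathematically identical class splits —
resolve to the smallest qualifying threshold, detected with a 1e−12
relative tolerance so that floating-point rounding cannot break the rule.
A constant response (degenerate histogram) raises an error at the module
level; the pipeline maps it to an all-background mask (VD = 0) with a
warning. The threshold is global per scan: the method produces one
binarized vessel map per image, not per-sector or locally adaptive
thresholds.

## Vessel density

vd_k = 100 · n_vessel(k) / n_total(k) exactly, per sector. The overall
`vd_mean` is pixel-weighted (total vessel pixels over total ROI pixels),
which equals the white-to-total fraction of the whole peripapillary
region; the unweighted average of the four sector densities is emitted
alongside (`vd_mean_unweighted`) since both conventions appear in
practice and they differ only when sector sizes differ materially. CSV
output formats percentages to 2 decimals; pixel counts and the threshold
are written at full precision, so results round-trip exactly.

## The phantom generator

`octavd.synthetic` emulates the features of the input the pipeline
actually depends on:

- bright curvilinear tubes radiating outward from an avascular elliptical
  ONH region — the radial peripapillary capillary topology that makes
  sector-wise truth meaningful; centerlines are random walks with a soft
  pull back to the radial direction, widths drawn per vessel from a
  configured range (default 2–9 px, i.e. ~11–51 µm at 5.7 µm/px),
  occasional thinner branches;
- a 48-point BMO contour on the ellipse, two points per each of 24
  simulated radial scan lines; the default ellipse (semi-axes
  120 × 100 px ≈ 1.37 × 1.14 mm diameter) sits slightly off the raster
  midpoint so that no pixel lies exactly on a sector boundary ray;
- a fovea 4000 µm from the BMOC — off the raster, exercising the same
  code path as real data;
- intensities 200 (vessel) on 25 (background) with a 0.8 px Gaussian
  point-spread blur, quantised to 8 bit;
- optional noise: multiplicative Rayleigh speckle (the conventional OCT
  noise family), parameterised as I′ = I · (1 + s·(R − 1)) with R
  unit-mean Rayleigh, because a raw Rayleigh scale parameter would only
  rescale intensities without changing relative speckle contrast; an
  additive Gaussian alternative exists for ablations.

Per-sector target coverages are reached by iterative vessel addition
with rejection: vessels aim at the most deficient sector, a candidate
that would overshoot the target by more than 1.5 VD points is rejected,
and near the target only the segment length (never the width
distribution) is reduced. The loop errors out on infeasible targets
(above ~55%, the practical packing limit of this tube geometry). All
randomness flows from a single seed; identical configurations produce
byte-identical phantoms.

What the phantoms do **not** model: decorrelation physics, projection
artifacts from overlying vessels, capillary meshes below the resolution
limit, motion artifacts, and vignetting. Passing the recovery tests
therefore shows that the geometry, filtering, thresholding, and counting
are implemented correctly and behave sanely under speckle — not that the
fixed Frangi/Otsu parameter set is optimal for any particular device's
real scans.

## Validation results and known bias

Validation problem sizes were chosen to exercise the full-size raster
where it matters and smaller rasters where only logic is under test: the
recovery experiments run 10 noise-free phantoms at the native
509 × 509 px with 35% per-sector targets, plus a speckle sweep at
strengths {0, 6, 12} with 8 phantoms per level and per-sector targets
drawn from U(15%, 45%) so that correlations are informative; unit and
geometry tests use 128–201 px rasters.

The pipeline systematically **overestimates** VD on high-contrast
flat-top tubes: the vesselness response extends roughly half a pixel
beyond each tube edge before the global Otsu threshold cuts it, which at
a mean tube width of ~7 px and 35% true coverage produces a positive
bias of about +4 VD points (mean absolute per-sector error 3.5–4.8
points over the 10-phantom experiment; single sectors can deviate up to
~7 points). This is inherent to Hessian-based vesselness at saturating
contrast, not a counting artifact — the same masks recount exactly
against a per-pixel oracle. Comparisons between groups measured with the
same parameter set are unaffected by a shared bias; absolute VD values
are, as always with this family of metrics, parameter- and
device-specific, which is why every result row carries a parameter hash.
Under speckle the truth–estimate Spearman correlation degrades
monotonically (≈0.96 clean, ≈0.67 at strength 12 in the shipped
acceptance run).

## Limitations

- The 48-point contour is used as-is; no elliptical fit or spline
  smoothing of the BMO margin.
- A single global threshold cannot adapt to regional signal loss
  (e.g. vignetting); poor-quality scans should be excluded upstream
  (the `quality_pass` flag is honoured in batch mode).
- Skeleton-based metrics (vessel length density, calibre indices) are
  out of scope; only area-based VD is computed.
- The two-decimal CSV formatting follows clinical reporting practice;
  downstream statistics should use the pixel counts, which are exact.
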