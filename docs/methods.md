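# Methods

This note records the models implemented, the defaults and why they
were chosen, what the synthetic scenes do and do not emulate, and the
numerical decisions that a maintainer would otherwise have to
reverse-engineer from the code.

## Photometric stereo

The imaging model is Lambertian: a surface element with unit normal
`n̂` and albedo ϱ lit from unit direction `l̂` records radiance
`ϱ·max(0, n̂·l̂)`. Both normals and lights are parameterised in
gradient space — `N = [-p, -q, 1]`, `L = [-ps, -qs, 1]` — with image
coordinates (row, col), x rightward, y downward, z toward the camera.
The clamp at zero models attached shadows (surface facing away from the
light); cast shadows (occlusion by other geometry) are *not* modelled —
they are excluded operationally by the intensity window instead.

Assumptions inherited from the model: the scene is distant relative to
its relief (parallel rays per light), reflection is diffuse, and pixels
used in a solve are lit by every light. The third assumption is
enforced, not assumed: `shadow_mask` keeps only pixels whose intensity
lies strictly inside `(low, high)` in every image, with defaults
`low = 0.02`, `high = 0.98` on [0, 1] intensities. The lower bound
removes attached/cast shadows and sensor noise floor; the upper bound
removes saturation, which field captures are prone to under direct sun.

`solve_ps_exact` inverts the 3×3 light matrix once and applies it to
every pixel; `solve_ps_lsq` groups pixels by their per-light
usable-intensity pattern (a bitmask) and solves each pattern with one
pseudo-inverse, so pixels shadowed in one of four images still get a
3-light solve rather than being discarded. Fewer than three usable
intensities marks the pixel invalid rather than raising: partial frames
are normal in the field.

The two-source variant assumes lights at `(±ps, 0)` — in line with the
platform's direction of travel. The Lambertian ratio
`(I₁ − I₂)/(I₁ + I₂) = p·ps` cancels both albedo and the unknown
y-slope exactly under the model above (substitute the reflectance
expression for both lights and simplify: the `√(1+p²+q²)` and ϱ factors
divide out, and the `q·qs` terms vanish because `qs = 0`). Pixels where
`I₁ + I₂` falls below `2·low` are flagged invalid: the ratio is
noise-dominated there.

### Gradient integration

A recovered gradient field is generally not integrable (noise breaks
`∂p/∂y = ∂q/∂x`), so depth is defined as the least-squares fit: minimise
`Σ (z_neighbour − z − g_edge)²` over all adjacent pixel pairs, with
midpoint-averaged gradient targets. Two solvers share this objective:

* full-frame: the normal equations are a 5-point Laplacian with natural
  (Neumann) boundaries, diagonalised exactly by the DCT-II — a
  spectral Poisson solve in O(N log N). The right-hand side is the
  exact normal-equation divergence including boundary flux terms (a
  plain central-difference divergence silently zeroes constant
  gradients, integrating a ramp to a constant).
* masked: the same least squares assembled sparsely over the valid
  mask only and solved with a direct sparse factorisation, with a tiny
  (1e-9) Tikhonov term pinning the free additive offset.

The output is mean-centred over the valid mask; depth from gradients is
only ever defined up to a constant.

## Curvature analysis and meristem detection

Derivatives of the depth map are Gaussian-smoothed central differences
at scale `sigma` (default 2 px). Before smoothing, the best-fit plane
is removed and its slopes added back to the first derivatives
afterwards: border padding then bends a residual that is ~0 at the
boundary rather than a tilted surface, so planes come out with
curvature at machine noise, not padding artefacts. The valid mask is
eroded by `2 + ceil(2·sigma)` pixels so no reported curvature is
touched by one-sided stencils or the smoothing kernel's support.

Full Monge-patch formulas (with the `1 + fx² + fy²` factors) are used
rather than the small-slope Hessian approximation because leaf slopes
routinely reach O(1). A consequence worth knowing: the shape index is
exactly scale-invariant only in the small-slope limit; at slopes ~1,
rescaling depth moves S by a few hundredths.

HK classification uses the standard 8-class sign table with dead-band
thresholds `eps_H = 2e-3 px⁻¹`, `eps_K = 1e-5 px⁻²`. These defaults
were chosen so a flat field with realistic discretisation noise
classifies as flat while a 50 px-radius sphere (K = 4e-4 px⁻²)
classifies as curved; they are configurable and *not* calibrated to any
particular camera geometry — metric curvatures require multiplying by
the pixel pitch.

Meristem polarity defaults to *pit* (H > 0, K > 0 under the
z-toward-camera convention): a rosette's growing point sits in the
central depression between the leaf bases. Plants whose meristem
protrudes can flip the polarity flag. Candidates are |K|-weighted
centroids of connected pit components of at least `min_blob_px` (5)
pixels, scored by mean |K| — the weighting pulls the candidate to the
curvature maximum rather than the component's geometric middle.

The gradient-histogram detector for two-light data is deliberately a
*scorer contract*: any callable from one L1-normalised histogram vector
to a scalar. The shipped reference trainer is a variance-whitened
class-mean discriminant — enough to demonstrate the scan/heat-map
machinery end-to-end; production use would plug in a proper classifier.
Histogram bin edges are fixed (symmetric over ±1.5 slope units) so
feature vectors are comparable across images; window stride defaults to
half the window; ties in the heat map break to the first window in
(row, col) scan order.

## Weed segmentation

Local entropy is the Shannon entropy (base 2) of the `n_levels`-bin
grey histogram over a centred square window, computed with a rank
filter after reflect-padding so the output matches the input frame and
border windows see plausible texture. Defaults: 32×32 px window, 256
levels. The segmentation thresholds *low* entropy (weed), then opens
(disk 5), closes (disk 9) and drops components under 200 px.

The automatic threshold is Otsu's method on the entropy map, capped at
`0.75·log2(n_levels)`. The cap is load-bearing: Otsu always produces a
split, and on a weed-free scene that split lands inside the high-entropy
grass mode, flagging half the field. Genuine dock thresholds sit well
below 6 bits (dock interiors run 2–4 bits against grass at ~6.6), so
the cap rejects only the degenerate unimodal case. A manual threshold
override is available for calibrated rigs.

Colour input is reduced with the green-excess channel `2G − R − B`
(vegetation vs soil); grass-on-grass scenes should use luminance, where
green excess carries no signal.

## Tuber metrology

The belt plane is fitted by least squares to the deepest
`belt_percentile` (default 60%) of ROI pixels — tubers are nearer the
camera than the belt, so the deepest pixels are belt — with one 3 mm
residual-trimming pass to shed tuber skirts that leak into the sample.
Height above belt is clamped at zero.

The height map is Gaussian-smoothed at 1.5 px before detection and
fitting. This matters: the algebraic ellipsoid fit is noise-sensitive
through the `z²` column (rim points at z ≈ 0 ± noise contribute a
noise-squared bias that mostly corrupts the vertical semi-axis), and
1 mm sensor noise unsmoothed degrades height estimates by tens of
percent. Smoothing at 1.5 px costs a fraction of a millimetre of bias
on 15–55 mm semi-axes and removes most of the variance.

Ellipsoid fitting is the 9-parameter algebraic quadric
`x'Ax + b'x = 1` by linear least squares, on points centred and scaled
to O(1) for conditioning, followed by an eigen-decomposition of A.
Only solutions with all positive eigenvalues are accepted; flat debris
and degenerate regions raise a typed fit failure that the caller turns
into a low-confidence flag. No iterative geometric refinement proved
necessary: with the smoothing above, axes come back within 5% at 1 mm
noise, and a Gauss–Newton polish changed results by less than the
residual noise floor.

Detection thresholds (8 mm height, 150 px area) separate tubers from
belt texture; the fit region is then *grown* down to the 3 mm skirt so
the near-belt rim — which pins the planar semi-axes — is included.
Touching tubers merge at skirt level; the single-ellipsoid fit's RMS
ray-residual exceeding `max_residual_mm` (2.5) triggers a watershed
split of the height map between its local maxima (min separation 10 mm,
min height 5 mm), each part refitted, recursing at most twice. Regions
that cannot be split are returned flagged at confidence 0.5 rather than
dropped.

Sieve size: the tuber passes the grading grid long-axis first, so the
limiting section is the ellipse with diameters (width, height). For an
aperture at angle θ the ellipse's axis-aligned extents are
`2√(a²cos²θ + b²sin²θ)` and its transpose; the sieve size is the
minimum over θ of the larger extent, found by bounded 1-D minimisation.
A dense rotation-grid evaluation (`sieve_size_bruteforce`) serves as
the independent oracle in the tests and supplies truth values in the
synthetic generator. Length is deliberately excluded from grading: the
major axis is the least reliable estimate (tubers are not true
ellipsoids and over-estimate lengthwise), and grading grids sort on
cross-section.

Size bands are half-open `[lo, hi)` on edges (45, 65, 80) mm, giving
labels `<45`, `45-65`, `65-80`, `80+`. Sources differ on whether four
or five bands are used commercially; the band set is a parameter and
everything downstream (records, grids, heat maps) is band-count
agnostic.

The accuracy metric is `100·(1 − |true − est|/est)` — error relative to
the **estimate**, not the truth. This is the form that reproduces every
published field-trial percentage to the printed precision (verified in
the test suite), so it is adopted as-is; note it can go negative for
gross errors and is asymmetric between over- and under-estimates.

Duplicate suppression across overlapping frames gates on centroid
distance within half a tuber width between records of different
timestamps, keeping the higher-confidence record.

## Yield mapping

Positions come from linear interpolation between bracketing GPS fixes;
records more than 5 s outside the track's time span are dropped and
counted. No smoothing is applied — harvester speeds are ~1.5 m/s and
fix intervals ~1 s, so interpolation error is well under a grid cell.
The projection is local equirectangular about the record centroid
(metres east/north); for fields under a kilometre the distortion is
centimetres. Cell size defaults to 5 m. Heat maps are scaled per band
by default (each band's own maximum), matching the use case of
comparing spatial pattern within a band; a flag shares one scale across
bands. Zero-count cells render transparent so maps overlay on imagery.

## Synthetic scenes

The generators are pure functions of their parameters and seed and
return exact analytic ground truth alongside the rendered data:

* **Surfaces** (plane, sphere cap, cylinder, saddle, half-ellipsoid,
  lobed leaf, rosette) have closed-form `z`, `p`, `q`; the rosette is
  radial leaves `g(r)·(1 + ε·cos(nφ))` minus a central Gaussian
  depression whose centre — the meristem — is recorded, with `n`,
  amplitudes and centre drawn per seed.
* **Renders** apply the exact forward model
  `clip(ϱ·max(0, n̂·l̂) + N(0, σ), 0, 1)` and record where the
  no-shadow assumption holds.
* **Conveyor frames** place upper-half ellipsoids (semi-axes drawn
  from 25–55 / 18–45 / 14–30 mm, sorted) at random yaw on a belt
  800 mm from the camera at 1 mm/px, with a 20% touching probability
  realised by placing a tuber in footprint contact with its
  predecessor; Gaussian depth noise (σ = 1 mm in the test conditions)
  and optional 1 mm quantisation emulate structured-light RGB-D
  sensors.
* **Grass/dock** scenes sum four randomly-oriented high-frequency
  noise fields (multi-directional grass texture with a near-uniform
  local histogram) and insert elliptical dock blobs filled with a very
  smooth field (±0.03 grey about a random base). The fill smoothness
  is what makes dock entropy low; a literally binary grass texture
  would itself score ≤1 bit at 256-level quantisation, so the grass
  field is continuous-valued by design.
* **GPS scenes** drive a serpentine track (default 200×120 m field,
  10 m pass spacing, 1.5 m/s, 1 Hz fixes) with Poisson-timed records
  (2 Hz) whose drawn sieve size is consistent with the drawn band.

What passing on these scenes does *not* show: robustness to specular
or wet surfaces, cast shadows from neighbouring plants, mud on tubers,
motion blur, real grass/dock appearance (the discriminator here is
entropy, not appearance — a CNN would need photorealism, this pipeline
does not), GPS multipath, or belt vibration. Those belong to field
calibration, not desk verification.

## Problem sizes and tolerances in the test suite

Scenes are sized for exactness rather than realism: 64–128 px surfaces
for PS and curvature (round-trip errors asserted at 1e-6 rad / 1e-8
relative, achievable because the forward and inverse models are the
same algebra), 512 px grass scenes (IoU ≥ 0.7 asserted against a ~0.87
typical), 20 conveyor frames of 6 tubers (≥90% within 10% asserted
against 100% typical), a 20×20 sieve grid against the brute-force
oracle at 0.1 mm, and exact count conservation in mapping. The
acceptance script re-derives all of these from a single command-line
seed in under a minute.

## Known limitations

* Lambertian only: specular or translucent foliage breaks the PS model;
  no highlight removal is attempted.
* Calibrated lights are required; uncalibrated PS is out of scope.
* Curvature thresholds are in pixel units; metric use requires scaling
  by pixel pitch.
* The ellipsoid fit sees only the top surface; strongly non-ellipsoidal
  tubers bias length high (consistent with the over-estimation the
  accuracy metric was designed around).
* The sieve model treats the grid as a square aperture and the tuber
  cross-section as the (width, height) ellipse; real sieving also
  involves tuber deformation and orientation dynamics.
* The reference meristem scorer is a linear discriminant; it
  demonstrates the contract, not state-of-the-art detection.
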