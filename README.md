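# fieldvision

2D/3D machine-vision toolkit for analysing plants and crops in the
field: photometric-stereo surface recovery for plant phenotyping and
directed weeding, texture-entropy weed segmentation in grassland, and a
depth-camera pipeline that sizes potato tubers on a moving harvester
and maps yield per size band over the field. Every pipeline can be
exercised end-to-end on synthetically rendered scenes with exact ground
truth, so the whole toolkit is testable at a desk.

## Who it is for

Agri-tech and machine-vision engineers building field rigs — tractor- or
harvester-mounted cameras — who need the image-analysis layer: surface
normals and albedo from multi-light captures, meristem localisation for
micro-dose herbicide application, dock detection in grass, and tuber
size distributions tied to GPS position.

## The models at the core

**Photometric stereo (PS).** A fixed camera views a Lambertian surface
`z = f(x, y)` under lights in known directions. With gradient-space
slopes `p = -∂f/∂x`, `q = -∂f/∂y`, surface normal `N = [-p, -q, 1]` and
a light at `L = [-ps, -qs, 1]`, the recorded radiance is

```
R(p, q) = ϱ (1 + p·ps + q·qs) / (√(1 + p² + q²) · √(1 + ps² + qs²))
```

i.e. `ϱ (n̂·l̂)` with albedo ϱ. Three non-coplanar lights determine the
scaled normal `ϱ n̂` per pixel by a 3×3 linear solve
(`ps_core.solve_ps_exact`); four or more lights are solved by least
squares (`solve_ps_lsq`). For a moving platform, two lights on the
camera's x-axis at `(±ps, 0)` give the one-axis gradient by the
albedo-cancelling ratio `p = ((I₁-I₂)/(I₁+I₂))/ps`
(`two_source_gradient`). Depth follows from a least-squares (spectral
DCT or masked sparse) integration of the gradient field
(`integrate_gradients`).

**Curvature analysis.** From a depth map the mean (H) and Gaussian (K)
curvatures are computed with full Monge-patch formulas; the signs of H
and K classify each pixel (peak/pit/ridge/valley/saddle/flat), and a
rosette weed's meristem is found as the strongest *pit* component
(`surface_analysis`). The shape index
`S = (2/π)·arctan((k₁+k₂)/(k₂-k₁))` is also provided, as is a
gradient-histogram sliding-window scorer for two-light data.

**Weed segmentation.** Grass has high-frequency multi-directional
texture (high local Shannon entropy); dock leaves are smooth (low
entropy). A 32×32 px local-entropy filter, a threshold (Otsu by
default), morphological opening/closing and small-component removal
produce the weed mask (`weed_segmentation`), optionally fused with a
depth band-pass.

**Tuber metrology.** Harvester depth frames (mm from camera) are
normalised to height-above-belt by a robust plane fit, thresholded into
candidate regions, and each region's top-surface points are fitted with
a least-squares ellipsoid; touching tubers are detected by the fit
residual and split at the height-map watershed
(`potato_metrology`). Sorted axis diameters give length/width/height;
the *virtual sieve size* is the smallest square aperture passing the
width×height cross-section, binned into the commercial grading bands
<45, 45–65, 65–80 and 80+ mm. Field-trial accuracy is quoted as
`100·(1 − |true − est|/est)`.

**Yield maps.** Tuber records are geo-tagged by linear interpolation
along the harvester GPS track, binned per size band on a local metre
grid, and rendered as blue→green→red heat maps plus GeoJSON
(`field_mapping`).

## Worked example

```python
import numpy as np
from fieldvision.synthetic_scenes import (
    SceneSpec, make_surface, render_lambertian, make_conveyor_frame)
from fieldvision.ps_core import LightSet, solve_ps_lsq, integrate_gradients
from fieldvision.surface_analysis import (
    curvature_fields, hk_segment, detect_meristem_hk)
from fieldvision.potato_metrology import measure_frame, accuracy_percent

# four-light photometric stereo on a synthetic rosette weed
spec = SceneSpec("rosette", {"size": 128}, seed=7)
_, fields_true, mask = make_surface(spec)
lights = LightSet([(0.5, 0), (-0.5, 0), (0, 0.5), (0, -0.5)])
stack, lit = render_lambertian(fields_true, lights, albedo=0.7)
fields = solve_ps_lsq(stack, lights)

# integrate to depth and locate the meristem as the central pit
depth = integrate_gradients(fields)
curv = curvature_fields(depth, sigma=2.0)
cands = detect_meristem_hk(hk_segment(curv), curv, min_blob_px=5)

# conveyor depth frame: measure and grade tubers
frame, truth = make_conveyor_frame(
    n_tubers=4, touching_prob=0.25, noise_sigma_mm=1.0, seed=3)
records = measure_frame(frame)
```

prints (via the formatting in the repo's example script):

```
normals recovered on 16384 px, mean angular error 2.06e-07 deg
meristem: detected (47.7, 73.8), true (47.7, 73.8), score 4.55e-03
tuber at ( 47.5,349.9): L/W/H  68.3/56.9/55.3 mm (true  67.9/56.5/53.0), sieve 56.1 mm -> band 45-65
tuber at (148.8,320.4): L/W/H  85.4/76.1/60.2 mm (true  85.2/75.8/58.6), sieve 68.6 mm -> band 65-80
tuber at (160.3, 71.6): L/W/H  55.8/54.3/52.6 mm (true  55.1/53.6/48.8), sieve 53.5 mm -> band 45-65
tuber at (161.2,246.6): L/W/H  78.9/51.5/45.9 mm (true  78.7/51.5/44.6), sieve 48.8 mm -> band 45-65
accuracy_percent(92, 109) = 84.4
```

The PS solve recovers normals to numerical precision on noiseless
renders; the meristem lands on the rosette's central depression; tuber
dimensions come back within a few percent of ground truth under 1 mm
depth noise and are graded into their sieve bands;
`accuracy_percent(92, 109) = 84.4` is the field-trial accuracy metric
for a caliper length of 92 mm estimated as 109 mm.

## Command line

The `fieldvision` umbrella CLI ties the pipelines together:

```
fieldvision synth sphere --seed 3 --out scene/       # ground-truthed fixtures
fieldvision ps solve --config scene/ps_config.yaml --out ps/ --method lsq
fieldvision ps integrate --fields ps/ --out depth.tif
fieldvision surface meristem --depth depth.tif --out candidates.csv
fieldvision weeds segment --image grass.png --out weeds/
fieldvision potatoes measure --frames frames/ --out records.csv
fieldvision map --records records.csv --gps track.csv --cell 5 --out maps/
```

Every run writes a `manifest.json` (inputs, config hash, versions,
seed) sufficient to reproduce it.

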