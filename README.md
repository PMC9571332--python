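# fingergonio

Monocular marker-based finger-joint goniometry: measure MCP/PIP/DIP joint
angles and phalanx lengths from a single RGB image of a finger carrying
four rectangular visual markers.

Clinical assessment of hand disability relies on the range of motion (ROM)
of the finger joints, conventionally measured one joint at a time with a
mechanical goniometer. An image-based alternative segments four
high-contrast markers taped over the phalanges, extracts their long-edge
lines, and reads all three joint angles from one photograph — faster,
contact-free, and with all joints measured simultaneously. This package
implements that measurement pipeline as a tested library and CLI for
researchers in rehabilitation engineering and biological image analysis,
together with a synthetic scene generator that replaces the acquisition
rig for validation.

## Method

**Calibration.** The camera watches a fixed detection plane, so the full
pinhole model collapses to a planar homography `x ~ H X` between
world-plane coordinates `X` (mm) and pixel coordinates `x`; `H` is solved
from ≥ 4 point correspondences by the normalized DLT, and pixel distances
become millimetres through `X ~ H⁻¹ x`. `H` is only valid while the
plane–camera distance is unchanged, so it is an explicit argument
everywhere (no hidden calibration state).

**Segmentation** (two interchangeable routes):

* *HSV gating* — RGB→HSV with `V = max(R,G,B)`, `S = (V−min)/V`, the
  three-branch hue formula, and the marker-blue gates H 100–130
  (degrees/2 convention), S 150–255, V 130–255;
* *gray thresholding* — BT.601 luma, then `g = 255 if f > T else 0`
  with `T` fixed or chosen by Otsu's between-class-variance criterion.

Connected target regions are traced into closed contours
(Moore-neighbour tracing) and the four markers are selected as the
4-subset with the most similar enclosed areas, ordered along the finger.

**Line extraction** (two interchangeable routes):

* *Canny + Hough* — Gaussian smoothing, Sobel gradients,
  `G = √(Gx²+Gy²)`, gradient direction quantized to {0°, 45°, 90°, 135°},
  non-maximum suppression, hysteresis; then a standard
  `x cosθ + y sinθ = ρ` Hough accumulator detects each marker's two
  long-edge lines — one on the concave (*inner*) and one on the convex
  (*outer*) side of the bent finger;
* *least squares* — the closed-form slope/intercept solution fitted to
  all contour points of a marker, giving its centerline directly.

**Joint angles.** For adjacent markers with direction vectors **a**, **b**
pointing away from their shared joint, `θ = arccos(a·b / |a||b|)`, so a
straight finger reads 180°. The Hough route computes the angle once from
the inner lines (θ_in) and once from the outer lines (θ_out) and reports
`θ = (θ_out + θ_in)/2`. Joint centers are centerline intersections;
phalanx lengths are their world-plane distances when `H` is supplied.

Crossing the two segmentation routes with the two line routes gives four
method variants (`hsv-hoislm`, `hsv-lsflkadm`, `ts-homldm`, `ts-lsflm`);
threshold + Hough (`ts-homldm`) is the default.

## Worked example

Render a synthetic scene with known joint angles (145°, 110°, 115°) and
measure it back:

```
$ fingergonio synth --angles 145,110,115 --seed 42 --out scene.png --truth truth.json
rendered 639x611 scene, truth angles (145.0, 110.0, 115.0)

$ fingergonio measure --image scene.png --method ts-homldm --out result.json
MCP: 144.99 deg (inner 145.03, outer 144.96)
PIP: 110.02 deg (inner 109.99, outer 110.04)
DIP: 115.06 deg (inner 115.09, outer 115.02)
```

Each joint is recovered to within a few hundredths of a degree of the
ground truth; `inner`/`outer` are the two single-side estimates whose mean
is reported. Adding a calibration (here the renderer's own pixel↔mm
mapping) also yields metric phalanx lengths:

```
$ fingergonio measure --image scene.png --homography H.json --out result.json
...
proximal 35.08 mm, middle 21.99 mm
```

against true segment lengths of 35 mm and 22 mm. The same `measure`
command runs unchanged on real photographs of a marked finger;
`fingergonio calibrate --points corr.csv --out H.json` solves the
homography from a `u,v,Wx,Wy` correspondence CSV.

The library API mirrors the CLI:

```python
from fingergonio import SceneSpec, render_scene, run_pipeline

img, truth = render_scene(SceneSpec(angles=(145, 110, 115), seed=42))
res = run_pipeline(img, variant="ts-homldm", h=truth.homography)
print(res.angles, res.lengths_mm)
```

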