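# Methods

## Measurement model

The system measures planar finger motion: the finger moves in a plane at a
fixed distance from a monocular camera, carrying four rectangular visual
markers — one over the dorsal hand/metacarpal and one over each phalanx.
Marker long edges are parallel to the underlying bone, so the angle
between adjacent marker axes is the joint's interior angle (180° =
straight, goniometric convention). Two modes share the machinery:

* **flexion** — the four markers form a kinematic chain along one finger;
  adjacent pairs give the MCP, PIP and DIP angles, with the two phalanx
  vectors at each joint pointing *away* from it;
* **abduction** — the markers sit on adjacent fingers fanning out of the
  palm; positional pairs give the three spread angles directly (no
  reversal, angles of a few tens of degrees).

Because the detection plane is fixed, metric measurement reduces to one
3×3 homography `H` (world mm → pixel) solved by the normalized DLT
(Hartley normalization of both point sets, SVD null space) from ≥ 4
correspondences. Degenerate configurations (duplicates, collinear world
points at N = 4, rank-deficient designs) are rejected with the offending
points named. `H` is an explicit argument of every metric operation: if
the plane–camera distance changes, the caller must re-solve it.

## Pipeline stages and defaults

**Segmentation.** Either HSV gating (H 100–130 in the degrees/2 storage
convention, S 150–255, V 130–255 — the only parameters fixed by the
measurement protocol; blue markers at (30, 60, 200) RGB sit near H = 115,
S ≈ 217) or BT.601 grayscale + threshold. The automatic threshold
maximizes the between-class variance over all 256 candidate levels
(smallest maximizer on ties); constant images are rejected toward fixed-T
mode. The pointwise rule `g = background where f > T else target` is
applied in both raster directions and the two passes are compared —
a mismatch would be an internal error, since the rule is pointwise.

**Contours.** Connected 8-neighbour target regions are traced with
Moore-neighbour boundary following starting at the lexicographically
smallest region pixel; the trace terminates when the (pixel, backtrack)
state repeats, which closes the outer boundary exactly once. Enclosed
area is the shoelace area of the pixel-center polygon; it differs from
the region's pixel count by roughly half the boundary length (the
pixel-center convention), which is immaterial for the area-similarity
filter. The four markers are the subset minimizing the relative area
spread `(max − min)/mean` (exhaustive over subsets, capped at the 16
largest contours; default tolerance 0.25), ordered along the finger by
the minimum-total-length open path through their centroids — robust for
straight and tightly curled chains alike, where a plain principal-axis
projection can mis-order the markers.

**Chain orientation.** Four identical markers carry no image evidence of
which end is proximal. With a `proximal_hint` (a pixel point on the known
proximal side — in a fixed rig the hand position supplies it) the chain
starts at the nearer end; otherwise the convention is the image-left end
of the sign-canonicalized principal axis. The synthetic experiments pass
the renderer's proximal hinge as the hint, emulating the rig's fixed hand
placement.

**Edges and lines.** Canny runs on the segmentation mask (0/255): marker
boundaries are then the only gradients, and the Hough stage behaves
identically for both segmentation routes. Stages: Gaussian smoothing
(σ = 1.4), Sobel gradients, magnitude/direction with the direction
quantized to {0°, 45°, 90°, 135°}, non-maximum suppression along the
quantized direction (`≥` forward, `>` backward — thins two-pixel plateaus
deterministically), hysteresis with low = 50, high = 150 on the Sobel
scale. The Hough accumulator uses ρ resolution 1 px, θ resolution 1°
over [0°, 180°); peaks are 3×3 local maxima above a vote threshold
(default: half the marker's long-edge extent in pixels), sorted by votes
descending with ties broken by (θ, ρ) ascending. Per marker, candidate
lines must be near-parallel (≤ 10°) to the contour's elongation axis and
offset from its centroid; the best-vote candidate on each side of the
centroid becomes one long edge. Each detected line is then refined by a
least-squares fit to the edge pixels within a 2 px perpendicular corridor
(default on; disable via `hough.refine_lines`) — this removes the 1° bin
quantization and is what brings recovery into the few-hundredths-of-a-
degree regime. Inner/outer labels follow chain concavity (cross-product
sign of adjacent chain tangents); a straight chain falls back to an
image-left convention.

The least-squares route evaluates the closed-form slope/intercept
solution on all contour points of a marker. When the x-variance is
smaller than the y-variance the regression runs as x-on-y and records the
axis flag; without the swap, steep marker orientations suffer severe
regression-attenuation bias (≈ 14° at a 105° heading for the default
marker aspect ratio). An explicit `axis=` override forces either form.
Note that even with the swap, vertical-offset regression on a full
rectangle boundary is biased by order `(width/length)²` relative to the
principal axis — about 1–2° at 35° headings for 10 mm × 1.5 mm markers.
This bias is inherent to the fitted-line definition of that variant and
matches the observed pattern that the least-squares variants deviate more
than the Hough variants; the Hough route is the default for exactly this
reason.

**Joints.** The marker centerline takes its direction from the mean of
the two (aligned) edge-line directions and is anchored at the region
centroid, which is sub-pixel accurate because it averages over all
≈ 10³ region pixels; anchoring at the edge lines themselves leaves a
heading-dependent half-pixel bias in the joint centers. Joint center =
intersection of consecutive centerlines; beyond a 175° included angle the
lines are near-parallel and the midpoint of the facing marker endpoints
is used instead. An intersection farther than 400 px from both markers is
rejected as unreliable. θ_in and θ_out come from the inner and outer edge
lines, the reported angle is their exact mean, and lengths are
`world_distance` between consecutive joint centers (proximal = MCP→PIP,
middle = PIP→DIP).

## Synthetic scene generator

The renderer emulates the acquisition rig: four blue (30, 60, 200)
rectangular markers — one shared size, 10 mm × width, with widths
1.5/2/2.5 mm as in the marker-scale study — placed by forward kinematics
of a planar chain with segment lengths (30, 35, 22, 16) mm (dorsal hand,
proximal, middle, distal; realistic dorsal spans, chosen once), over a
skin-toned background (205, 170, 145) with low-amplitude smoothed value
texture (σ_tex = 3), at 0.1 mm/px (a 1.5 mm marker is 15 px wide). The
default pose battery is the three knuckle-hold poses (145, 110, 115),
(160, 130, 110), (150, 165, 130). Illumination levels high/medium/low map
to multiplicative linear brightness ramps of strength 0.05/0.2/0.4 (the
rig adjusts lamp height; no radiometric model is published, so the ramp
strengths are surrogates). After geometry — so the truth is exact — the
scene gets the ramp, a 0.6 px optical blur, and Gaussian sensor noise
(default σ = 2 on the 0–255 scale). Markers are rasterized with 4×
supersampled coverage, giving anti-aliased sub-pixel edges. Everything is
deterministic given the seed; truth corners, angles, lengths and the
pixel↔mm homography are emitted exactly, and `chain_angles_from_corners`
recomputes the angles from the emitted geometry to 1e−9.

What the generator does *not* model: perspective distortion (the rig
fixes the plane–camera distance), lens distortion, specular highlights,
skin creases and hair, marker occlusion or peeling, motion blur.
Passing tests on these scenes therefore validate the geometry and the
operator chain, not robustness to real-skin appearance.

## Evaluation statistics

The figure of merit is the mean absolute angle deviation
`mean(|measured − reference|)`, displayed half-up-rounded (3 decimals for
the four-method comparison, 2 elsewhere) with the raw mean always
retained. `reproduce_printed_tables` recomputes every published
mean-deviation cell from its printed angle inputs and flags cells whose
printed value cannot be obtained from the inputs under the table's
display convention: the four-method-comparison HSV+least-squares mean
(printed 0.967, recomputes 0.977), abduction volunteers 1, 2 and 6, and —
in the in-text 1.5 mm list, whose values are evidently truncated rather
than rounded (so both conventions are accepted there) — volunteers 2, 8
and 9, two of which are fed by obvious input-cell typos (139.74, 159.31).
Flags are reported, never repaired. The published scale-study extremes
(0.27 / 1.38) are likewise contaminated by the typo rows and are checked
structurally rather than numerically.

`run_scale_experiment` replicates the scale study's design on synthetic
data: poses × seeds per marker width, default threshold+Hough variant,
per-scale aggregation with failure counts (never silently dropped),
deterministic per-run seeds derived from the base seed.

## Problem sizes and numerical choices in the test suite

* Recovery battery: 3 poses × 3 widths × 10 seeds (90 runs) under default
  noise; mean absolute error must stay ≤ 1°, mirroring the sub-degree
  deviations the physical system reports. Observed ≈ 0.03–0.05° per
  width — the synthetic scenes are idealized, so the margin is expected.
* Pose grid: 90–180° per joint in 30° steps (64 poses, one seed each), a
  coarse-grid stand-in for a dense sweep, sized to keep the suite fast.
* Four-variant spread: one noise-free canonical scene; every joint within
  2° for all four variants (the least-squares variants' ≈ 1.8° worst case
  is the rectangle-regression bias discussed above).
* Noise monotonicity: σ ∈ {0, 8, 20}, 20 common-random-number seeds.
  Between nearby small σ values the error is raster-floor-dominated and
  noise can act as dither (non-monotone in the 4–12 range), so the
  property is asserted across well-separated levels where it is
  physically meaningful; failed runs score 90°.
* Hough oracle masks are ≤ 64×64 so the brute-force accumulator stays
  cheap; the oracle runs share the binning contract but none of the code.

## Known limitations

* **Low-angle illumination** (ramp 0.4) can defeat the single global
  threshold: the darkened image side drops below T and merges with the
  markers. The physical study likewise selected high-angle lighting; HSV
  gating fails earlier still because V falls below its gate. A locally
  adaptive threshold is out of scope.
* The least-squares variants carry the geometric fitting bias described
  above; they are provided for method comparison, not as the default.
* Proximal/distal labeling without a hint relies on an image-left
  convention and will mislabel a finger pointing right-to-left.
* Abduction pairing is positional; crossed fingers are not detected.
* Hough peak detection does not merge the θ ≈ 0°/180° wrap; marker
  candidate gating makes this harmless in the pipeline, but isolated
  `hough_lines` calls on near-vertical lines can report a split peak.
* Thumb kinematics, DIP–PIP coupling, video smoothing and 3-D extension
  are out of scope.
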