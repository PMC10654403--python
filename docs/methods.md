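# Methods

This note documents the models, estimators, defaults and known limits of
`depotmetry`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Session model

An assay is a time-ordered series of reconstructed 3D grayscale volumes
(multi-page TIFF, z-slices as pages, isotropic voxel size supplied in µm),
an optional pressure trace (CSV: `time_s,pressure_mbar`), and a YAML
config. The reference protocol is 36 volumes at one per 5 min over 3 h
with the pump started 10 min after the acquisition cascade, so frames 1–2
are insulin-free. Frame k is acquired over `[(k−1)·5, k·5)` min; pump
impulses occur at 10, 15, …, 175 min — 34 impulses, strictly before the
session end. Odd-indexed frames are acquired with one rotation direction
and even frames with the other; the two directions carry a slight mutual
tilt, which is why segmentation keeps one reference per parity.

Conventions: 0-based voxel indices, axis order (z, y, x) with z the depth
from the skin surface; lengths in mm, volumes in mm³ (1 mm³ = 1 µL),
surfaces in mm²; intensities are arbitrary linear units (no Hounsfield
calibration is attempted). Missing or unreadable frames are flagged, not
fatal: the morphometry table always emits one row per frame so that
uncomputable frames remain visible downstream.

## Segmentation

Per frame: subtract the matching-parity reference, clamp negatives to
zero, zero the cannula cylinder (nominal radius + 1 voxel dilation, the
partial-volume halo around the Teflon wall), min–max rescale to [0, 1]
(order-preserving, kept for numerical hygiene), binarize strictly above
the 0.95 linear-interpolation quantile of all voxels of the masked volume
(including the clamped zeros — configurable), and keep the 18-connected
component (faces + edges, no vertex diagonals) containing the cannula
tip. No registration is applied; at these infused volumes tissue
displacement is negligible, and an off-by-default hook is the natural
place to add it for larger volumes.

Because the dilated cannula mask can clear the tip voxel and its whole
18-neighborhood, the seeded selection searches, in order: the tip voxel,
its 18-neighborhood, then (radius `r_cannula + dilation + 2` voxels) the
components represented in a ball around the tip, keeping the **largest**
candidate component. Largest-wins matters: with a 5% foreground budget the
noise floor contains small clusters, and the nearest foreground voxel to
the tip is occasionally one of them rather than the depot.

The strict `>` at the threshold guarantees a foreground fraction of at
most `1 − q` plus tie mass (plus a `1/n` discreteness term). Quantile
thresholding makes the whole chain exactly invariant under positive affine
rescaling of the input intensities.

## Surface and volume estimation

Volume is voxel counting times the voxel volume. For the surface, two
estimators are provided:

* **mesh** (default): marching cubes at level 0.5 on the zero-padded mask
  after Gaussian smoothing with σ = 1 voxel. Raw marching cubes on a
  binary mask inherits the voxelization staircase and overestimates the
  area of smooth objects by ~9% (measured on digitized spheres, r = 10–30);
  the 1-voxel smoothing removes the staircase at the cost of a curvature
  bias that decays like σ²·(curvature), i.e. ~1/r for a sphere. On
  digitized spheres the estimator is within 2.1% at r = 10 and 0.1% at
  r = 30, converging monotonically; on digitized cubes (sharp edges, the
  worst case for any smoothing) it reads ~2.7% low at edge 64. Masks are
  measured in a content-determined canonical axis orientation because the
  marching-cubes triangulation itself is not exactly symmetric under axis
  permutation; with canonicalization the estimate is bit-identical under
  grid permutations and integer translations.
* **voxel_face**: exposed-face counting. It overestimates oblique smooth
  surfaces by up to ×1.5 but never underestimates, so `IoD ≥ 1` is
  guaranteed and it upper-bounds the mesh estimate — a useful cross-check
  pair.

Resolution limit: the mesh estimator is only quantitative for features
thicker than its smoothing kernel. Depots a single impulse large
(thin septal sheets, hollow caps around the cannula tip) are under-read by
10–20%; the test suite applies its 10% STVR tolerance only to depots of
at least ~10³ voxels, and first-impulse IoD values should be read as
qualitative.

`V_compact` is never stored: the compact reference sphere is defined to
hold the measured volume, so `V_compact(t) ≡ V_measured(t)`.

## Aggregation

Across assays on a shared time grid: per-step mean and sample SD (n−1;
group sizes are small), the mean of per-step SDs as a scalar variability
summary, and final-time IoD per assay (value at the last non-flagged
frame; assays with no measurable frame are excluded) summarized as
min/Q1/median/Q3/max with linear-interpolation quartiles.

## Layer classification

The primary label follows what the cannula tip reached: extradermal above
the epidermis depth, intradermal in the dermis, "limit" within a band of
±3 voxels (~51 µm at 17 µm voxels) around the dermis–hypodermis boundary
— the limit class is visual in origin and carries no stated tolerance, so
the band width is an explicit, documented parameter — and hypodermal
below. Depot volume fractions per layer are computed independently from
the mask (flat boundary depths by default; per-(x,y) boundary surfaces
accepted), and spread notes are emitted when ≥5% of the depot lies outside
the tip's layer.

## Pressure analysis

Two-scale decomposition: a centered rolling median (60 s window) is the
low-pass component; impulses are detected on the high-pass residual after
a 1 s moving average (roughly matched to a pump stroke's width, it
suppresses sample-level sensor noise without displacing peaks) via peak
picking with 10 mBar prominence and 60 s minimum separation. Step
elevations are maximal intervals where the low-pass component exceeds a
baseline by ≥50 mBar for ≥600 s, re-validated against a local pre-onset
baseline (300 s rolling median); events lasting ≥1800 s are flagged as
occlusions. All thresholds are exposed because the protocol states none.
Both detectors are baseline-relative, hence invariant to adding a constant
to the trace. Elevation onsets are matched to the acquisition frame whose
interval contains them, and reported together with whether the previous
frame had an air bubble in the cannula (annotations come from phantom
ground truth or an external CSV; visual in origin for real data).

The sensor sampling rate is unspecified in the protocol; the phantom
defaults to 10 Hz.

## Phantom

The generator emulates what the pipeline exploits, at a scaled-down field
of view (default 96×128×128 voxels at 17 µm — a few mm around the
infusion site rather than a full 17 mm explant, keeping desk-scale runs
tractable; all reported quantities are either dimensionless or in
physical units, so the scale does not enter the conclusions):

* layered background: air, a dense dermis band, hypodermal lobules
  (intensity 100) divided by septal walls (140) formed by the boundaries
  of a Voronoi tessellation of 24 random centers; walls are 3 voxels thick
  (post-bariatric explants have thickened, fibrotic septa, and the wall
  thickness sets the sheet thickness of a septal depot);
* a vertical cannula (radius 2.5 voxels, scaled like the field of view)
  whose lumen can contain an air segment on scheduled frames, and an
  occlusion mode with no depot growth and suppressed impulses up to a
  given frame;
* depot shapes: `sphere`, `cube`, `cylinder` (closed-form volume/surface
  oracles, nested by construction) and `septal_growth` (default): from a
  seed cap around the cannula tip, 1500 voxels per impulse are added on
  the 18-connected frontier, choosing septal-wall voxels with probability
  0.9 when available — which keeps ≥80% of the depot on walls and
  reproduces a monotonically rising IoD. Depot intensity is 190, i.e. a
  contrast of 50 over the walls it grows along; with the default image
  noise SD of 10 this is a contrast-to-noise ratio of 5 (defined as the
  minimal depot contrast over the replaced background divided by the
  single-image noise SD). The depot never enters the cannula's one-voxel
  partial-volume halo: a voxel there is indistinguishable from the Teflon
  wall and is removed by any cannula-masking analysis, so the phantom
  models the *measurable* depot;
* an optional 0.3-voxel translation of even frames emulating the
  rotation-direction tilt (it exercises the dual-reference logic: the
  matching-parity subtraction cancels it exactly, the wrong parity leaves
  septal residue);
* additive Gaussian noise, deterministic per (seed, frame index); the
  pressure trace adds triangular impulse spikes (2 s wide, 30 mBar — the
  true stroke waveform is unspecified, only that impulses are easy to
  identify), optional step plateaus with 5 s ramps, optional ±340 mBar
  saturation clipping, and Gaussian noise (SD 1 mBar).

What the phantom does **not** emulate: ring/beam-hardening artifacts
(handled upstream by the scanner's Al filter), anatomically realistic
septal geometry, tissue deformation under infusion, X-ray physics, or
flow/porous-media transport. Passing tests therefore demonstrate the
correctness of the measurement chain under the stated image-formation
model, not performance on arbitrary real scans.

## Evaluation choices

* Voxel-level recall/precision against ground truth is evaluated on
  tilt-free phantoms: under a sub-voxel translation the boundary voxels of
  the true depot are fractionally occupied and have no true binary label,
  so voxel-exact metrics would measure the rounding convention rather than
  the segmentation. The tilt path is validated separately (exact
  cancellation by the matching-parity reference).
* IoD calibration uses digitized spheres (r = 10…30) and cubes
  (edge 64) with closed-form references; the growth law uses an
  elongating cylinder (radius 3, length 45→225 voxels) whose IoD follows
  `L^(1/3)` up to cap corrections, run through the full
  simulate→segment→measure pipeline.
* Problem sizes in tests and in `scripts/acceptance.py` (the default
  phantom grid, 36-frame sessions, 10⁶-sample quantile checks) were chosen
  as the package's own desk-scale validation conditions.

## Known limitations

* The mesh surface estimator's accuracy degrades for sharp-edged objects
  (−2.7% on a 64-voxel cube) and for sub-kernel features (see above);
  `voxel_face` is exact for axis-aligned faces but badly biased for
  oblique smooth surfaces. No single local estimator is exact for both at
  voxel scale.
* The quantile threshold ties the foreground budget to `1 − q`: when the
  depot occupies far less than that, the threshold sits in the noise tail
  and precision relies on the seeded-component selection; when the depot
  approaches the budget, recall drops. The defaults are calibrated for
  depots between ~0.1% and ~5% of the volume.
* Layer boundaries are config inputs (flat by default); no automatic
  boundary detection from image texture is attempted.
* Bubble annotation of real data is external; only the phantom provides
  it automatically.
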