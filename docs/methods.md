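# Methods

This note documents the models, numerical choices and limitations of the
processing chain. Everything quantitative stated here is computed by the
test suite or the acceptance script; nothing is asserted from memory.

## Segmentation model

The chain assumes passive thermography in a controlled room: the limb has
equilibrated with the environment but remains warmer than the background,
so the temperature matrix itself separates RoI from scene. The stages are

- **Normalization** — per-frame affine map onto [0, 1]. A constant frame is
  rejected as degenerate (there is nothing to segment). Because the map is
  per-frame, everything downstream is relative to the frame's own extremes;
  this is what makes the method automatic, and also what creates its
  failure mode (below).
- **Thresholding** at τ ∈ (0, 1), default 0.8. Cells exactly equal to τ are
  kept (the comparison is ≥). Thresholding is idempotent and raising τ can
  only shrink the foreground (both are property-tested).
- **Binarization and 4-connected labeling** (Manhattan radius 1, diagonals
  do not connect). Labels follow raster order of each component's first
  pixel; components carry area, centroid, bounding box and a border flag.
- **RoI selection** — largest area, ties broken by centroid distance to the
  frame center, then by smallest label. The limb is central and larger than
  any interference under the stated acquisition conditions; no anatomical
  prior or classifier is used, which keeps the method applicable to any
  warm RoI. No morphological opening/closing is applied: holes inside the
  RoI are genuine radiometric structure and are preserved.
- **Cleaning** — all non-RoI components are zeroed in the thresholded
  array. RoI temperatures are always read back from the *original* Celsius
  grid; the chain never alters a temperature (tested exactly).

**Documented failure mode.** If an interference is hot enough that, after
range normalization, every limb pixel falls below τ, the limb becomes
background and the interference is selected. The exact boundary follows
from the normalization algebra: the limb survives iff
`(foot_max − min) ≥ τ·(frame_max − min)`. The phantom exposes a helper that
constructs a super-critical blob, and the suite asserts the failure
*occurs* — it is a property of the method, not a bug. The practical
remedy is an insulated background, as thermography protocols already
recommend. We deliberately do not hard-code a percentage bound for the
tolerable interference contrast; it depends on the frame's dynamic range,
and τ is the exposed control.

## False-color rendering and its inverse

Rendering uses a 256-entry colormap lookup table (default jet). Entry 0 is
reserved for the background; RoI values are mapped linearly over entries
1–255 from the RoI's lowest surviving normalized value to 1, which both
boosts intra-RoI contrast and guarantees no RoI pixel can collide with the
background color. 8-bit quantization of jet collapses a few neighboring
entries onto the same color (the saturated-blue corner); colliding entries
are nudged by single 8-bit units so the table is injective and therefore
exactly invertible by nearest-color lookup — inversion recovers a value to
within half a quantization step, and the full render→invert round trip is
tested to one step.

## Fusion geometry

The bifocal camera fixes the two sensors' relative geometry, so no
registration is estimated: the visible 480 × 640 photograph is rescaled by
1.25 (bilinear), the 240 × 320 overlay is alpha-composited center-aligned,
and the central 400 × 300 window is cropped. Scale, alignment offset and
crop are configuration parameters because different hardware pairs sensors
differently. Two deliberate asymmetries: the visible image may be
interpolated (it is scenery), the IR overlay never is (interpolating across
the RoI edge would fabricate temperatures). Background keying uses the
segmentation mask as ground truth, with exact-color chasing of the recorded
background sentinel kept as a compatibility path for externally produced
renderings — exact-color keying alone is fragile across colormap
implementations. At the binary opacities used in practice (0 and 1) the
compositor passes pixels through untouched, so the merged image is
bit-identical to the rescaled visible frame outside the RoI footprint and
to the overlay inside it (tested across seeds against a brute-force
per-pixel compositor).

## Angular-emissivity model

The error of a viewpoint θ against the normal view is modeled linearly:
`ΔT = (T_n − T_θ)/(T_n − T_a)`, with `T_n`, `T_θ` averages of a homogeneous
reference zone and `T_a` the room temperature. The record stores the
*signed* value — skin reads warmer at oblique angles, making ΔT negative —
and reports the magnitude as a percentage, matching how such errors are
published. Compensation adds the constant `T_n − T_θ` to RoI pixels only:
the model is one scalar per frame, and shifting the background would
corrupt the segmentation contrast of any later re-processing (the
background/RoI switch is exposed in the API via the mask argument).
Constant shifts preserve all pairwise temperature differences, so the color
distribution inside the RoI is unaffected; only the temperature scale
moves. For sweeps extending past the measured 0–90° profile range, the
profile is folded by angular distance to the normal view and linearly
interpolated (clamped beyond the last sample).

The default reference zone is a centered box spanning 40% of the RoI
bounding-box height and 20% of its width — tall and narrow so it stays on
the limb even in oblique views where the silhouette thins; on real data the
zone between metatarsal and heel should be supplied explicitly.

## Colorbar limits

Per-frame RoI extrema (background excluded by construction) are averaged
into set-level limits; their sample standard deviations (n−1; 0 for a
single frame) quantify stability across viewpoints. Display mapping clamps
out-of-range temperatures instead of erroring: limits are averages, so
roughly half the frames must exceed them. Extrema are taken *after*
compensation — the pipeline orders calibration offset → segmentation →
compensation → rendering/fusion → scale association → export.

## Mesh bridge

3D reconstruction itself is external (COLMAP, Open-MVS); the bridge writes
the numbered merged-image sequence with a JSON manifest, reads the textured
OBJ/PLY result (trimesh), and re-attaches temperature by sampling each
vertex's texel (nearest-neighbor, to avoid blending RoI and scene colors at
the silhouette edge) and inverting the recorded colormap. A color farther
than 8/255 per channel from every table entry — a tolerance for the slight
blurring MVS texturing introduces, configurable — is non-thermal: the
visible-light background can never acquire a temperature.

## Phantom generator

The phantom emulates the acquisition conditions the chain is designed for:

| parameter | default | rationale |
|---|---|---|
| frame shape | 240 × 320 | IR sensor resolution |
| visible shape | 480 × 640 | visible sensor resolution |
| sweep | 0°–168° in 12° steps (15 views) | acquisition protocol |
| foot temperature | 34 °C + ≤1 °C row-wise gradient | plantar skin range |
| background | 22 °C | insulated backdrop near room temp |
| room temperature | 20 °C | controlled environment |
| pixel noise | Gaussian, sd 0.05 °C | sensor thermal sensitivity ≤ 50 mK |

The silhouette is an ellipse with three toe bumps whose horizontal
semi-axis scales with |cos θ| (floored at 0.35 of its frontal value):
shape realism is irrelevant to chain correctness — only area, centrality
and contrast matter. The within-region gradient depends on the row only,
so a fixed reference zone sees the same gradient at every viewpoint; this
makes an exactly additive drift exactly compensable (to ~1e-15 °C in
practice), which is the point of that test: it isolates the compensation
arithmetic from confounds. Interferences are stamped with a max rule (a
blob can only warm pixels). Visible frames are checkerboard plus coarse
value noise with a skin-toned silhouette — enough texture for external SfM
feature detectors, generated deterministically. Seeds drive two
independent child generators (IR, visible) so the IR stream is identical
whether or not visibles are rendered; fixed seeds give bit-identical
output.

**What the phantom does not model:** anatomical shape, vascular temperature
patterns, motion between captures, camera optics (vignetting, defocus),
emissivity variation *within* the skin surface, and non-additive angular
effects. Passing tests therefore demonstrate the correctness of the
processing chain under its stated assumptions, not clinical performance on
real feet.

## Problem sizes and numerical notes

The suite exercises 200 seeded full-size sweeps (3 000 frames) for mask
recovery, 20 sweeps each for colorbar stability and fusion conservation,
and 5 for compensation recovery; jitter-recovery Monte Carlo (200 seeds)
runs on 80 × 104 frames since the statistic is size-independent. Exact
comparisons are used wherever the arithmetic is exact (masks, pass-through
pixels, round trips at shortest-repr precision); 1e-9 °C bounds cover
floating-point accumulation in means and constant shifts. Degenerate
inputs: constant frames are errors, empty RoIs are warnings (batch sweeps
continue), τ and opacity are validated before any I/O.

## Known limitations

- One RoI per frame; multi-limb scenes need cropping upstream.
- The interference-size assumption (smaller than the limb, near borders)
  is structural; a central interference larger than the limb wins.
- The 1.25/centered fusion geometry is hardware-specific; other cameras
  need their own scale/offset, for which no estimator is provided.
- Colormap inversion is meaningful only for textures produced by this
  chain (or repainted with the recorded table); arbitrary thermograms
  cannot be inverted.
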