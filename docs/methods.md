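# Methods

This note documents the models, parameters and numerical choices behind
`petrisynth`, and what its tests do and do not establish.

## Clustering

Colonies on crowded plates overlap, so pasting them individually would
destroy the geometry of their shared edges. Two colonies are linked when
their bounding boxes overlap by strictly more than a threshold fraction
(default 0.01) of the *smaller* box's area; connected components of this
graph, found by breadth-first search, are extracted and pasted as units.
The "smaller area" denominator is a deliberate choice: the overlap
criterion is then symmetric and fires whenever either colony loses more
than 1% of itself, which matters only for extreme aspect-ratio pairs.
Components are emitted in ascending order of their smallest member with
members sorted, so downstream sampling is reproducible.

## Extraction chain

Per cluster, the union rectangle of member boxes plus a margin
(`cutout_margin`, default 5 px) is cut out together with the boxes' mask
m_bx (zero wherever no member box covers the pixel).

* **Unsharp mask** (`unsharp_radius` 3 px, `unsharp_amount` 1.0) sharpens
  colony rims before thresholding and segmentation. The filter is applied
  to floats in [0, 1] and clipped. (Implementation note: scikit-image's
  `unsharp_mask` is called with a positive `channel_axis`; a negative axis
  miscomputes on multichannel input in the installed build.)
* **Dark-artifact removal.** A pixel is an artifact when L\* <
  `dark_L_threshold` (default 40, scale 0–100) or b\* < `dark_b_threshold`
  (default −5): dark ink and bluish print on a bright substrate. The
  thresholds are absolute, not adaptive — plates with intrinsically dark
  colonies may need them lowered, which is why both are exposed. The mask
  is dilated (`dark_dilate_radius` 2 px) and each flagged pixel is replaced
  by the first valid pixel met by a uniform 8-neighborhood random walk
  started at it. Walks read donors from the frozen input (never from
  already-replaced pixels), are seeded by `rng_seed` and capped at
  10 × the fragment perimeter steps, after which the nearest valid pixel by
  Euclidean distance is used. An all-artifact fragment is an error.
* **Non-local means** (`nlm_strength` 15 on the 0–255 scale, `nlm_patch`
  5 px) cancels the speckle introduced by the random walk. 15 was chosen
  once as the smallest default that actually suppresses impulse noise at
  1% density while leaving colony boundaries sharp enough for segmentation;
  at ≤ 10 the patch-similarity weighting leaves isolated outliers intact.
* **Chan–Vese** runs on the luminance channel with smoothing weight `cv_mu`
  (0.25), checkerboard initialization, dt 0.5, and at most `cv_max_iter`
  (200) iterations. The foreground phase is the one whose mean luminance
  differs more from the fragment border's mean — the border is substrate
  when the margin is adequate. A constant fragment yields an empty mask
  with a warning. The mask is dilated by `seg_dilate_radius` (2 px) so
  colony edges survive.
* **Blending mask.** m_b is the per-pixel Euclidean CIELab distance to the
  mean background color (pixels outside m_s), normalized by the fragment
  maximum to [0, 255] and shaped by `blend_gamma` (1.0). Normalizing per
  fragment guarantees the full opacity range is used; the cost is that m_b
  values are not comparable across fragments, which is irrelevant because
  each cutout is composited independently. CIELab conversion assumes sRGB
  with D65 white.
* **Alpha.** alpha = m_bx ∘ m_s ∘ m_b with binary masks as 0/1 factors. A
  cluster whose alpha is identically zero is dropped with a warning.
  Per-colony masks are alpha > 0 restricted to each member box.

## Composition

Backgrounds are 512×512 (default) crops of a uniformly rotated empty dish,
drawn uniformly among windows free of rotation fill. Per patch one species
is sampled uniformly and a colony target is drawn from Exponential(mean
`count_mean` = 10), rounded half-up with zero allowed — empty patches exist
on real plates. Cluster cutouts of that species are drawn with replacement;
each draw gets up to `max_place_attempts` (50) random poses (rotation in
[0, 360), independent flips, uniform position), and a pose is accepted when
its alpha footprint, dilated by one pixel, is inside the patch and disjoint
from all previous footprints. Footprints rather than boxes are tested
because cutouts of overlapping clusters have loose boxes that would
over-reject. Placement stops when the cumulative colony count reaches the
target (a multi-colony cluster may overshoot; the actual count is recorded)
or after `budget_factor` × target draws. Optional scaling augmentation
(`allow_scaling`, off by default) draws a uniform scale in [0.8, 1.25].
Interpolation during pose transforms is alpha-premultiplied so transparent
pixels never bleed color. Because accepted poses lie fully inside the
patch, the keep-if-≥30%-visible rule for edge-clipped colonies
(`min_visible_fraction`) is a safeguard that rarely fires.

Per-patch RNGs derive from (master seed, patch index) via `SeedSequence`,
so any patch can be regenerated alone and a dataset is a pure function of
(seed, config).

## Style transfer

The loss is implemented literally with Gram matrices on *both* terms,
G = F Fᵀ/(CHW), unsquared Frobenius norms summed over the selected layers
(default: all five blocks). The common alternative — raw feature matching
for the content term — is not the default here. A consequence of the
unsquared content norm is that the exact content image is a non-smooth
local minimum of the total loss whenever λ < ½; cold starts therefore
perturb the zero-initialized generator head with a small seeded normal
(std 0.05), giving a near-identity start with a usable descent direction.
With a zero head the generator is exactly the identity, which is what
zero-iteration ("raw") runs use.

The feature extractor is a fixed random-weight convolutional pyramid: five
3×3-conv + ReLU blocks (8, 12, 16, 16, 16 channels) with 2× average
pooling between blocks, weights drawn once from a seeded He-scaled normal
and never trained. Random convolutional features carry enough texture and
color statistics for Gram-based style matching at this scale, and a frozen
seeded extractor makes the loss a deterministic function of its inputs.
Odd spatial sizes are trimmed by one row/column before pooling so style
images of any size are accepted (Gram matrices are size-agnostic).

Two generators are provided, both residual RGB→RGB networks written
directly on numpy arrays with hand-derived backward passes (verified
against central finite differences to relative error < 1e−3): `highres`
keeps a persistent full-resolution branch with two cross-resolution fusion
stages (≈ 10.9k parameters), `light` is a three-level branch-and-sum net
(≈ 2.2k parameters) for CPU-scale tests. Training is plain SGD (default
learning rate 1e−2; 200 iterations at full resolution, ~30 suffice for the
64-px test tiles). Four patches are stylized per tile (1024×1024 for
512-px patches), styles cycle round-robin from a pool of 20 fragments, and
warm starts reuse the previous tile's weights. λ = 0.02 and 0.05 are the
semi- and fully-stylized presets; λ > 0.05 triggers a warning (heavier
stylization erodes species-specific appearance) but is not forbidden.

## Fixtures

The fixture generator emulates the *inputs* the pipeline expects: a bright
agar disk with a darker rim on a dark surround, a linear lighting ramp
(relative amplitude 0.15), Gaussian pixel noise (σ = 2), colonies rendered
as anisotropic super-Gaussian blobs exp(−ρ^p) with per-species color
palettes and edge exponents p (sharp small staphylococci and yeasts, large
blurred pseudomonads), pairwise overlap forced with probability 0.3, and
dark ink glyphs (L\* < 30) stamped on the substrate. Ground-truth masks
are the ρ-level set at 0.35 and boxes are their tight rectangles. Fixtures
reproduce the geometry and contrast statistics that the extraction chain
relies on — not photographic texture, sensor artifacts, condensation or
agar reflections. Tests passing on fixtures therefore validate the
pipeline's contracts (mask algebra, determinism, segmentation behaviour on
blob-like objects), not detection performance on real plates.

## Numerical choices and degenerate inputs

Boxes are 0-based and half-open, eliminating off-by-one ambiguity in area
and overlap arithmetic; boxes are clipped to the image on load and
zero-area remnants dropped with a warning. Masks are serialized as
uncompressed COCO-style RLE (column-major, leading zero-run), which unlike
polygons represents cutouts with holes exactly. Manifests contain no
timestamps so byte-identity is meaningful. Annotation field names are
remappable because upstream datasets differ in their JSON schema.

Problem sizes in the test-suite (fixture dishes of ~236 px, 256-px patches
for bulk checks, 64-px stylization tiles, a handful of full 512-px patches
and one 1024-px tile for geometry checks) were chosen as the smallest
scales at which every contract is exercised end-to-end; all defaults remain
at the full-scale values documented above.

## Known limitations

* Whole-dish (≈ 4000×4000) synthesis is out of scope; the generator emits
  patches only.
* The sMAPE denominator uses (p + t)/2 with the 0/0 term defined as 0;
  variants using max(p, t) exist and give different saturation behaviour.
* The dark-artifact thresholds are global per fragment; adaptive
  thresholding per dish is not implemented.
* Stylization quality is bounded by the small random-feature extractor;
  it diversifies lighting and color statistics but is not a substitute for
  perceptual-quality stylization with a large pretrained feature network.
* No GAN-based generation: the method requires exact control of colony
  placement and count, which unconstrained generative models do not offer.
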