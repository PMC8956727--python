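"""Colony cluster extraction: cut, clean, denoise, segment, blend.

Each cluster of overlapping colonies is cut from its dish as a rectangular
fragment and turned into an RGBA cutout whose alpha channel is the Hadamard
product ``m_bx ∘ m_s ∘ m_b`` of three masks:

* ``m_bx`` — boxes' mask: 1 inside the union of the cluster's bounding boxes,
  0 elsewhere, so nothing outside the annotated boxes can leak into a paste;
* ``m_s``  — segmentation mask from Chan–Vese level sets (dilated slightly so
  colony edges are kept);
* ``m_b``  — blending mask in [0, 255], proportional to each pixel's CIELab
  distance from the average background color, which fades out pixels that
  look like substrate and makes pastes blend into new backgrounds.

Before segmentation the fragment is unsharp-filtered, dark substrate
artifacts (printed text, contamination) are excised by CIELab thresholding
and replaced by random-walk donor pixels, and the resulting speckle is
removed with non-local-means denoising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, filters, morphology
from skimage.restoration import denoise_nl_means
from skimage.segmentation import chan_vese

from .datamodel import AnnotatedDish, BoundingBox, ValidationError

logger = logging.getLogger("petrisynth")


@dataclass
class ExtractionConfig:
    """Tunables of the extraction chain.

    The dark-artifact thresholds are absolute CIELab values (L* in [0, 100],
    b* roughly [-128, 127]): a pixel is flagged when it is either very dark
    (``L* < dark_L_threshold``) or strongly blue-shifted
    (``b* < dark_b_threshold``), which captures printed text and specks on a
    bright agar substrate.
    """

    unsharp_radius: float = 3.0        # px, Gaussian radius of the unsharp mask
    unsharp_amount: float = 1.0        # unsharp strength (0 disables)
    dark_L_threshold: float = 40.0     # L* below this is "dark"
    dark_b_threshold: float = -5.0     # b* below this is "dark" (bluish ink)
    dark_dilate_radius: int = 2        # px, artifact-mask dilation
    nlm_strength: float = 15.0         # intensity units on the 0-255 scale
    nlm_patch: int = 5                 # px, non-local-means patch size
    cv_mu: float = 0.25                # Chan-Vese boundary-length weight
    cv_max_iter: int = 200             # Chan-Vese iteration cap
    seg_dilate_radius: int = 2         # px, margin added to m_s
    blend_gamma: float = 1.0           # exponent on the normalized CIELab distance
    cutout_margin: int = 5             # px, margin around the cluster box union
    rng_seed: int = 0                  # seeds the random-walk donor search

    def __post_init__(self) -> None:
        for name in ("unsharp_radius", "dark_dilate_radius", "seg_dilate_radius",
                     "cutout_margin", "nlm_patch"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.cv_max_iter < 1:
            raise ValidationError("cv_max_iter must be >= 1")


@dataclass
class ClusterCutout:
    """An extracted cluster: RGBA sprite plus per-colony annotations."""

    rgb: np.ndarray                      # h x w x 3 uint8 (cleaned, denoised)
    m_bx: np.ndarray                     # h x w bool
    m_d: np.ndarray                      # h x w bool
    m_s: np.ndarray                      # h x w bool
    m_b: np.ndarray                      # h x w uint8 in [0, 255]
    alpha: np.ndarray                    # h x w uint8
    per_colony_boxes: list[BoundingBox]  # fragment-local coordinates
    per_colony_masks: list[np.ndarray]   # h x w bool each
    species: str
    source_id: str = ""


# ---------------------------------------------------------------------------
# Stage 1: cut the cluster fragment
# ---------------------------------------------------------------------------

def cut_cluster(
    dish: AnnotatedDish,
    cluster: list[int],
    margin: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[BoundingBox]]:
    """Cut the union rectangle of a cluster's boxes (plus margin) from the dish.

    Returns the RGB fragment, the boxes' mask ``m_bx`` and the member boxes
    re-expressed in fragment-local coordinates.
    """
    if not cluster:
        raise ValidationError("cluster must be nonempty")
    h, w = dish.shape
    boxes = [dish.annotations[i].bbox for i in cluster]
    x1 = max(min(b.x for b in boxes) - margin, 0)
    y1 = max(min(b.y for b in boxes) - margin, 0)
    x2 = min(max(b.x2 for b in boxes) + margin, w)
    y2 = min(max(b.y2 for b in boxes) + margin, h)
    if (x1 > 0 or y1 > 0) and (
        min(b.x for b in boxes) - margin < 0 or min(b.y for b in boxes) - margin < 0
    ):
        logger.info("cluster margin truncated at image edge (%s)", dish.source_id)
    fragment = dish.image[y1:y2, x1:x2].copy()
    m_bx = np.zeros(fragment.shape[:2], dtype=bool)
    local_boxes = []
    for b in boxes:
        lb = BoundingBox(b.x - x1, b.y - y1, b.w, b.h)
        local_boxes.append(lb)
        m_bx[lb.y : lb.y2, lb.x : lb.x2] = True
    return fragment, m_bx, local_boxes


# ---------------------------------------------------------------------------
# Stage 2: unsharp + dark-artifact removal
# ---------------------------------------------------------------------------

def unsharp(rgb: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Unsharp-mask the fragment (uint8 in, uint8 out)."""
    if cfg.unsharp_amount == 0 or cfg.unsharp_radius == 0:
        return rgb.copy()
    sharp = filters.unsharp_mask(
        rgb.astype(np.float64) / 255.0,
        radius=cfg.unsharp_radius, amount=cfg.unsharp_amount, channel_axis=2,
    )
    return (np.clip(sharp, 0.0, 1.0) * 255).round().astype(np.uint8)


def remove_dark_artifacts(
    rgb: np.ndarray, cfg: ExtractionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Excise dark text/contamination and fill with random-walk donor pixels.

    The artifact mask ``m_d`` is the dilated union of the two CIELab
    thresholds.  Every flagged pixel receives the exact RGB value of the
    first valid pixel met by a seeded 8-neighborhood random walk started at
    it (donors are read from the frozen input, never from already-replaced
    pixels); a walk that exhausts its step cap falls back to the nearest
    valid pixel by Euclidean distance.  Pixels outside ``m_d`` are untouched.
    """
    lab = color.rgb2lab(rgb)
    dark = (lab[:, :, 0] < cfg.dark_L_threshold) | (lab[:, :, 2] < cfg.dark_b_threshold)
    if cfg.dark_dilate_radius > 0:
        m_d = morphology.dilation(dark, morphology.disk(cfg.dark_dilate_radius))
    else:
        m_d = dark
    out = rgb.copy()
    if not m_d.any():
        return out, m_d
    if m_d.all():
        raise ValidationError("no valid pixels for replacement: artifact mask covers fragment")

    h, w = m_d.shape
    rng = np.random.default_rng(cfg.rng_seed)
    max_steps = 10 * 2 * (h + w)
    # fallback: nearest valid pixel for walks that hit the step cap
    nearest = ndimage.distance_transform_edt(m_d, return_distances=False, return_indices=True)
    steps = np.array(
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    )
    ys, xs = np.nonzero(m_d)
    for y0, x0 in zip(ys, xs):
        y, x = int(y0), int(x0)
        found = False
        for _ in range(max_steps):
            dy, dx = steps[rng.integers(8)]
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                y, x = ny, nx
                if not m_d[y, x]:
                    found = True
                    break
        if not found:
            y, x = int(nearest[0][y0, x0]), int(nearest[1][y0, x0])
        out[y0, x0] = rgb[y, x]
    return out, m_d


# ---------------------------------------------------------------------------
# Stage 3: denoise
# ---------------------------------------------------------------------------

def denoise(rgb: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Non-local-means speckle removal (uint8 in, uint8 out)."""
    if cfg.nlm_strength <= 0:
        return rgb.copy()
    img = rgb.astype(np.float64) / 255.0
    out = denoise_nl_means(
        img,
        h=cfg.nlm_strength / 255.0,
        patch_size=cfg.nlm_patch,
        patch_distance=6,
        fast_mode=True,
        channel_axis=-1,
    )
    return (np.clip(out, 0.0, 1.0) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Stage 4: Chan-Vese segmentation
# ---------------------------------------------------------------------------

def segment_chan_vese(rgb: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    """Segment colonies from substrate on the luminance channel.

    Chan–Vese partitions the fragment into two phases; the colony phase is
    taken as the one whose mean luminance differs more from the fragment
    border's mean (the border is assumed to be substrate).  The result is
    dilated by ``seg_dilate_radius`` so colony edges survive into the mask.
    """
    gray = color.rgb2gray(rgb)
    if np.ptp(gray) < 1e-6:
        warnings.warn("constant fragment: no separable phases, returning empty mask",
                      stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    seg = chan_vese(
        gray,
        mu=cfg.cv_mu,
        max_num_iter=cfg.cv_max_iter,
        init_level_set="checkerboard",
        dt=0.5,
    )
    border = np.concatenate([gray[0, :], gray[-1, :], gray[:, 0], gray[:, -1]])
    border_mean = border.mean()
    in_mean = gray[seg].mean() if seg.any() else border_mean
    out_mean = gray[~seg].mean() if (~seg).any() else border_mean
    if abs(in_mean - border_mean) < abs(out_mean - border_mean):
        seg = ~seg
    if cfg.seg_dilate_radius > 0:
        seg = morphology.dilation(seg, morphology.disk(cfg.seg_dilate_radius))
    return seg


# ---------------------------------------------------------------------------
# Stage 5: blending mask + alpha composition
# ---------------------------------------------------------------------------

def blending_mask(
    rgb: np.ndarray, m_s: np.ndarray, gamma: float = 1.0
) -> np.ndarray:
    """Per-pixel opacity proportional to CIELab distance from the background.

    The background reference is the mean CIELab color over pixels outside
    ``m_s``; distances are normalized by the fragment maximum and scaled to
    [0, 255], optionally shaped by ``gamma``.
    """
    if m_s.all():
        raise ValidationError("no background sample: segmentation mask covers fragment")
    lab = color.rgb2lab(rgb)
    background = lab[~m_s].mean(axis=0)
    dist = np.linalg.norm(lab - background, axis=-1)
    d_max = dist.max()
    if d_max == 0:
        return np.zeros(m_s.shape, dtype=np.uint8)
    norm = (dist / d_max) ** gamma
    return (255.0 * norm).round().astype(np.uint8)


def compose_alpha(
    m_bx: np.ndarray, m_s: np.ndarray, m_b: np.ndarray
) -> np.ndarray:
    """Final alpha channel: element-wise product m_bx ∘ m_s ∘ m_b."""
    if not (m_bx.shape == m_s.shape == m_b.shape):
        raise ValidationError(
            f"mask shape mismatch: {m_bx.shape}, {m_s.shape}, {m_b.shape}"
        )
    return (
        m_bx.astype(np.uint16) * m_s.astype(np.uint16) * m_b.astype(np.uint16)
    ).astype(np.uint8)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def extract_cluster(
    dish: AnnotatedDish,
    cluster: list[int],
    cfg: ExtractionConfig | None = None,
) -> ClusterCutout | None:
    """Run the full extraction chain on one cluster.

    Returns ``None`` (with a warning) for clusters whose final alpha is
    entirely zero; such cutouts carry no visible pixels and are excluded
    from the bank.
    """
    cfg = cfg or ExtractionConfig()
    fragment, m_bx, local_boxes = cut_cluster(dish, cluster, cfg.cutout_margin)
    sharp = unsharp(fragment, cfg)
    cleaned, m_d = remove_dark_artifacts(sharp, cfg)
    smooth = denoise(cleaned, cfg)
    m_s = segment_chan_vese(smooth, cfg)
    if m_s.all():
        # pathological fragment: keep a 1-px background rim so blending has a reference
        m_s[0, :] = m_s[-1, :] = m_s[:, 0] = m_s[:, -1] = False
    m_b = blending_mask(smooth, m_s, cfg.blend_gamma)
    alpha = compose_alpha(m_bx, m_s, m_b)
    if not alpha.any():
        warnings.warn(
            f"cluster {cluster} of dish {dish.source_id!r} has empty alpha; rejected",
            stacklevel=2,
        )
        return None
    per_colony_masks = []
    for b in local_boxes:
        mask = np.zeros(alpha.shape, dtype=bool)
        mask[b.y : b.y2, b.x : b.x2] = alpha[b.y : b.y2, b.x : b.x2] > 0
        per_colony_masks.append(mask)
    species = dish.annotations[cluster[0]].species
    return ClusterCutout(
        rgb=smooth,
        m_bx=m_bx,
        m_d=m_d,
        m_s=m_s,
        m_b=m_b,
        alpha=alpha,
        per_colony_boxes=local_boxes,
        per_colony_masks=per_colony_masks,
        species=species,
        source_id=dish.source_id,
    )


def extract_dish(
    dish: AnnotatedDish,
    cfg: ExtractionConfig | None = None,
    overlap_threshold: float | None = None,
) -> list[ClusterCutout]:
    """Cluster a dish's annotations and extract every cluster."""
    from .clusters import DEFAULT_OVERLAP_THRESHOLD, cluster_boxes

    thr = DEFAULT_OVERLAP_THRESHOLD if overlap_threshold is None else overlap_threshold
    boxes = [a.bbox for a in dish.annotations]
    cutouts = []
    for cluster in cluster_boxes(boxes, thr):
        cut = extract_cluster(dish, cluster, cfg)
        if cut is not None:
            cutouts.append(cut)
    return cutouts


__all__ = [
    "ExtractionConfig",
    "ClusterCutout",
    "cut_cluster",
    "unsharp",
    "remove_dark_artifacts",
    "denoise",
    "segment_chan_vese",
    "blending_mask",
    "compose_alpha",
    "extract_cluster",
    "extract_dish",
]
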