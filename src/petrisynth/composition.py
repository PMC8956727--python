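"""Patch composition: place extracted cutouts on empty-dish backgrounds.

A synthetic patch starts from a randomly rotated, randomly cropped window of
a real (or fixture) empty dish.  One species is drawn per patch, a target
colony count is drawn from an exponential law (mean 10 by default, matching
the per-patch colony statistics of real plates), and cluster cutouts of that
species are pasted at random poses until the target is reached, rejecting
any pose whose alpha footprint would touch an already placed cluster.
Every placed colony's mask and tight bounding box are recorded, giving
pixel-exact instance annotations for free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .datamodel import (
    AnnotatedDish,
    ColonyAnnotation,
    SynthPatchRecord,
    ValidationError,
    tight_bbox,
    write_dataset,
)
from .extraction import ClusterCutout

logger = logging.getLogger("petrisynth")


@dataclass
class CompositionConfig:
    patch_size: int = 512
    count_mean: float = 10.0          # 1/lambda of the exponential count law
    max_place_attempts: int = 50      # pose rejections before giving up on a cutout
    budget_factor: int = 10           # cutout draws allowed per target colony
    n_empty_dishes: int = 10
    rng_seed: int = 0
    allow_scaling: bool = False
    scale_range: tuple[float, float] = (0.8, 1.25)
    min_visible_fraction: float = 0.3  # keep a clipped colony if this much survives

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValidationError("patch_size must be > 0")
        if self.count_mean <= 0:
            raise ValidationError("count_mean must be > 0")


@dataclass
class Placement:
    """An accepted pose for one cutout on one patch."""

    cutout: ClusterCutout
    rotation: float                      # degrees, counter-clockwise
    flips: tuple[bool, bool]             # (horizontal, vertical)
    position: tuple[int, int]            # (row, col) of the footprint's top-left
    scale: float = 1.0
    # transformed rasters cached at acceptance time
    rgb: np.ndarray | None = None        # th x tw x 3 float in [0, 255]
    alpha: np.ndarray | None = None      # th x tw float in [0, 255]
    colony_masks: list[np.ndarray] = field(default_factory=list)


@dataclass
class PatchState:
    """Mutable per-patch canvas: image plus footprint occupancy."""

    image: np.ndarray                    # S x S x 3 float
    occupancy: np.ndarray                # S x S bool, dilated footprints

    @classmethod
    def from_background(cls, background: np.ndarray) -> "PatchState":
        return cls(
            image=background.astype(np.float64),
            occupancy=np.zeros(background.shape[:2], dtype=bool),
        )


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(
    empty_dish: AnnotatedDish,
    size: int,
    rng: np.random.Generator,
    angle: float | None = None,
    corner: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rotate the empty dish by a random angle and crop a random valid window.

    The crop window is drawn uniformly from positions whose every pixel comes
    from the source image (no rotation fill).  ``angle`` and ``corner``
    override the random draws, which is useful for deterministic checks.
    """
    img = empty_dish.image
    h, w = img.shape[:2]
    if angle is None:
        angle = float(rng.uniform(0.0, 360.0))
    rot = sktransform.rotate(
        img.astype(np.float64), angle, resize=False, order=1, mode="constant",
        cval=-1.0, preserve_range=True,
    )
    valid = ~np.any(rot < 0, axis=-1)
    # count of valid pixels in each size x size window via an integral image
    ii = np.pad(np.cumsum(np.cumsum(valid, axis=0), axis=1), ((1, 0), (1, 0)))
    nh, nw = h - size + 1, w - size + 1
    if nh <= 0 or nw <= 0:
        raise ValidationError(
            f"dish {empty_dish.source_id!r} is {h}x{w}; needs at least {size}x{size}"
        )
    win = (
        ii[size : size + nh, size : size + nw]
        - ii[:nh, size : size + nw]
        - ii[size : size + nh, :nw]
        + ii[:nh, :nw]
    )
    ok_rows, ok_cols = np.nonzero(win == size * size)
    if ok_rows.size == 0:
        raise ValidationError(
            f"dish {empty_dish.source_id!r} ({h}x{w}) has no fill-free {size}x{size} "
            f"window at rotation {angle:.1f} deg; a larger dish image is required"
        )
    if corner is None:
        k = int(rng.integers(ok_rows.size))
        r0, c0 = int(ok_rows[k]), int(ok_cols[k])
    else:
        r0, c0 = corner
    crop = rot[r0 : r0 + size, c0 : c0 + size]
    return np.clip(crop, 0, 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Colony-count law
# ---------------------------------------------------------------------------

def sample_colony_count(
    rng: np.random.Generator, count_mean: float = 10.0, raw: bool = False
) -> int | float:
    """Draw a per-patch colony count from Exponential(mean=count_mean).

    The continuous draw is rounded half-up to an integer (``raw=True``
    returns it unrounded); zero counts are legitimate — real plates include
    empty patches.
    """
    if count_mean <= 0:
        raise ValidationError("count_mean must be > 0")
    x = float(rng.exponential(count_mean))
    return x if raw else int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Pose transform + placement
# ---------------------------------------------------------------------------

def transform_cutout(
    cutout: ClusterCutout,
    rotation: float,
    flips: tuple[bool, bool],
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Flip/rotate (and optionally scale) a cutout's RGBA jointly.

    Interpolation is alpha-premultiplied so transparent pixels never bleed
    color into the footprint.  Returns float RGB (0-255), float alpha
    (0-255) and the transformed per-colony boolean masks.
    """
    rgb = cutout.rgb.astype(np.float64)
    alpha = cutout.alpha.astype(np.float64)
    masks = [m.astype(np.float64) for m in cutout.per_colony_masks]
    hflip, vflip = flips
    if hflip:
        rgb, alpha = rgb[:, ::-1], alpha[:, ::-1]
        masks = [m[:, ::-1] for m in masks]
    if vflip:
        rgb, alpha = rgb[::-1], alpha[::-1]
        masks = [m[::-1] for m in masks]
    if scale != 1.0:
        rgb = sktransform.rescale(rgb, scale, order=1, channel_axis=-1,
                                  preserve_range=True, anti_aliasing=scale < 1.0)
        alpha = sktransform.rescale(alpha, scale, order=1, preserve_range=True,
                                    anti_aliasing=scale < 1.0)
        masks = [
            sktransform.rescale(m, scale, order=0, preserve_range=True,
                                anti_aliasing=False)
            for m in masks
        ]
    if rotation % 360.0 != 0.0:
        prem = rgb * alpha[..., None]
        prem = sktransform.rotate(prem, rotation, resize=True, order=1,
                                  preserve_range=True)
        alpha = sktransform.rotate(alpha, rotation, resize=True, order=1,
                                   preserve_range=True)
        masks = [
            sktransform.rotate(m, rotation, resize=True, order=0, preserve_range=True)
            for m in masks
        ]
        with np.errstate(invalid="ignore", divide="ignore"):
            rgb = np.where(alpha[..., None] > 1e-6, prem / alpha[..., None], 0.0)
    alpha = np.clip(alpha, 0.0, 255.0)
    fp = alpha > 0
    bool_masks = [(m > 0.5) & fp for m in masks]
    return np.clip(rgb, 0, 255), alpha, bool_masks


_DILATE_1PX = np.ones((3, 3), dtype=bool)


def _transform_alpha(
    alpha_u8: np.ndarray, rotation: float, flips: tuple[bool, bool], scale: float
) -> np.ndarray:
    """Alpha-only version of :func:`transform_cutout` (same geometry)."""
    alpha = alpha_u8.astype(np.float64)
    if flips[0]:
        alpha = alpha[:, ::-1]
    if flips[1]:
        alpha = alpha[::-1]
    if scale != 1.0:
        alpha = sktransform.rescale(alpha, scale, order=1, preserve_range=True,
                                    anti_aliasing=scale < 1.0)
    if rotation % 360.0 != 0.0:
        alpha = sktransform.rotate(alpha, rotation, resize=True, order=1,
                                   preserve_range=True)
    return np.clip(alpha, 0.0, 255.0)


def try_place(
    state: PatchState,
    cutout: ClusterCutout,
    rng: np.random.Generator,
    max_attempts: int = 50,
    allow_scaling: bool = False,
    scale_range: tuple[float, float] = (0.8, 1.25),
) -> Placement | None:
    """Propose random poses until one lands without overlap; None on failure.

    A pose is accepted when its alpha footprint, dilated by one pixel, is
    fully inside the patch and disjoint from every previously placed
    footprint.
    """
    size = state.occupancy.shape[0]
    for _ in range(max_attempts):
        rotation = float(rng.uniform(0.0, 360.0))
        flips = (bool(rng.integers(2)), bool(rng.integers(2)))
        scale = float(rng.uniform(*scale_range)) if allow_scaling else 1.0
        # cheap probe: transform only the alpha until a pose is accepted
        alpha = _transform_alpha(cutout.alpha, rotation, flips, scale)
        th, tw = alpha.shape
        if th + 2 > size or tw + 2 > size:
            continue  # footprint cannot fit with its 1-px guard band
        r0 = int(rng.integers(1, size - th))
        c0 = int(rng.integers(1, size - tw))
        footprint = ndimage.binary_dilation(alpha > 0, structure=_DILATE_1PX)
        if not footprint.any():
            return None
        region = state.occupancy[r0 : r0 + th, c0 : c0 + tw]
        if np.logical_and(region, footprint).any():
            continue
        state.occupancy[r0 : r0 + th, c0 : c0 + tw] |= footprint
        rgb, alpha, masks = transform_cutout(cutout, rotation, flips, scale)
        return Placement(
            cutout=cutout, rotation=rotation, flips=flips, position=(r0, c0),
            scale=scale, rgb=rgb, alpha=alpha, colony_masks=masks,
        )
    return None


def blend(patch: np.ndarray, placement: Placement) -> np.ndarray:
    """Alpha-over composite one placed cutout onto the patch (uint8 in/out)."""
    out = patch.astype(np.float64)
    r0, c0 = placement.position
    a = placement.alpha / 255.0
    th, tw = a.shape
    region = out[r0 : r0 + th, c0 : c0 + tw]
    out[r0 : r0 + th, c0 : c0 + tw] = (
        a[..., None] * placement.rgb + (1.0 - a[..., None]) * region
    )
    return np.clip(out, 0, 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Patch and dataset generation
# ---------------------------------------------------------------------------

def generate_patch(
    bank: dict[str, list[ClusterCutout]],
    empty_dishes: list[AnnotatedDish],
    cfg: CompositionConfig,
    rng: np.random.Generator,
) -> SynthPatchRecord:
    """Compose one annotated patch.

    One species is sampled uniformly; clusters of that species are drawn with
    replacement and placed until the cumulative colony count reaches the
    exponential target (a multi-colony cluster may overshoot) or the
    placement budget is exhausted.
    """
    if not bank or any(len(v) == 0 for v in bank.values()):
        raise ValidationError("cutout bank must hold at least one cutout per species")
    species = sorted(bank)[int(rng.integers(len(bank)))]
    dish_idx = int(rng.integers(len(empty_dishes)))
    background = sample_background(empty_dishes[dish_idx], cfg.patch_size, rng)
    state = PatchState.from_background(background)

    target = sample_colony_count(rng, cfg.count_mean)
    annotations: list[ColonyAnnotation] = []
    masks: list[np.ndarray] = []
    image = background
    placed = 0
    budget = cfg.budget_factor * max(target, 1)
    while placed < target and budget > 0:
        budget -= 1
        cutouts = bank[species]
        cutout = cutouts[int(rng.integers(len(cutouts)))]
        placement = try_place(
            state, cutout, rng, cfg.max_place_attempts,
            cfg.allow_scaling, cfg.scale_range,
        )
        if placement is None:
            logger.debug("placement failed after %d attempts", cfg.max_place_attempts)
            continue
        image = blend(image, placement)
        state.image = image.astype(np.float64)
        r0, c0 = placement.position
        for cmask in placement.colony_masks:
            original = int(cmask.sum())
            full = np.zeros((cfg.patch_size, cfg.patch_size), dtype=bool)
            full[r0 : r0 + cmask.shape[0], c0 : c0 + cmask.shape[1]] = cmask
            visible = int(full.sum())
            if original == 0 or visible < cfg.min_visible_fraction * original:
                logger.debug("dropping colony: %d of %d px visible", visible, original)
                continue
            annotations.append(
                ColonyAnnotation(tight_bbox(full), species, len(annotations))
            )
            masks.append(full)
            placed += 1
    provenance = {
        "empty_dish": empty_dishes[dish_idx].source_id,
        "style": "raw",
        "species": species,
        "target_count": target,
    }
    return SynthPatchRecord(image, annotations, masks, provenance)


def patch_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-derived per-patch generator so any patch is independently
    reproducible from (master seed, patch index)."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_patches(
    bank: dict[str, list[ClusterCutout]],
    empty_dishes: list[AnnotatedDish],
    cfg: CompositionConfig,
    n_patches: int,
    seed: int,
) -> list[SynthPatchRecord]:
    records = []
    for i in range(n_patches):
        rec = generate_patch(bank, empty_dishes, cfg, patch_rng(seed, i))
        rec.provenance["seed"] = seed
        rec.provenance["index"] = i
        records.append(rec)
    return records


def generate_dataset(
    bank: dict[str, list[ClusterCutout]],
    empty_dishes: list[AnnotatedDish],
    cfg: CompositionConfig,
    n_patches: int,
    seed: int,
    out_dir: str | Path,
    fmt: str = "coco_json",
    overwrite: bool = False,
) -> Path:
    """Generate ``n_patches`` patches and write them via the dataset writer."""
    if n_patches < 1:
        raise ValidationError("n_patches must be >= 1")
    records = generate_patches(bank, empty_dishes, cfg, n_patches, seed)
    return write_dataset(
        records, out_dir, fmt=fmt, overwrite=overwrite,
        extra_meta={"seed": seed, "patch_size": cfg.patch_size},
    )


__all__ = [
    "CompositionConfig",
    "Placement",
    "PatchState",
    "sample_background",
    "sample_colony_count",
    "transform_cutout",
    "try_place",
    "blend",
    "generate_patch",
    "generate_patches",
    "generate_dataset",
    "patch_rng",
]
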