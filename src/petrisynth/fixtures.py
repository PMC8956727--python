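"""Programmatic pseudo-real dish fixtures.

Generates top-view Petri-dish rasters with blob-like colonies, substrate
text artifacts, lighting gradients and sensor noise, together with exact
bounding boxes and ground-truth masks, so the whole extraction/composition
pipeline can be built and tested without any external dataset.

Colonies are rendered as anisotropic super-Gaussian blobs whose edge
sharpness is a per-species parameter: some species grow as small sharp
colonies, others as large blurred ones, and the fixture palette mimics that
spread.  Fixtures emulate the geometry and contrast statistics of real
plates, not their photographic texture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .datamodel import (
    DEFAULT_SPECIES,
    AnnotatedDish,
    BoundingBox,
    ColonyAnnotation,
    ValidationError,
    tight_bbox,
)

#: Per-species rendering palette: RGB color, edge sharpness exponent of the
#: super-Gaussian profile (higher = sharper rim), and relative size factor.
SPECIES_STYLE = {
    "S.aureus": {"color": (205, 155, 45), "edge_power": 6.0, "size": 0.8},
    "B.subtilis": {"color": (248, 242, 225), "edge_power": 5.0, "size": 1.0},
    "P.aeruginosa": {"color": (125, 152, 138), "edge_power": 3.0, "size": 1.3},
    "E.coli": {"color": (172, 132, 92), "edge_power": 5.0, "size": 1.0},
    "C.albicans": {"color": (250, 250, 248), "edge_power": 6.0, "size": 0.9},
}

#: Profile level treated as the colony boundary for ground-truth masks.
MASK_LEVEL = 0.35


@dataclass
class FixtureConfig:
    dish_diameter: int = 220          # px
    n_colonies: int = 5
    colony_radius_range: tuple[int, int] = (8, 16)   # px
    overlap_probability: float = 0.3
    artifact_text: bool = True
    lighting_gradient: float = 0.15   # relative amplitude of the linear ramp
    noise_sigma: float = 2.0          # Gaussian pixel noise, 0-255 scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dish_diameter <= 4 * self.colony_radius_range[1]:
            raise ValidationError("dish diameter must exceed 4x the max colony radius")
        if not (0.0 <= self.overlap_probability <= 1.0):
            raise ValidationError("overlap_probability must be in [0, 1]")
        if not (0.0 <= self.lighting_gradient <= 1.0):
            raise ValidationError("lighting_gradient must be in [0, 1]")


def _dish_canvas(cfg: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    """Bright agar disk with a darker rim on a dark surround, plus lighting."""
    size = cfg.dish_diameter + 16
    r = cfg.dish_diameter / 2
    cy = cx = size / 2
    yy, xx = np.mgrid[0:size, 0:size]
    rad = np.hypot(yy - cy, xx - cx)
    img = np.full((size, size, 3), 55.0)
    agar = np.array([196.0, 189.0, 172.0])
    rim = np.array([120.0, 115.0, 104.0])
    img[rad <= r] = agar
    ring = (rad <= r) & (rad > r - 5)
    img[ring] = rim
    # linear lighting ramp in a random direction
    theta = rng.uniform(0, 2 * math.pi)
    ramp = ((xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)) / size
    img *= (1.0 + cfg.lighting_gradient * ramp)[..., None]
    return img


def make_empty_dish(
    cfg: FixtureConfig | None = None,
    rng: np.random.Generator | None = None,
    source_id: str = "fixture_empty",
) -> AnnotatedDish:
    """An empty dish: agar disk, rim, lighting gradient, Gaussian noise."""
    cfg = cfg or FixtureConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    img = _dish_canvas(cfg, rng)
    img += rng.normal(0.0, cfg.noise_sigma, img.shape)
    image = np.clip(img, 0, 255).round().astype(np.uint8)
    return AnnotatedDish(image=image, annotations=[], source_id=source_id)


def _render_colony(
    img: np.ndarray,
    center: tuple[float, float],
    radii: tuple[float, float],
    phi: float,
    col: np.ndarray,
    edge_power: float,
) -> np.ndarray:
    """Paint one colony in place; return its boolean ground-truth mask."""
    size = img.shape[0]
    cy, cx = center
    ry, rx = radii
    reach = int(math.ceil(max(ry, rx) * 1.8)) + 2
    y1, y2 = max(int(cy) - reach, 0), min(int(cy) + reach + 1, size)
    x1, x2 = max(int(cx) - reach, 0), min(int(cx) + reach + 1, size)
    yy, xx = np.mgrid[y1:y2, x1:x2]
    u = (xx - cx) * math.cos(phi) + (yy - cy) * math.sin(phi)
    v = -(xx - cx) * math.sin(phi) + (yy - cy) * math.cos(phi)
    rho = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    g = np.exp(-(rho ** edge_power))
    img[y1:y2, x1:x2] = img[y1:y2, x1:x2] * (1 - g[..., None]) + col * g[..., None]
    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[y1:y2, x1:x2] = g > MASK_LEVEL
    return mask


def make_annotated_dish(
    cfg: FixtureConfig | None = None,
    rng: np.random.Generator | None = None,
    species: str | None = None,
    source_id: str = "fixture_dish",
) -> tuple[AnnotatedDish, list[np.ndarray]]:
    """A dish with ``n_colonies`` colonies of one species plus ground truth.

    With probability ``overlap_probability`` each colony after the first is
    seeded next to an existing one so their boxes overlap, which exercises
    the cluster graph.  Returns the dish and the list of exact ground-truth
    masks parallel to its annotations.
    """
    cfg = cfg or FixtureConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    species = species or str(rng.choice(list(DEFAULT_SPECIES)))
    style = SPECIES_STYLE[species]
    size = cfg.dish_diameter + 16
    dish_r = cfg.dish_diameter / 2
    center = size / 2

    img = _dish_canvas(cfg, rng)
    masks: list[np.ndarray] = []
    annotations: list[ColonyAnnotation] = []
    centers: list[tuple[float, float, float]] = []  # (cy, cx, mean radius)
    r_lo, r_hi = cfg.colony_radius_range
    for i in range(cfg.n_colonies):
        base = rng.uniform(r_lo, r_hi) * style["size"]
        ry, rx = base * rng.uniform(0.85, 1.15), base * rng.uniform(0.85, 1.15)
        reach = max(ry, rx) * 1.2
        placed = False
        for _ in range(200):
            if centers and rng.uniform() < cfg.overlap_probability:
                oy, ox, orad = centers[rng.integers(len(centers))]
                d = 0.8 * (orad + base)
                ang = rng.uniform(0, 2 * math.pi)
                cy, cx = oy + d * math.sin(ang), ox + d * math.cos(ang)
            else:
                ang = rng.uniform(0, 2 * math.pi)
                rad = (dish_r - reach - 6) * math.sqrt(rng.uniform())
                cy, cx = center + rad * math.sin(ang), center + rad * math.cos(ang)
            if math.hypot(cy - center, cx - center) + reach < dish_r - 4:
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"cannot fit colony {i} inside the dish; use smaller colony radii"
            )
        col = np.clip(
            np.asarray(style["color"], dtype=float) + rng.normal(0, 6, 3), 0, 255
        )
        mask = _render_colony(img, (cy, cx), (ry, rx), rng.uniform(0, math.pi),
                              col, style["edge_power"])
        masks.append(mask)
        centers.append((cy, cx, base))
        annotations.append(ColonyAnnotation(tight_bbox(mask), species, i))

    if cfg.artifact_text:
        _stamp_artifacts(img, [a.bbox for a in annotations], dish_r, center, rng)
    img += rng.normal(0.0, cfg.noise_sigma, img.shape)
    image = np.clip(img, 0, 255).round().astype(np.uint8)
    return AnnotatedDish(image, annotations, source_id), masks


def _stamp_artifacts(
    img: np.ndarray,
    boxes: list[BoundingBox],
    dish_r: float,
    center: float,
    rng: np.random.Generator,
    n_glyphs: int = 4,
) -> None:
    """Stamp dark ink strokes/digit-like glyphs on the substrate (L* < 30).

    Glyphs avoid colony boxes so fixture ground truth stays exact.
    """
    ink = np.array([22.0, 24.0, 45.0])  # near-black, slightly blue
    size = img.shape[0]
    stamped = 0
    for _ in range(60):
        if stamped >= n_glyphs:
            break
        gh, gw = int(rng.integers(6, 12)), int(rng.integers(8, 20))
        y = int(rng.integers(0, size - gh))
        x = int(rng.integers(0, size - gw))
        gy, gx = y + gh / 2, x + gw / 2
        if math.hypot(gy - center, gx - center) > dish_r - max(gh, gw):
            continue
        glyph_box = BoundingBox(x, y, gw, gh)
        from .clusters import overlap_fraction

        if any(overlap_fraction(glyph_box, b) > 0 for b in boxes):
            continue
        if rng.uniform() < 0.5:  # horizontal stroke
            row = y + gh // 2
            img[row : row + 2, x : x + gw] = ink
        else:  # hollow digit-like glyph
            img[y : y + 2, x : x + gw] = ink
            img[y + gh - 2 : y + gh, x : x + gw] = ink
            img[y : y + gh, x : x + 2] = ink
        stamped += 1


def write_fixture_set(
    out_dir: str | Path,
    n_dishes: int,
    n_empty: int = 2,
    cfg: FixtureConfig | None = None,
    seed: int = 0,
) -> Path:
    """Write annotated + empty fixture dishes in the input dialect.

    Emits ``dish_k.png`` / ``dish_k.json`` pairs (the JSON mirrors the
    per-image annotation dialect of :func:`petrisynth.datamodel.read_annotated_dish`)
    plus ``empty_k.png`` / ``empty_k.json`` with no colony records.
    """
    cfg = cfg or FixtureConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species_cycle = list(DEFAULT_SPECIES)
    for k in range(n_dishes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        sp = species_cycle[k % len(species_cycle)]
        dish, _ = make_annotated_dish(cfg, rng, species=sp, source_id=f"dish_{k}")
        iio.imwrite(out_dir / f"dish_{k}.png", dish.image)
        payload = {
            "classes": [sp],
            "labels": [
                {
                    "class": a.species,
                    "x": a.bbox.x,
                    "y": a.bbox.y,
                    "width": a.bbox.w,
                    "height": a.bbox.h,
                }
                for a in dish.annotations
            ],
        }
        (out_dir / f"dish_{k}.json").write_text(json.dumps(payload, indent=1))
    for k in range(n_empty):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 10_000 + k]))
        dish = make_empty_dish(cfg, rng, source_id=f"empty_{k}")
        iio.imwrite(out_dir / f"empty_{k}.png", dish.image)
        (out_dir / f"empty_{k}.json").write_text(json.dumps({"classes": [], "labels": []}))
    return out_dir


__all__ = [
    "FixtureConfig",
    "SPECIES_STYLE",
    "MASK_LEVEL",
    "make_empty_dish",
    "make_annotated_dish",
    "write_fixture_set",
]
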