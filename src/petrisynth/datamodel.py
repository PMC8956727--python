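"""Canonical data types and dataset I/O.

Coordinate convention: boxes are 0-based and half-open — a box ``(x, y, w, h)``
covers columns ``[x, x+w)`` and rows ``[y, y+h)``, so a 1x1 box covers exactly
one pixel.  Instance masks are serialized as uncompressed COCO-style RLE
(column-major counts, starting with the number of leading zeros).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("petrisynth")

#: Default closed label set: the five species of the public agar-plate
#: benchmark this generator targets.
DEFAULT_SPECIES = (
    "S.aureus",
    "B.subtilis",
    "P.aeruginosa",
    "E.coli",
    "C.albicans",
)

#: Field names of the per-image annotation JSON dialect.  Remappable because
#: upstream datasets name these fields differently.
DEFAULT_FIELD_MAP = {
    "colonies": "labels",
    "species": "class",
    "x": "x",
    "y": "y",
    "width": "width",
    "height": "height",
}


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: ``x``/``y`` top-left column/row, ``w``/``h`` extent."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"box must have positive extent, got {self}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def x2(self) -> int:
        """One past the right edge (half-open)."""
        return self.x + self.w

    @property
    def y2(self) -> int:
        """One past the bottom edge (half-open)."""
        return self.y + self.h

    def clip(self, width: int, height: int) -> "BoundingBox | None":
        """Intersect with the image rectangle; ``None`` if nothing remains."""
        x1, y1 = max(self.x, 0), max(self.y, 0)
        x2, y2 = min(self.x2, width), min(self.y2, height)
        if x2 <= x1 or y2 <= y1:
            return None
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class ColonyAnnotation:
    bbox: BoundingBox
    species: str
    instance_id: int


@dataclass
class AnnotatedDish:
    """An RGB dish photograph plus its per-colony annotations.

    ``annotations`` may be empty: empty dishes are first-class inputs (they
    supply the backgrounds that synthetic patches are composed on).
    """

    image: np.ndarray  # H x W x 3, uint8
    annotations: list[ColonyAnnotation] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
            raise ValidationError(
                f"dish image must be HxWx3 uint8, got shape {img.shape} dtype {img.dtype}"
            )
        self.image = img

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class SynthPatchRecord:
    """One generated patch: image + parallel annotation and mask lists."""

    image: np.ndarray  # S x S x 3 uint8
    annotations: list[ColonyAnnotation]
    masks: list[np.ndarray]  # each S x S bool, parallel to annotations
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.annotations):
            raise ValidationError(
                f"{len(self.masks)} masks for {len(self.annotations)} annotations"
            )


def tight_bbox(mask: np.ndarray) -> BoundingBox:
    """Tight bounding box of a nonempty binary mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValidationError("cannot take the bounding box of an empty mask")
    return BoundingBox(
        x=int(cols[0]),
        y=int(rows[0]),
        w=int(cols[-1] - cols[0] + 1),
        h=int(rows[-1] - rows[0] + 1),
    )


# ---------------------------------------------------------------------------
# RLE mask codec (COCO-compatible uncompressed form)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Encode a binary mask as uncompressed RLE.

    Counts alternate runs of 0s and 1s over the mask flattened in Fortran
    (column-major) order, always beginning with the zero-run (possibly 0).
    """
    m = np.asarray(mask, dtype=bool)
    flat = m.flatten(order="F").astype(np.int8)
    # run boundaries
    diff = np.flatnonzero(np.diff(flat))
    starts = np.concatenate(([0], diff + 1, [flat.size]))
    counts = np.diff(starts).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    if flat.size == 0:
        counts = []
    return {"size": [int(m.shape[0]), int(m.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = True
        pos += count
        val = not val
    if pos != h * w:
        raise ValidationError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_annotated_dish(
    image_path: str | Path,
    annotation_path: str | Path,
    species_set: tuple[str, ...] = DEFAULT_SPECIES,
    field_map: dict | None = None,
) -> AnnotatedDish:
    """Read a dish raster and its per-colony annotation JSON.

    Boxes are clipped to the image bounds on load; a record whose box falls
    entirely outside the image is dropped with a warning.  Unknown species
    labels raise :class:`ValidationError` listing the permitted labels.
    """
    image_path, annotation_path = Path(image_path), Path(annotation_path)
    fm = {**DEFAULT_FIELD_MAP, **(field_map or {})}
    try:
        image = iio.imread(image_path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {image_path}: {exc}") from exc
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    image = np.ascontiguousarray(image[:, :, :3]).astype(np.uint8)
    h, w = image.shape[:2]

    try:
        payload = json.loads(annotation_path.read_text())
    except OSError as exc:
        raise OSError(f"cannot read annotations {annotation_path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise OSError(f"corrupt annotation file {annotation_path}: {exc}") from exc

    annotations: list[ColonyAnnotation] = []
    next_id = 0
    for rec in payload.get(fm["colonies"], []):
        species = rec[fm["species"]]
        if species not in species_set:
            raise ValidationError(
                f"unknown species {species!r} in {annotation_path}; "
                f"permitted labels: {list(species_set)}"
            )
        raw = BoundingBox(
            x=int(rec[fm["x"]]),
            y=int(rec[fm["y"]]),
            w=int(rec[fm["width"]]),
            h=int(rec[fm["height"]]),
        )
        clipped = raw.clip(w, h)
        if clipped is None:
            warnings.warn(
                f"dropping zero-area box {raw} after clipping in {annotation_path}",
                stacklevel=2,
            )
            continue
        if clipped != raw:
            logger.info("clipped box %s -> %s in %s", raw, clipped, annotation_path)
        annotations.append(ColonyAnnotation(clipped, species, next_id))
        next_id += 1
    return AnnotatedDish(image=image, annotations=annotations, source_id=image_path.stem)


# ---------------------------------------------------------------------------
# Dataset writer / reader
# ---------------------------------------------------------------------------

def write_dataset(
    records: list[SynthPatchRecord],
    out_dir: str | Path,
    fmt: str = "coco_json",
    species_set: tuple[str, ...] = DEFAULT_SPECIES,
    overwrite: bool = False,
    extra_meta: dict | None = None,
) -> Path:
    """Write patches as PNGs plus instance annotations; return the manifest path.

    ``coco_json`` emits a single COCO-style ``annotations.json`` (bbox
    ``[x, y, w, h]``, segmentation as uncompressed RLE, 1-based
    ``category_id``); ``per_image_json`` emits one JSON per image.  The
    manifest lists every image with its annotation count and is deliberately
    free of timestamps so identical inputs produce identical bytes.
    """
    if fmt not in ("coco_json", "per_image_json"):
        raise ValidationError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )

    cat_ids = {sp: i + 1 for i, sp in enumerate(species_set)}
    manifest_entries = []
    coco_images, coco_anns = [], []
    ann_id = 1
    for idx, rec in enumerate(records):
        name = f"patch_{idx:06d}.png"
        iio.imwrite(out_dir / name, rec.image)
        h, w = rec.image.shape[:2]
        manifest_entries.append(
            {
                "file_name": name,
                "n_annotations": len(rec.annotations),
                "provenance": rec.provenance,
            }
        )
        if fmt == "coco_json":
            coco_images.append({"id": idx, "file_name": name, "width": w, "height": h})
            for ann, mask in zip(rec.annotations, rec.masks):
                coco_anns.append(
                    {
                        "id": ann_id,
                        "image_id": idx,
                        "category_id": cat_ids[ann.species],
                        "bbox": [ann.bbox.x, ann.bbox.y, ann.bbox.w, ann.bbox.h],
                        "area": int(np.count_nonzero(mask)),
                        "segmentation": rle_encode(mask),
                        "iscrowd": 0,
                    }
                )
                ann_id += 1
        else:
            per_image = {
                "file_name": name,
                "labels": [
                    {
                        "class": ann.species,
                        "x": ann.bbox.x,
                        "y": ann.bbox.y,
                        "width": ann.bbox.w,
                        "height": ann.bbox.h,
                        "segmentation": rle_encode(mask),
                    }
                    for ann, mask in zip(rec.annotations, rec.masks)
                ],
            }
            (out_dir / f"patch_{idx:06d}.json").write_text(
                json.dumps(per_image, sort_keys=True)
            )

    if fmt == "coco_json":
        coco = {
            "images": coco_images,
            "annotations": coco_anns,
            "categories": [
                {"id": cid, "name": sp} for sp, cid in cat_ids.items()
            ],
        }
        (out_dir / "annotations.json").write_text(json.dumps(coco, sort_keys=True))

    manifest = {
        "format": fmt,
        "n_images": len(records),
        "species_set": list(species_set),
        "images": manifest_entries,
        **(extra_meta or {}),
    }
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest_path


def read_dataset(out_dir: str | Path) -> list[SynthPatchRecord]:
    """Read back a dataset written by :func:`write_dataset` (either format)."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    species_set = manifest["species_set"]
    records: list[SynthPatchRecord] = []
    if manifest["format"] == "coco_json":
        coco = json.loads((out_dir / "annotations.json").read_text())
        cats = {c["id"]: c["name"] for c in coco["categories"]}
        by_image: dict[int, list[dict]] = {}
        for ann in coco["annotations"]:
            by_image.setdefault(ann["image_id"], []).append(ann)
        for img in sorted(coco["images"], key=lambda r: r["id"]):
            image = iio.imread(out_dir / img["file_name"])
            anns, masks = [], []
            for k, ann in enumerate(by_image.get(img["id"], [])):
                x, y, w, h = ann["bbox"]
                anns.append(
                    ColonyAnnotation(BoundingBox(x, y, w, h), cats[ann["category_id"]], k)
                )
                masks.append(rle_decode(ann["segmentation"]))
            prov = manifest["images"][img["id"]].get("provenance", {})
            records.append(SynthPatchRecord(image, anns, masks, prov))
    else:
        for idx, entry in enumerate(manifest["images"]):
            image = iio.imread(out_dir / entry["file_name"])
            payload = json.loads(
                (out_dir / entry["file_name"].replace(".png", ".json")).read_text()
            )
            anns, masks = [], []
            for k, rec in enumerate(payload["labels"]):
                if rec["class"] not in species_set:
                    raise ValidationError(f"unknown species {rec['class']!r}")
                anns.append(
                    ColonyAnnotation(
                        BoundingBox(rec["x"], rec["y"], rec["width"], rec["height"]),
                        rec["class"],
                        k,
                    )
                )
                masks.append(rle_decode(rec["segmentation"]))
            records.append(SynthPatchRecord(image, anns, masks, entry.get("provenance", {})))
    return records


__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_FIELD_MAP",
    "ValidationError",
    "BoundingBox",
    "ColonyAnnotation",
    "AnnotatedDish",
    "SynthPatchRecord",
    "tight_bbox",
    "rle_encode",
    "rle_decode",
    "read_annotated_dish",
    "write_dataset",
    "read_dataset",
]
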