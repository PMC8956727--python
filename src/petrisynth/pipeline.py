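"""End-to-end orchestration: extract -> compose -> stylize.

Runs the three stages of the generation method under one configuration and
one master seed.  Per-patch randomness is derived from (master seed, patch
index) so any individual patch can be regenerated without rerunning the
whole job, and per-tile stylization seeds are derived the same way.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .composition import generate_patches
from .config import GenConfig, validate_config
from .datamodel import AnnotatedDish, SynthPatchRecord, write_dataset
from .extraction import ClusterCutout, extract_dish
from .fixtures import FixtureConfig, make_annotated_dish, make_empty_dish
from .stylization import StyleConfig, stylize_batch
from .datamodel import read_annotated_dish

logger = logging.getLogger("petrisynth")

#: Stylization strengths of the three dataset flavors.
STYLE_MODES = {"raw": None, "semi": 0.02, "full": 0.05}


class PipelineError(RuntimeError):
    """A stage failure annotated with stage name and patch index."""

    def __init__(self, stage: str, index: int | None, cause: Exception):
        self.stage, self.index, self.cause = stage, index, cause
        where = f" patch={index}" if index is not None else ""
        super().__init__(f"stage={stage}{where}: {cause}")


# ---------------------------------------------------------------------------
# input resolution
# ---------------------------------------------------------------------------

def load_input_dishes(
    input_dir: str | Path, species_set,
) -> tuple[list[AnnotatedDish], list[AnnotatedDish]]:
    """Load ``dish_*.png``/``.json`` pairs; dishes without colonies are backgrounds."""
    input_dir = Path(input_dir)
    annotated, empty = [], []
    for img_path in sorted(input_dir.glob("*.png")):
        ann_path = img_path.with_suffix(".json")
        if not ann_path.exists():
            continue
        dish = read_annotated_dish(img_path, ann_path, species_set=tuple(species_set))
        (annotated if dish.annotations else empty).append(dish)
    return annotated, empty


def fixture_input_dishes(
    cfg: GenConfig, seed: int, n_per_species: int = 2, n_empty: int | None = None,
) -> tuple[list[AnnotatedDish], list[AnnotatedDish]]:
    """In-memory fixture dishes emulating the annotated + empty input sets.

    The empty-dish fixtures are rendered large enough that a patch-sized
    crop always fits inside the rotated dish image.
    """
    fix_cfg = FixtureConfig()
    annotated = []
    k = 0
    for sp in cfg.species_set:
        for _ in range(n_per_species):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 77, k]))
            dish, _ = make_annotated_dish(fix_cfg, rng, species=sp,
                                          source_id=f"fixture_dish_{k}")
            annotated.append(dish)
            k += 1
    # backgrounds: dish must exceed the patch so rotated crops stay fill-free
    bg_cfg = FixtureConfig(
        dish_diameter=max(3 * cfg.composition.patch_size, fix_cfg.dish_diameter),
        noise_sigma=fix_cfg.noise_sigma,
    )
    n_empty = cfg.composition.n_empty_dishes if n_empty is None else n_empty
    empty = [
        make_empty_dish(bg_cfg, np.random.default_rng(np.random.SeedSequence([seed, 88, j])),
                        source_id=f"fixture_empty_{j}")
        for j in range(n_empty)
    ]
    return annotated, empty


def resolve_styles(cfg: GenConfig, seed: int, n_styles: int = 20,
                   annotated: list[AnnotatedDish] | None = None) -> list[np.ndarray]:
    """Style-carrier fragments: loaded from disk, or cropped from input dishes.

    The method uses a modest pool of real fragments with varied lighting as
    style carriers, cycled round-robin over stylization tiles.
    """
    import imageio.v3 as iio

    if cfg.styles_dir:
        paths = sorted(Path(cfg.styles_dir).glob("*.png")) + sorted(
            Path(cfg.styles_dir).glob("*.jpg"))
        styles = [np.ascontiguousarray(iio.imread(p)[:, :, :3]) for p in paths]
        if styles:
            return styles[:n_styles]
    if not annotated:
        raise PipelineError("stylize", None, ValueError("no style sources available"))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    styles = []
    for _ in range(n_styles):
        dish = annotated[int(rng.integers(len(annotated)))]
        h, w = dish.shape
        s = min(128, h, w)
        r0 = int(rng.integers(0, h - s + 1))
        c0 = int(rng.integers(0, w - s + 1))
        styles.append(dish.image[r0 : r0 + s, c0 : c0 + s].copy())
    return styles


# ---------------------------------------------------------------------------
# bank construction + stylization sweep
# ---------------------------------------------------------------------------

def build_bank(
    annotated: list[AnnotatedDish], cfg: GenConfig,
) -> dict[str, list[ClusterCutout]]:
    bank: dict[str, list[ClusterCutout]] = {sp: [] for sp in cfg.species_set}
    for dish in annotated:
        try:
            for cut in extract_dish(dish, cfg.extraction, cfg.overlap_threshold):
                bank.setdefault(cut.species, []).append(cut)
        except Exception as exc:  # pragma: no cover - surfaced with context
            raise PipelineError("extract", None, exc) from exc
    bank = {sp: cuts for sp, cuts in bank.items() if cuts}
    if not bank:
        raise PipelineError("extract", None, ValueError("cutout bank is empty"))
    for sp in cfg.species_set:
        if sp not in bank:
            logger.warning("stage=extract species=%s has no cutouts; skipped", sp)
    return bank


def stylize_records(
    records: list[SynthPatchRecord],
    styles: list[np.ndarray],
    style_cfg: StyleConfig,
    seed: int,
) -> list[SynthPatchRecord]:
    """Stylize a record list tile-by-tile with round-robin styles + warm starts.

    A trailing group smaller than ``patches_per_tile`` is padded by repeating
    its last patch; the pad outputs are discarded.
    """
    n_tile = style_cfg.patches_per_tile
    out: list[SynthPatchRecord] = []
    weights = None
    for t0 in range(0, len(records), n_tile):
        group = records[t0 : t0 + n_tile]
        pad = n_tile - len(group)
        padded = group + [group[-1]] * pad
        style_idx = (t0 // n_tile) % len(styles)
        tile_seed = int(np.random.SeedSequence([seed, 555, t0]).generate_state(1)[0] % (2**31))
        styled, weights = stylize_batch(
            padded,
            styles[style_idx],
            style_cfg,
            init_weights=weights if style_cfg.warm_start else None,
            style_id=f"style_{style_idx}",
            seed=tile_seed,
        )
        out.extend(styled[: len(group)])
    return out


# ---------------------------------------------------------------------------
# the end-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(
    cfg: GenConfig,
    n_patches: int,
    seed: int,
    style_mode: str = "raw",
    out_dir: str | Path = "out",
    overwrite: bool = False,
) -> Path:
    """Extract, compose and (optionally) stylize; return the manifest path.

    ``style_mode``: ``raw`` skips stylization, ``semi`` stylizes with
    lambda = 0.02, ``full`` with lambda = 0.05.  The manifest records mode,
    seed and a configuration hash.  On a stage failure, partial output is
    kept next to a ``FAILED`` marker naming the stage and patch index.
    """
    if style_mode not in STYLE_MODES:
        raise ValueError(f"style_mode must be one of {sorted(STYLE_MODES)}")
    errors = [m for lvl, m in validate_config(cfg) if lvl == "error"]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out_dir = Path(out_dir)
    try:
        if cfg.input_dir:
            annotated, empty = load_input_dishes(cfg.input_dir, cfg.species_set)
        else:
            annotated, empty = fixture_input_dishes(cfg, seed)
        if not empty:
            raise PipelineError("inputs", None, ValueError("no empty dishes available"))
        logger.info("stage=extract dishes=%d seed=%d", len(annotated), seed)
        bank = build_bank(annotated, cfg)
        comp_cfg = cfg.composition
        bank = {sp: cuts for sp, cuts in bank.items()}
        logger.info("stage=compose n_patches=%d seed=%d", n_patches, seed)
        records = generate_patches(bank, empty, comp_cfg, n_patches, seed)

        lam = STYLE_MODES[style_mode]
        if lam is not None:
            side = int(round(cfg.style.patches_per_tile ** 0.5))
            style_cfg = StyleConfig(
                lambda_weight=lam,
                feature_layers=cfg.style.feature_layers,
                iterations=cfg.style.iterations,
                learning_rate=cfg.style.learning_rate,
                tile_size=comp_cfg.patch_size * side,
                patches_per_tile=cfg.style.patches_per_tile,
                warm_start=cfg.style.warm_start,
                generator_arch=cfg.style.generator_arch,
            )
            styles = resolve_styles(cfg, seed, annotated=annotated)
            logger.info("stage=stylize mode=%s lambda=%.3f tiles=%d seed=%d",
                        style_mode, lam, (len(records) + 3) // 4, seed)
            records = stylize_records(records, styles, style_cfg, seed)

        manifest = write_dataset(
            records, out_dir, fmt="coco_json",
            species_set=tuple(cfg.species_set), overwrite=overwrite,
            extra_meta={"style_mode": style_mode, "seed": seed,
                        "config_hash": cfg.digest()},
        )
        return manifest
    except PipelineError as err:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "FAILED").write_text(json.dumps(
            {"stage": err.stage, "patch_index": err.index, "error": str(err.cause)}))
        raise
    except Exception as exc:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "FAILED").write_text(json.dumps(
            {"stage": "compose", "error": str(exc)}))
        raise


__all__ = [
    "STYLE_MODES",
    "PipelineError",
    "load_input_dishes",
    "fixture_input_dishes",
    "resolve_styles",
    "build_bank",
    "stylize_records",
    "run_pipeline",
]
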