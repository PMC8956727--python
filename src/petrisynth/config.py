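"""Pipeline configuration: the 13 tunable stage parameters plus plumbing.

The generator intentionally exposes a small tunable surface — thirteen
parameters spread over the stages of the method (colony clustering, unsharp
filtering, CIELab artifact thresholding, artifact-mask dilation, speckle
cancellation, Chan–Vese segmentation, segmentation-mask dilation, blending
mask, style transfer).  Everything else (patch size, counts, seeds, paths)
is operational plumbing and lives in separate config sections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clusters import DEFAULT_OVERLAP_THRESHOLD
from .composition import CompositionConfig
from .datamodel import DEFAULT_SPECIES
from .extraction import ExtractionConfig
from .stylization import StyleConfig

#: The tunable-parameter inventory, grouped by pipeline stage:
#: (stage, yaml key, (sub-config, attribute)).  Enumerating the leaves
#: yields exactly the 13 user-tunable parameters of the method.
TUNABLE_INVENTORY: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("colonies_clustering", "overlap_threshold", ("overlap_threshold",)),
    ("unsharp_mask_filtering", "radius", ("extraction", "unsharp_radius")),
    ("unsharp_mask_filtering", "amount", ("extraction", "unsharp_amount")),
    ("cielab_thresholding", "L", ("extraction", "dark_L_threshold")),
    ("cielab_thresholding", "b", ("extraction", "dark_b_threshold")),
    ("artifact_mask_dilation", "radius", ("extraction", "dark_dilate_radius")),
    ("speckle_noise_cancellation", "strength", ("extraction", "nlm_strength")),
    ("speckle_noise_cancellation", "patch", ("extraction", "nlm_patch")),
    ("chan_vese_segmentation", "mu", ("extraction", "cv_mu")),
    ("chan_vese_segmentation", "max_iter", ("extraction", "cv_max_iter")),
    ("segmentation_mask_dilation", "radius", ("extraction", "seg_dilate_radius")),
    ("blending_mask", "gamma", ("extraction", "blend_gamma")),
    ("neural_style_transfer", "lambda", ("style", "lambda_weight")),
)

#: Expected tunables per stage.
STAGE_COUNTS = {
    "colonies_clustering": 1,
    "unsharp_mask_filtering": 2,
    "cielab_thresholding": 2,
    "artifact_mask_dilation": 1,
    "speckle_noise_cancellation": 2,
    "chan_vese_segmentation": 2,
    "segmentation_mask_dilation": 1,
    "blending_mask": 1,
    "neural_style_transfer": 1,
}


@dataclass
class GenConfig:
    """Full pipeline configuration."""

    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    composition: CompositionConfig = field(default_factory=CompositionConfig)
    style: StyleConfig = field(default_factory=StyleConfig)
    species_set: tuple[str, ...] = DEFAULT_SPECIES
    input_dir: str | None = None      # annotated + empty dishes; None -> fixtures
    styles_dir: str | None = None     # style-carrier fragments; None -> fixtures

    # -- tunable access ----------------------------------------------------
    def _resolve(self, path: tuple[str, ...]):
        obj = self
        for name in path[:-1]:
            obj = getattr(obj, name)
        return obj, path[-1]

    def tunables(self) -> dict[str, dict[str, float]]:
        """The stage-grouped view of the 13 tunable parameters."""
        out: dict[str, dict[str, float]] = {}
        for stage, key, path in TUNABLE_INVENTORY:
            obj, attr = self._resolve(path)
            out.setdefault(stage, {})[key] = getattr(obj, attr)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stages": self.tunables(),
            "composition": {
                "patch_size": self.composition.patch_size,
                "count_mean": self.composition.count_mean,
                "max_place_attempts": self.composition.max_place_attempts,
                "n_empty_dishes": self.composition.n_empty_dishes,
                "allow_scaling": self.composition.allow_scaling,
            },
            "style_transfer": {
                "iterations": self.style.iterations,
                "learning_rate": self.style.learning_rate,
                "tile_size": self.style.tile_size,
                "patches_per_tile": self.style.patches_per_tile,
                "warm_start": self.style.warm_start,
                "generator_arch": self.style.generator_arch,
            },
            "species_set": list(self.species_set),
            "paths": {"input_dir": self.input_dir, "styles_dir": self.styles_dir},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GenConfig":
        cfg = cls()
        stages = doc.get("stages", {})
        for stage, key, path in TUNABLE_INVENTORY:
            if stage in stages and key in stages[stage]:
                obj, attr = cfg._resolve(path)
                cur = getattr(obj, attr)
                setattr(obj, attr, type(cur)(stages[stage][key]))
        for sect, obj in (("composition", cfg.composition), ("style_transfer", cfg.style)):
            for k, v in doc.get(sect, {}).items():
                if hasattr(obj, k):
                    setattr(obj, k, v)
        if "species_set" in doc:
            cfg.species_set = tuple(doc["species_set"])
        paths = doc.get("paths", {})
        cfg.input_dir = paths.get("input_dir")
        cfg.styles_dir = paths.get("styles_dir")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(cfg: GenConfig) -> list[tuple[str, str]]:
    """Check ranges and the 13-parameter inventory; return (level, message) findings.

    Levels are ``"error"`` and ``"warning"``; an empty error list means the
    configuration is usable.
    """
    findings: list[tuple[str, str]] = []
    tun = cfg.tunables()
    counts = {stage: len(params) for stage, params in tun.items()}
    if counts != STAGE_COUNTS:
        findings.append(("error", f"tunable inventory mismatch: {counts} != {STAGE_COUNTS}"))
    total = sum(counts.values())
    if total != 13:
        findings.append(("error", f"expected 13 tunable parameters, found {total}"))

    ex = cfg.extraction
    for name in ("unsharp_radius", "dark_dilate_radius", "seg_dilate_radius",
                 "nlm_strength", "nlm_patch"):
        if getattr(ex, name) < 0:
            findings.append(("error", f"extraction.{name} must be >= 0"))
    if ex.cv_max_iter < 1:
        findings.append(("error", "extraction.cv_max_iter must be >= 1"))
    if not (0.0 < cfg.overlap_threshold < 1.0):
        findings.append(("error", "overlap_threshold must lie in (0, 1)"))
    if cfg.composition.patch_size <= 0:
        findings.append(("error", "composition.patch_size must be > 0"))
    if cfg.composition.count_mean <= 0:
        findings.append(("error", "composition.count_mean must be > 0"))
    lam = cfg.style.lambda_weight
    if not (0.0 <= lam <= 1.0):
        findings.append(("error", "style lambda must lie in [0, 1]"))
    elif lam > 0.05:
        findings.append(("warning",
                         f"style lambda {lam} > 0.05 may degrade species fidelity"))
    side = int(round(cfg.style.patches_per_tile ** 0.5))
    if cfg.style.tile_size != cfg.composition.patch_size * side:
        findings.append(("error",
                         f"style.tile_size {cfg.style.tile_size} must equal "
                         f"patch_size * sqrt(patches_per_tile) = "
                         f"{cfg.composition.patch_size * side}"))
    if len(set(cfg.species_set)) != len(cfg.species_set) or not cfg.species_set:
        findings.append(("error", "species_set must be a nonempty set of unique labels"))
    return findings


__all__ = [
    "GenConfig",
    "TUNABLE_INVENTORY",
    "STAGE_COUNTS",
    "validate_config",
]
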