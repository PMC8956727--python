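"""One-shot neural style transfer with Gram-matrix losses.

A small image-generation network is trained per (content, style) pair to
minimize

    L(y, y_c, y_s) = (1 - lam) * ||G(y) - G(y_c)|| + lam * ||G(y) - G(y_s)||

where G are Gram matrices of feature maps from a frozen convolutional
feature extractor, the norm is the (unsquared) Frobenius norm summed over
the selected layers, and ``lam`` mixes content against style (0.02 gives a
semi-stylized output, 0.05 a fully-stylized one; pushing ``lam`` much higher
starts to wash out class-relevant colony appearance).

Everything here — the feature extractor, the generator networks and their
backward passes — is implemented directly on numpy arrays.  The extractor is
a fixed random-weight convolutional pyramid: its weights are drawn once from
a seeded He-scaled normal and never trained, so Gram statistics are stable
across runs and the loss is a deterministic function of its inputs.  The
generator parameterizes its output as input + residual with a zero-initial
head, so an untrained generator is exactly the identity; this keeps warm
starts well-behaved and makes zero-iteration stylization a no-op.

Training is plain stochastic gradient descent.  To amortize the per-style
training cost, four patches are assembled into one 2x2 tile (1024x1024 for
512-px patches) and stylized in a single shot; with warm starts the weights
from the previous tile seed the next one.  Stylization never touches
annotations or masks — it is pixel-only and geometry-preserving.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import SynthPatchRecord, ValidationError

logger = logging.getLogger("petrisynth")

#: Channel widths of the five extractor blocks (each block: 3x3 conv + ReLU,
#: with 2x average pooling between blocks).
FEATURE_CHANNELS = (8, 12, 16, 16, 16)
_EXTRACTOR_SEED = 1_000_003


@dataclass
class StyleConfig:
    lambda_weight: float = 0.05          # style weight in [0, 1]
    feature_layers: tuple[int, ...] = (0, 1, 2, 3, 4)
    iterations: int = 200
    learning_rate: float = 1e-2
    tile_size: int = 1024
    patches_per_tile: int = 4
    warm_start: bool = True
    generator_arch: str = "highres"      # or "light" for CPU-scale work

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_weight <= 1.0):
            raise ValidationError("lambda_weight must lie in [0, 1]")
        if self.lambda_weight > 0.05:
            warnings.warn(
                f"lambda_weight={self.lambda_weight} > 0.05: heavy stylization "
                "degrades species fidelity",
                stacklevel=2,
            )
        if not self.feature_layers:
            raise ValidationError("feature_layers must be nonempty")
        side = int(round(self.patches_per_tile ** 0.5))
        if side * side != self.patches_per_tile:
            raise ValidationError("patches_per_tile must be a perfect square")


# ---------------------------------------------------------------------------
# numpy layers with explicit backward passes
# ---------------------------------------------------------------------------

class _Conv3x3:
    """Same-padded 3x3 convolution on (C, H, W) tensors."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.w = np.zeros((cout, cin, 3, 3))
        else:
            std = np.sqrt(2.0 / (cin * 9))
            self.w = rng.normal(0.0, std, (cout, cin, 3, 3))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        out = np.broadcast_to(self.b[:, None, None], (self.w.shape[0], h, w)).copy()
        for dy in range(3):
            for dx in range(3):
                out += np.tensordot(self.w[:, :, dy, dx],
                                    xp[:, dy : dy + h, dx : dx + w], axes=([1], [0]))
        if cache:
            self._xp = xp
        return out

    def backward(self, go: np.ndarray) -> np.ndarray:
        xp = self._xp
        _, h, w = go.shape
        self.gb += go.sum(axis=(1, 2))
        gxp = np.zeros_like(xp)
        for dy in range(3):
            for dx in range(3):
                self.gw[:, :, dy, dx] += np.tensordot(
                    go, xp[:, dy : dy + h, dx : dx + w], axes=([1, 2], [1, 2])
                )
                gxp[:, dy : dy + h, dx : dx + w] += np.tensordot(
                    self.w[:, :, dy, dx], go, axes=([0], [0])
                )
        return gxp[:, 1 : h + 1, 1 : w + 1]

    @property
    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, go: np.ndarray) -> np.ndarray:
        return go * self._mask


def _avg_pool(x: np.ndarray, f: int) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // f, f, w // f, f).mean(axis=(2, 4))


def _avg_pool_backward(go: np.ndarray, f: int) -> np.ndarray:
    c, h, w = go.shape
    return np.repeat(np.repeat(go, f, axis=1), f, axis=2) / (f * f)


def _upsample(x: np.ndarray, f: int) -> np.ndarray:
    return np.repeat(np.repeat(x, f, axis=1), f, axis=2)


def _upsample_backward(go: np.ndarray, f: int) -> np.ndarray:
    c, h, w = go.shape
    return go.reshape(c, h // f, f, w // f, f).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# frozen feature extractor
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Frozen five-block convolutional pyramid used for Gram statistics.

    Weights are seeded random and never updated; only activations flow.
    """

    def __init__(self, channels: tuple[int, ...] = FEATURE_CHANNELS,
                 seed: int = _EXTRACTOR_SEED):
        rng = np.random.default_rng(seed)
        cin = 3
        self.convs: list[_Conv3x3] = []
        for cout in channels:
            self.convs.append(_Conv3x3(cin, cout, rng))
            cin = cout
        self.relus = [_ReLU() for _ in channels]

    def forward(self, x: np.ndarray, cache: bool = False,
                n_blocks: int | None = None) -> list[np.ndarray]:
        """Feature maps of the first ``n_blocks`` blocks of an (H, W, 3) image.

        Odd spatial extents are trimmed by one row/column before each 2x
        pooling so arbitrary image sizes are accepted; the trims are replayed
        (zero-gradient) in :meth:`backward`.
        """
        t = np.ascontiguousarray(x.transpose(2, 0, 1)).astype(np.float64)
        feats = []
        trims: list[tuple[int, int]] = []
        n = len(self.convs) if n_blocks is None else min(n_blocks, len(self.convs))
        for i in range(n):
            if i > 0:
                c, h, w = t.shape
                trims.append((h % 2, w % 2))
                t = t[:, : h - h % 2, : w - w % 2]
                t = _avg_pool(t, 2)
            t = self.relus[i].forward(self.convs[i].forward(t, cache=cache),
                                      cache=cache)
            feats.append(t)
        if cache:
            self._trims = trims
        return feats

    def backward(self, feat_grads: list[np.ndarray]) -> np.ndarray:
        """Backpropagate per-layer feature gradients to the input image."""
        g = None
        n = len(feat_grads)
        for i in range(n - 1, -1, -1):
            gi = feat_grads[i]
            g = gi if g is None else g + gi
            g = self.convs[i].backward(self.relus[i].backward(g))
            if i > 0:
                g = _avg_pool_backward(g, 2)
                th, tw = self._trims[i - 1]
                if th or tw:
                    g = np.pad(g, ((0, 0), (0, th), (0, tw)))
        return g.transpose(1, 2, 0).astype(np.float64)


_default_extractor: FeatureExtractor | None = None


def default_extractor() -> FeatureExtractor:
    global _default_extractor
    if _default_extractor is None:
        _default_extractor = FeatureExtractor()
    return _default_extractor


# ---------------------------------------------------------------------------
# Gram matrices and the style/content loss
# ---------------------------------------------------------------------------

def gram(features: np.ndarray) -> np.ndarray:
    """Gram matrix G = F F^T / (C H W) of a (C, H, W) feature tensor."""
    c, h, w = features.shape
    f = features.reshape(c, h * w).astype(np.float64)
    return (f @ f.T) / (c * h * w)


def _gram_term(feats_y, feats_t, layers):
    """Sum of per-layer Frobenius distances and the matrices needed for grads."""
    total = 0.0
    mats = {}
    for layer in layers:
        d = gram(feats_y[layer]) - gram(feats_t[layer])
        n = float(np.linalg.norm(d))
        total += n
        mats[layer] = (d, n)
    return total, mats


def style_content_loss(
    y: np.ndarray,
    y_c: np.ndarray,
    y_s: np.ndarray,
    cfg: StyleConfig,
    extractor: FeatureExtractor | None = None,
    return_grad: bool = False,
):
    """Evaluate L(y, y_c, y_s); optionally also dL/dy.

    Images are (H, W, 3) floats in [0, 1]; the style image may have a
    different size from the content (Gram matrices are size-agnostic).
    """
    ext = extractor or default_extractor()
    layers = cfg.feature_layers
    lam = cfg.lambda_weight
    n_blocks = max(layers) + 1
    feats_y = ext.forward(y, cache=return_grad, n_blocks=n_blocks)
    feats_c = ext.forward(y_c, n_blocks=n_blocks) if y_c is not None else None
    feats_s = ext.forward(y_s, n_blocks=n_blocks) if y_s is not None else None

    loss = 0.0
    grads_G: dict[int, np.ndarray] = {}
    for weight, feats_t in (((1.0 - lam), feats_c), (lam, feats_s)):
        if weight == 0.0 or feats_t is None:
            continue
        term, mats = _gram_term(feats_y, feats_t, layers)
        loss += weight * term
        if return_grad:
            for layer, (d, n) in mats.items():
                if n > 0:
                    g = weight * d / n
                    grads_G[layer] = grads_G.get(layer, 0.0) + g
    if not return_grad:
        return loss

    feat_grads = []
    for i, f in enumerate(feats_y):
        c, h, w = f.shape
        if i in grads_G:
            m = grads_G[i]
            fg = (2.0 / (c * h * w)) * (m @ f.reshape(c, h * w).astype(np.float64))
            feat_grads.append(fg.reshape(c, h, w))
        else:
            feat_grads.append(np.zeros_like(f))
    return loss, ext.backward(feat_grads)


# ---------------------------------------------------------------------------
# generator networks
# ---------------------------------------------------------------------------

class _GeneratorBase:
    """Residual RGB->RGB generator: output = input + head(trunk(input))."""

    stride_requirement = 4
    convs: dict[str, _Conv3x3]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, conv in self.convs.items():
            out[f"{name}.w"] = conv.w.copy()
            out[f"{name}.b"] = conv.b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, conv in self.convs.items():
            conv.w[...] = state[f"{name}.w"]
            conv.b[...] = state[f"{name}.b"]

    def zero_grad(self) -> None:
        for conv in self.convs.values():
            conv.gw[...] = 0.0
            conv.gb[...] = 0.0

    def sgd_step(self, lr: float) -> None:
        for conv in self.convs.values():
            conv.w -= lr * conv.gw
            conv.b -= lr * conv.gb

    def n_parameters(self) -> int:
        return sum(c.w.size + c.b.size for c in self.convs.values())

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Forward an (H, W, 3) image in [0, 1]."""
        x = np.ascontiguousarray(image.transpose(2, 0, 1)).astype(np.float64)
        y = self.forward_chw(x)
        return y.transpose(1, 2, 0).astype(np.float64)

    def backward_image(self, grad_y: np.ndarray) -> None:
        self.backward_chw(np.ascontiguousarray(
            grad_y.transpose(2, 0, 1)).astype(np.float64))


class LightGenerator(_GeneratorBase):
    """3-level residual fully-convolutional net for CPU-scale runs.

    A stem feeds three parallel branches at full, half and quarter
    resolution; their outputs are fused by summation and a zero-initialized
    head produces the residual.
    """

    def __init__(self, rng: np.random.Generator, width: int = 8):
        self.convs = {
            "stem": _Conv3x3(3, width, rng),
            "full": _Conv3x3(width, width, rng),
            "half": _Conv3x3(width, width, rng),
            "quarter": _Conv3x3(width, width, rng),
            "head": _Conv3x3(width, 3, rng, zero_init=True),
        }
        self.relus = {k: _ReLU() for k in ("stem", "full", "half", "quarter")}

    def forward_chw(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        s = self.relus["stem"].forward(self.convs["stem"].forward(x))
        f = self.relus["full"].forward(self.convs["full"].forward(s))
        h = _upsample(self.relus["half"].forward(
            self.convs["half"].forward(_avg_pool(s, 2))), 2)
        q = _upsample(self.relus["quarter"].forward(
            self.convs["quarter"].forward(_avg_pool(s, 4))), 4)
        fused = f + h + q
        return x + self.convs["head"].forward(fused)

    def backward_chw(self, go: np.ndarray) -> None:
        g = self.convs["head"].backward(go)
        gs = self.convs["full"].backward(self.relus["full"].backward(g))
        gh = _avg_pool_backward(
            self.convs["half"].backward(
                self.relus["half"].backward(_upsample_backward(g, 2))), 2)
        gq = _avg_pool_backward(
            self.convs["quarter"].backward(
                self.relus["quarter"].backward(_upsample_backward(g, 4))), 4)
        self.convs["stem"].backward(self.relus["stem"].backward(gs + gh + gq))


class HighResGenerator(_GeneratorBase):
    """Small multi-resolution generator with a persistent full-resolution branch.

    Two fusion stages exchange information between a full-resolution branch
    and a half-resolution branch (downsample/upsample convs), in the spirit
    of high-resolution representation networks; the head is zero-initialized
    so the untrained network is the identity.
    """

    def __init__(self, rng: np.random.Generator, width: int = 8, width_lo: int = 16):
        self.convs = {"stem": _Conv3x3(3, width, rng)}
        self.relus = {"stem": _ReLU()}
        for s in (1, 2):
            self.convs[f"full{s}"] = _Conv3x3(width, width, rng)
            self.convs[f"low{s}"] = _Conv3x3(width_lo, width_lo, rng)
            self.convs[f"down{s}"] = _Conv3x3(width, width_lo, rng)
            self.convs[f"up{s}"] = _Conv3x3(width_lo, width, rng)
            for k in (f"full{s}", f"low{s}", f"down{s}", f"up{s}"):
                self.relus[k] = _ReLU()
        self.convs["head"] = _Conv3x3(width, 3, rng, zero_init=True)

    def forward_chw(self, x: np.ndarray) -> np.ndarray:
        s = self.relus["stem"].forward(self.convs["stem"].forward(x))
        full = s
        low = self.relus["down1"].forward(self.convs["down1"].forward(_avg_pool(s, 2)))
        for st in (1, 2):
            if st == 2:
                low = low + self.relus["down2"].forward(
                    self.convs["down2"].forward(_avg_pool(full, 2)))
            full_new = self.relus[f"full{st}"].forward(
                self.convs[f"full{st}"].forward(full))
            low_new = self.relus[f"low{st}"].forward(
                self.convs[f"low{st}"].forward(low))
            fused = full_new + _upsample(
                self.relus[f"up{st}"].forward(self.convs[f"up{st}"].forward(low_new)), 2)
            full, low = fused, low_new
        self._x = x
        return x + self.convs["head"].forward(full)

    def backward_chw(self, go: np.ndarray) -> None:
        g_full = self.convs["head"].backward(go)
        g_low = np.zeros(
            (self.convs["low2"].w.shape[0],
             g_full.shape[1] // 2, g_full.shape[2] // 2))
        for st in (2, 1):
            g_low_new = self.convs[f"up{st}"].backward(
                self.relus[f"up{st}"].backward(_upsample_backward(g_full, 2))) + g_low
            g_full_in = self.convs[f"full{st}"].backward(
                self.relus[f"full{st}"].backward(g_full))
            g_low_in = self.convs[f"low{st}"].backward(
                self.relus[f"low{st}"].backward(g_low_new))
            if st == 2:
                g_full_in = g_full_in + _avg_pool_backward(
                    self.convs["down2"].backward(
                        self.relus["down2"].backward(g_low_in)), 2)
                g_low = g_low_in  # identity branch of low = low + down2(...)
                g_full = g_full_in
            else:
                g_stem = g_full_in + _avg_pool_backward(
                    self.convs["down1"].backward(
                        self.relus["down1"].backward(g_low_in)), 2)
        self.convs["stem"].backward(self.relus["stem"].backward(g_stem))


def build_generator(arch: str, size: int,
                    rng: np.random.Generator | None = None,
                    head_init: str = "zero",
                    head_std: float = 0.05) -> _GeneratorBase:
    """Instantiate a generator; ``size`` must be divisible by 4 (pool strides).

    ``head_init="zero"`` gives an exact-identity network (output == input);
    ``"small"`` draws the head from a normal with ``head_std``, a
    near-identity start that leaves the loss surface's flat point.  The
    unsquared Gram norms make the exact content image a non-smooth local
    minimum, so cold-start training needs the small random head to have a
    usable descent direction.
    """
    if size % 4 != 0:
        raise ValidationError(f"generator input size {size} must be divisible by 4")
    rng = rng if rng is not None else np.random.default_rng(0)
    if arch == "light":
        gen: _GeneratorBase = LightGenerator(rng)
    elif arch == "highres":
        gen = HighResGenerator(rng)
    else:
        raise ValidationError(f"unknown generator architecture {arch!r}")
    if head_init == "small":
        gen.convs["head"].w += rng.normal(0.0, head_std, gen.convs["head"].w.shape)
    elif head_init != "zero":
        raise ValidationError(f"unknown head_init {head_init!r}")
    return gen


# ---------------------------------------------------------------------------
# training and batch stylization
# ---------------------------------------------------------------------------

def train_stylizer(
    content_tile: np.ndarray,
    style_image: np.ndarray,
    cfg: StyleConfig,
    init_weights: dict[str, np.ndarray] | None = None,
    extractor: FeatureExtractor | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """One-shot SGD training of the generator on a single (content, style) pair.

    Images are (H, W, 3) floats in [0, 1].  Returns the trained weights and
    the per-iteration loss trace (entry 0 is the pre-step loss).  With
    ``init_weights`` the generator warm-starts from a previous tile's
    solution instead of the seeded random initialization.
    """
    size = content_tile.shape[0]
    head_init = "small" if init_weights is None and cfg.iterations > 0 else "zero"
    gen = build_generator(cfg.generator_arch, size, np.random.default_rng(seed),
                          head_init=head_init)
    if init_weights is not None:
        gen.load_state_dict(init_weights)
    losses: list[float] = []
    for it in range(cfg.iterations):
        y = gen(content_tile)
        loss, grad_y = style_content_loss(
            y, content_tile, style_image, cfg, extractor, return_grad=True)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite stylization loss at iteration {it} "
                f"(learning_rate={cfg.learning_rate})"
            )
        losses.append(float(loss))
        gen.zero_grad()
        gen.backward_image(grad_y)
        gen.sgd_step(cfg.learning_rate)
    return gen.state_dict(), losses


def assemble_tile(patches: list[np.ndarray]) -> np.ndarray:
    """Assemble equally sized patches into a square tile, row-major."""
    side = int(round(len(patches) ** 0.5))
    if side * side != len(patches):
        raise ValidationError("number of patches must be a perfect square")
    shapes = {p.shape for p in patches}
    if len(shapes) != 1:
        raise ValidationError(f"patch sizes differ: {sorted(shapes)}")
    rows = [np.concatenate(patches[r * side : (r + 1) * side], axis=1)
            for r in range(side)]
    return np.concatenate(rows, axis=0)


def split_tile(tile: np.ndarray, n: int) -> list[np.ndarray]:
    """Inverse of :func:`assemble_tile`."""
    side = int(round(n ** 0.5))
    s = tile.shape[0] // side
    return [tile[r * s : (r + 1) * s, c * s : (c + 1) * s]
            for r in range(side) for c in range(side)]


def stylize_batch(
    raw_patches: list[SynthPatchRecord],
    style_image: np.ndarray,
    cfg: StyleConfig,
    init_weights: dict[str, np.ndarray] | None = None,
    extractor: FeatureExtractor | None = None,
    style_id: str = "style",
    seed: int = 0,
) -> tuple[list[SynthPatchRecord], dict[str, np.ndarray]]:
    """Stylize ``patches_per_tile`` patches as one tile with a single style.

    The patches are assembled row-major into a square tile, the one-shot
    generator is trained on (tile, style), and the stylized tile is split
    back.  Annotations and masks are carried over untouched — stylization is
    geometry-preserving by construction.
    """
    if len(raw_patches) != cfg.patches_per_tile:
        raise ValidationError(
            f"need exactly {cfg.patches_per_tile} patches, got {len(raw_patches)}"
        )
    patch_size = raw_patches[0].image.shape[0]
    side = int(round(cfg.patches_per_tile ** 0.5))
    if cfg.tile_size != patch_size * side:
        raise ValidationError(
            f"tile_size {cfg.tile_size} != patch_size {patch_size} * {side}"
        )
    tile = assemble_tile([r.image for r in raw_patches]).astype(np.float64) / 255.0
    style = style_image.astype(np.float64) / 255.0 if style_image.dtype == np.uint8 \
        else np.asarray(style_image, dtype=np.float64)

    weights, losses = train_stylizer(tile, style, cfg, init_weights, extractor, seed)
    gen = build_generator(cfg.generator_arch, tile.shape[0], np.random.default_rng(seed))
    gen.load_state_dict(weights)
    out_tile = np.clip(gen(tile), 0.0, 1.0)
    out_patches = split_tile((out_tile * 255).round().astype(np.uint8),
                             cfg.patches_per_tile)
    records = []
    for rec, img in zip(raw_patches, out_patches):
        records.append(
            SynthPatchRecord(
                image=img,
                annotations=list(rec.annotations),
                masks=[m.copy() for m in rec.masks],
                provenance={**rec.provenance, "style": style_id,
                            "lambda": cfg.lambda_weight},
            )
        )
    if losses:
        logger.info("stylized tile: loss %.4f -> %.4f over %d iterations",
                    losses[0], losses[-1], len(losses))
    return records, weights


__all__ = [
    "StyleConfig",
    "FeatureExtractor",
    "default_extractor",
    "gram",
    "style_content_loss",
    "build_generator",
    "LightGenerator",
    "HighResGenerator",
    "train_stylizer",
    "assemble_tile",
    "split_tile",
    "stylize_batch",
]
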