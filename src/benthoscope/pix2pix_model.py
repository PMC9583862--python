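"""Conditional-GAN image-to-image translation of RGB tiles to class-color maps.

The translator follows the pix2pix recipe: a U-Net generator (stride-2
4x4-kernel encoder, mirrored transposed-convolution decoder with skip
connections, tanh output) regresses the palette-colored ground-truth map
from the RGB tile, while a PatchGAN discriminator judges (input, map) pairs;
the generator objective is the adversarial term plus ``lambda_l1`` times the
mean absolute error between translated and target color images.  The
network regresses *colors*, not per-class scores — faithful to training on
colored ground-truth imagery — and the continuous output is discretized by
nearest-palette-color lookup, with ZM subclasses merged back to ZM.

All hyperparameters are surfaced in :class:`GanConfig`; the defaults
(lambda 100, Adam lr 2e-4 beta1 0.5, batch 4) are the customary values for
this model family.  Capacity scales down so a 64-pixel-tile model trains in
minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _nn as nn
from .raster_io import (
    ALL_LABELS,
    LabelMap,
    OrthoImage,
    encode_labels,
    merge_subclasses,
    nearest_class_indices,
)
from .tiling import TilePair, reassemble, slice_tiles

__all__ = [
    "GanConfig",
    "TranslationModel",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "train",
    "translate",
]

logger = logging.getLogger(__name__)


@dataclass
class GanConfig:
    """Hyperparameters of the translation model.

    ``tile_size`` must be divisible by 2^depth (U-Net downsampling);
    ``lambda_l1`` weights the reconstruction term of the generator loss.
    """

    tile_size: int = 64
    base_channels: int = 16
    depth: int = 3
    lambda_l1: float = 100.0
    learning_rate: float = 2e-4
    beta1: float = 0.5
    batch_size: int = 4
    epochs: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.tile_size % (2 ** self.depth) != 0 or self.tile_size < 2 ** self.depth:
            raise ValueError(
                f"tile_size {self.tile_size} not divisible by 2^depth = {2 ** self.depth}"
            )
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


class UNetGenerator:
    """Encoder-decoder with skip connections; RGB in, RGB (tanh) out."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        bc, d = config.base_channels, config.depth
        self.depth = d
        self.channels = [min(bc * 2 ** i, 8 * bc) for i in range(d)]
        self.down = []
        self.down_bn = []
        cin = 3
        for i, ch in enumerate(self.channels):
            self.down.append(nn.Conv2d(cin, ch, rng))
            self.down_bn.append(nn.BatchNorm2d(ch, rng) if i > 0 else None)
            cin = ch
        self.up = []
        self.up_bn = []
        cur = self.channels[-1]
        for i in range(d - 2, -1, -1):
            ch = self.channels[i]
            self.up.append(nn.ConvTranspose2d(cur, ch, rng))
            self.up_bn.append(nn.BatchNorm2d(ch, rng))
            cur = ch * 2  # after skip concatenation
        self.final = nn.ConvTranspose2d(cur, 3, rng)

    def params(self):
        ps = []
        for layer in self.down + self.up + [self.final]:
            ps.extend(layer.params())
        for bn in self.down_bn + self.up_bn:
            if bn is not None:
                ps.extend(bn.params())
        return ps

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        h = x
        for i, conv in enumerate(self.down):
            h = conv(h)
            if self.down_bn[i] is not None:
                h = self.down_bn[i](h)
            h = nn.leaky_relu(h)
            skips.append(h)
        h = skips[-1]
        for j, convt in enumerate(self.up):
            h = convt(h)
            h = self.up_bn[j](h)
            h = nn.relu(h)
            h = nn.concat(h, skips[self.depth - 2 - j])
        return nn.tanh(self.final(h))


class PatchDiscriminator:
    """PatchGAN on concatenated (input, map) pairs; outputs a logit map."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        bc = config.base_channels
        self.c1 = nn.Conv2d(6, bc, rng)                       # /2
        self.c2 = nn.Conv2d(bc, bc * 2, rng)                  # /4
        self.bn2 = nn.BatchNorm2d(bc * 2, rng)
        self.c3 = nn.Conv2d(bc * 2, bc * 4, rng, stride=1)    # receptive ~ 34 px
        self.bn3 = nn.BatchNorm2d(bc * 4, rng)
        self.c4 = nn.Conv2d(bc * 4, 1, rng, stride=1)

    def params(self):
        ps = []
        for layer in (self.c1, self.c2, self.c3, self.c4, self.bn2, self.bn3):
            ps.extend(layer.params())
        return ps

    def __call__(self, x: nn.Tensor, y: nn.Tensor) -> nn.Tensor:
        h = nn.leaky_relu(self.c1(nn.concat(x, y)))
        h = nn.leaky_relu(self.bn2(self.c2(h)))
        h = nn.leaky_relu(self.bn3(self.c3(h)))
        return self.c4(h)


@dataclass
class TranslationModel:
    """Trained generator + discriminator with the full loss history."""

    generator: UNetGenerator
    discriminator: PatchDiscriminator
    config: GanConfig
    history: dict[str, list[float]] = field(default_factory=dict)


def build_generator(config: GanConfig) -> UNetGenerator:
    """Seeded generator; identical seeds give identical initial parameters."""
    config.validate()
    return UNetGenerator(config, np.random.default_rng([config.seed, 1]))


def build_discriminator(config: GanConfig) -> PatchDiscriminator:
    config.validate()
    return PatchDiscriminator(config, np.random.default_rng([config.seed, 2]))


def _to_unit(pixels: np.ndarray) -> np.ndarray:
    """uint8 RGB -> float32 in [-1, 1], NCHW."""
    return (pixels.astype(np.float32) / 127.5 - 1.0).transpose(2, 0, 1)


def train(pairs: list[TilePair], config: GanConfig | None = None) -> TranslationModel:
    """Train the translation model on (image tile, label tile) pairs.

    Label tiles are rendered to their palette colors (with ZM subclasses
    where posterization was applied) and serve as the regression and
    adversarial targets.  Deterministic for a fixed seed and input order on
    one BLAS thread; raises on an empty training set or non-finite loss.
    """
    config = config or GanConfig()
    config.validate()
    if not pairs:
        raise ValueError("empty training set")
    for t in pairs:
        if t.size != config.tile_size:
            raise ValueError(f"tile size {t.size} != configured {config.tile_size}")

    x_all = np.stack([_to_unit(t.image_tile.pixels) for t in pairs])
    y_all = np.stack([_to_unit(encode_labels(t.label_tile)) for t in pairs])

    gen = build_generator(config)
    dis = build_discriminator(config)
    opt_g = nn.Adam(gen.params(), lr=config.learning_rate, beta1=config.beta1)
    opt_d = nn.Adam(dis.params(), lr=config.learning_rate, beta1=config.beta1)
    shuffle_rng = np.random.default_rng([config.seed, 3])

    history = {"d_loss": [], "g_adv": [], "g_l1": [], "g_total": []}
    n = len(pairs)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        ep = {k: 0.0 for k in history}
        n_batches = 0
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            x = nn.Tensor(x_all[idx])
            y = nn.Tensor(y_all[idx])

            fake = gen(x)

            # discriminator step: real pairs -> 1, translated pairs -> 0
            d_real = dis(x, y)
            d_fake = dis(x, fake.detach())
            loss_d = nn.scale(
                nn.add(nn.bce_with_logits(d_real, 1.0), nn.bce_with_logits(d_fake, 0.0)),
                0.5,
            )
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()

            # generator step: fool the discriminator + weighted L1 to target
            d_fake2 = dis(x, fake)
            g_adv = nn.bce_with_logits(d_fake2, 1.0)
            g_l1 = nn.l1_loss(fake, y.data)
            loss_g = nn.add(g_adv, nn.scale(g_l1, config.lambda_l1))
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard D's gradients from the G pass
            loss_g.backward()
            opt_g.step()

            vals = {
                "d_loss": float(loss_d.data), "g_adv": float(g_adv.data),
                "g_l1": float(g_l1.data), "g_total": float(loss_g.data),
            }
            for k, v in vals.items():
                if not np.isfinite(v):
                    raise FloatingPointError(
                        f"non-finite {k} at epoch {epoch}, batch {n_batches}"
                    )
                ep[k] += v
            n_batches += 1
        for k in history:
            history[k].append(ep[k] / max(n_batches, 1))
        logger.info(
            "epoch %d/%d d=%.4f g_adv=%.4f g_l1=%.4f", epoch + 1, config.epochs,
            history["d_loss"][-1], history["g_adv"][-1], history["g_l1"][-1],
        )
    return TranslationModel(gen, dis, config, history)


def translate(
    model: TranslationModel, image: OrthoImage, tile_size: int | None = None,
    batch_size: int = 8,
) -> LabelMap:
    """Translate a whole image into a five-class label map.

    Slices the image into tiles, runs the generator, decodes every output
    pixel to the nearest palette color, merges ZM subclasses, and
    reassembles.  The output covers the cropped extent
    (floor(H/T) x floor(W/T) tiles).
    """
    t = tile_size or model.config.tile_size
    if t != model.config.tile_size:
        raise ValueError(
            f"tile size {t} does not match the model's {model.config.tile_size}"
        )
    from .scene_sim import ScenePair  # local: only for slice_tiles' interface

    dummy = LabelMap(np.zeros(image.shape, dtype=np.uint8))
    scene = ScenePair.__new__(ScenePair)
    scene.image, scene.truth = image, dummy
    tiles = slice_tiles(scene, t, region="validation")
    if not tiles:
        raise ValueError("image smaller than one tile")
    out = []
    for start in range(0, len(tiles), batch_size):
        batch = tiles[start:start + batch_size]
        x = nn.Tensor(np.stack([_to_unit(b.image_tile.pixels) for b in batch]))
        y = model.generator(x).data  # (N,3,T,T) in [-1,1]
        rgb = ((y.transpose(0, 2, 3, 1) + 1.0) * 127.5).clip(0, 255)
        for b, r in zip(batch, rgb):
            lab = LabelMap(nearest_class_indices(r, ALL_LABELS))
            out.append((b.grid_row, b.grid_col, merge_subclasses(lab)))
    h, w = image.shape
    return reassemble(out, (h // t, w // t))
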