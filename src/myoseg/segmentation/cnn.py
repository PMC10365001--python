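"""Supervised U-Net muscle segmenter trained with a patch-adversarial loss
on (image, mask) pairs — the pix2pix recipe adapted to binary segmentation.

The segmentation term is pixelwise binary cross-entropy on the U-Net
logits; the adversarial term scores the (image, predicted-mask) pair with a
patch discriminator in least-squares form.  The discriminator sees real
pairs (image, ground-truth mask) against fake pairs (image, predicted
probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..augment import sample_batch
from ..nn import Adam, UNet, patch_discriminator


@dataclass
class CNNConfig:
    epochs: int = 20
    learning_rate: float = 2e-4
    batch_size: int = 4
    base_channels: int = 8
    depth: int = 2
    disc_channels: int = 8
    disc_layers: int = 2
    adv_weight: float = 0.05
    image_pad_to: int = 72
    crop_size: int = 64
    seed: int = 0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class CNNSegmenter:
    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.net = UNet(in_ch=1, out_ch=1, base=cfg.base_channels,
                        depth=cfg.depth, rng=rng)
        self.disc = patch_discriminator(in_ch=2, base=cfg.disc_channels,
                                        n_layers=cfg.disc_layers, rng=rng)
        self.loss_history: list[dict] = []

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Binary muscle mask for one [0,1] image (probability > 0.5)."""
        img = np.asarray(image, dtype=np.float32)
        h, w = img.shape
        mult = 2 ** self.cfg.depth
        ph = (-h) % mult
        pw = (-w) % mult
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
        x = img[None, None] * 2.0 - 1.0
        logits, _ = self.net.forward(x)
        prob = _sigmoid(logits[0, 0, :h, :w].astype(np.float64))
        return prob > 0.5


def train_cnn_segmenter(images, masks, cfg: CNNConfig | None = None) -> CNNSegmenter:
    """Train the adversarial U-Net segmenter on paired images and masks."""
    if len(images) == 0:
        raise ValueError("empty training set")
    cfg = cfg or CNNConfig()
    model = CNNSegmenter(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt_g = Adam(model.net.params(), lr=cfg.learning_rate)
    opt_d = Adam(model.disc.params(), lr=cfg.learning_rate)
    imgs = [np.asarray(im, dtype=np.float32) for im in images]
    msks = [np.asarray(m, dtype=np.float32) for m in masks]
    steps = max(1, len(imgs) // cfg.batch_size)

    for epoch in range(cfg.epochs):
        seg_sum = adv_sum = d_sum = 0.0
        for _ in range(steps):
            x01, m = sample_batch(imgs, rng, cfg.batch_size,
                                  cfg.image_pad_to, cfg.crop_size, masks=msks)
            x = x01 * 2.0 - 1.0
            n = m.size

            logits, cache_g = model.net.forward(x)
            prob = _sigmoid(logits)
            # bce with logits, mean over pixels and batch
            seg = float(np.mean(np.maximum(logits, 0) - logits * m
                                + np.log1p(np.exp(-np.abs(logits)))))
            d_logits = (prob - m) / n

            pair_fake = np.concatenate([x, prob], axis=1).astype(np.float32)
            df, cache_df = model.disc.forward(pair_fake)
            adv = float(np.mean((df - 1.0) ** 2))
            opt_d.zero_grad()
            d_pair = model.disc.backward(
                (cfg.adv_weight * 2.0 * (df - 1.0) / df.size).astype(np.float32),
                cache_df)
            d_prob = d_pair[:, 1:2] * (prob * (1.0 - prob))
            opt_g.zero_grad()
            model.net.backward((d_logits + d_prob).astype(np.float32), cache_g)
            opt_g.step()

            # discriminator update on detached predictions
            opt_d.zero_grad()
            dr, cache_dr = model.disc.forward(
                np.concatenate([x, m], axis=1).astype(np.float32))
            df2, cache_df2 = model.disc.forward(pair_fake)
            d_loss = 0.5 * float(np.mean((dr - 1.0) ** 2) + np.mean(df2 ** 2))
            model.disc.backward(((dr - 1.0) / dr.size).astype(np.float32), cache_dr)
            model.disc.backward((df2 / df2.size).astype(np.float32), cache_df2)
            opt_d.step()

            if not np.isfinite(seg):
                raise RuntimeError(f"non-finite segmentation loss at epoch {epoch}")
            seg_sum += seg
            adv_sum += adv
            d_sum += d_loss
        model.loss_history.append({"epoch": epoch, "seg": seg_sum / steps,
                                   "adv": adv_sum / steps, "disc": d_sum / steps})
    return model
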