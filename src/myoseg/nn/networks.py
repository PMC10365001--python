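"""Network architectures: residual generator, patch discriminator, U-Net.

The generator follows the familiar residual encoder/transformer/decoder
recipe for unpaired translation (c7s1 stem, strided-conv downsampling,
residual blocks, nearest-upsample + conv decoding, tanh output on the
[-1, 1] internal scale).  The discriminator is a patch-level CNN emitting a
score map rather than a single scalar.  The U-Net is a small
encoder-decoder with skip connections used by the supervised segmenter.
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2x, Conv2d, InstanceNorm2d, Layer, LeakyReLU,
                     Param, ReLU, ResidualBlock, Sequential, Tanh, Upsample2x)


def resnet_generator(in_ch: int = 1, out_ch: int = 1, base: int = 8,
                     n_blocks: int = 2, n_down: int = 1,
                     rng: np.random.Generator | None = None) -> Sequential:
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [
        Conv2d(in_ch, base, 7, pad=3, pad_mode="reflect", rng=rng),
        InstanceNorm2d(base), ReLU(),
    ]
    ch = base
    for _ in range(n_down):
        layers += [Conv2d(ch, ch * 2, 3, stride=2, pad=1, rng=rng),
                   InstanceNorm2d(ch * 2), ReLU()]
        ch *= 2
    for _ in range(n_blocks):
        layers.append(ResidualBlock(ch, rng))
    for _ in range(n_down):
        layers += [Upsample2x(), Conv2d(ch, ch // 2, 3, pad=1, rng=rng),
                   InstanceNorm2d(ch // 2), ReLU()]
        ch //= 2
    layers += [Conv2d(ch, out_ch, 7, pad=3, pad_mode="reflect", rng=rng), Tanh()]
    return Sequential(*layers)


def patch_discriminator(in_ch: int = 1, base: int = 8, n_layers: int = 2,
                        rng: np.random.Generator | None = None) -> Sequential:
    """Patch CNN scoring local realness; raw (un-squashed) score map output."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [Conv2d(in_ch, base, 4, stride=2, pad=1, rng=rng),
                           LeakyReLU(0.2)]
    ch = base
    for _ in range(n_layers - 1):
        layers += [Conv2d(ch, ch * 2, 4, stride=2, pad=1, rng=rng),
                   InstanceNorm2d(ch * 2), LeakyReLU(0.2)]
        ch *= 2
    layers += [Conv2d(ch, ch * 2, 4, stride=1, pad=1, rng=rng),
               InstanceNorm2d(ch * 2), LeakyReLU(0.2),
               Conv2d(ch * 2, 1, 4, stride=1, pad=1, rng=rng)]
    return Sequential(*layers)


class UNet(Layer):
    """Small U-Net with ``depth`` pooling stages and skip connections.

    Emits logits; the caller applies a sigmoid / threshold.
    """

    def __init__(self, in_ch: int = 1, out_ch: int = 1, base: int = 8,
                 depth: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.depth = depth

        def block(ci, co):
            return Sequential(Conv2d(ci, co, 3, pad=1, rng=rng), InstanceNorm2d(co), ReLU(),
                              Conv2d(co, co, 3, pad=1, rng=rng), InstanceNorm2d(co), ReLU())

        self.enc = []
        ch = in_ch
        f = base
        for _ in range(depth):
            self.enc.append(block(ch, f))
            ch, f = f, f * 2
        self.pool = AvgPool2x()
        self.bottom = block(ch, f)
        self.up: list[Upsample2x] = []
        self.upconv: list[Sequential] = []
        self.dec: list[Sequential] = []
        for _ in range(depth):
            self.up.append(Upsample2x())
            self.upconv.append(Sequential(Conv2d(f, f // 2, 3, pad=1, rng=rng),
                                          InstanceNorm2d(f // 2), ReLU()))
            self.dec.append(block(f, f // 2))  # input = skip (f//2) + up (f//2)
            f //= 2
        self.head = Conv2d(f, out_ch, 1, rng=rng)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.enc:
            out += b.params()
        out += self.bottom.params()
        for uc, d in zip(self.upconv, self.dec):
            out += uc.params() + d.params()
        out += self.head.params()
        return out

    def forward(self, x):
        caches = {"enc": [], "pool": [], "up": [], "upconv": [], "dec": []}
        skips = []
        for b in self.enc:
            x, c = b.forward(x)
            caches["enc"].append(c)
            skips.append(x)
            x, c = self.pool.forward(x)
            caches["pool"].append(c)
        x, caches["bottom"] = self.bottom.forward(x)
        for i in range(self.depth):
            x, c = self.up[i].forward(x)
            caches["up"].append(c)
            x, c = self.upconv[i].forward(x)
            caches["upconv"].append(c)
            skip = skips[self.depth - 1 - i]
            x = np.concatenate([skip, x], axis=1)
            x, c = self.dec[i].forward(x)
            caches["dec"].append(c)
        y, caches["head"] = self.head.forward(x)
        return y, caches

    def backward(self, dy, caches):
        dx = self.head.backward(dy, caches["head"])
        dskips = []
        for i in reversed(range(self.depth)):
            dx = self.dec[i].backward(dx, caches["dec"][i])
            half = dx.shape[1] // 2
            dskips.append(dx[:, :half])
            dx = self.upconv[i].backward(dx[:, half:], caches["upconv"][i])
            dx = self.up[i].backward(dx, caches["up"][i])
        dx = self.bottom.backward(dx, caches["bottom"])
        for i in reversed(range(self.depth)):
            dx = self.pool.backward(dx, caches["pool"][i])
            dx = dx + dskips[i]  # dskips[k] pairs with skips[k] by construction
            dx = self.enc[i].backward(dx, caches["enc"][i])
        return dx
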