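"""Shared training-time augmentation: random crops from reflect-padded
images, rotations by multiples of 90 degrees, and flips."""

from __future__ import annotations

import numpy as np


def augment_pair(image: np.ndarray, mask: np.ndarray | None,
                 rng: np.random.Generator, pad_to: int, crop_size: int):
    """Jointly augment an image and (optionally) its mask.

    The image is reflect-padded to ``pad_to`` per side, a ``crop_size``
    square is cropped at a random position, then rotated by a random
    multiple of 90 degrees and randomly flipped.
    """
    h, w = image.shape
    ph, pw = max(pad_to - h, 0), max(pad_to - w, 0)
    spec = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))

    def prep(arr):
        return np.pad(arr, spec, mode="reflect") if (ph or pw) else arr

    img = prep(image)
    msk = prep(mask) if mask is not None else None
    hh, ww = img.shape
    top = int(rng.integers(0, hh - crop_size + 1))
    left = int(rng.integers(0, ww - crop_size + 1))
    k = int(rng.integers(0, 4))
    fv = bool(rng.integers(0, 2))
    fh = bool(rng.integers(0, 2))

    def cut(arr):
        a = arr[top:top + crop_size, left:left + crop_size]
        a = np.rot90(a, k)
        if fv:
            a = a[::-1, :]
        if fh:
            a = a[:, ::-1]
        return np.ascontiguousarray(a)

    return (cut(img), cut(msk)) if msk is not None else (cut(img), None)


def sample_batch(images, rng: np.random.Generator, batch_size: int,
                 pad_to: int, crop_size: int, masks=None):
    """Sample an augmented (N, 1, H, W) batch (and mask batch if given)."""
    idx = rng.integers(0, len(images), size=batch_size)
    imgs, msks = [], []
    for i in idx:
        im, mk = augment_pair(images[i], None if masks is None else masks[i],
                              rng, pad_to, crop_size)
        imgs.append(im)
        if masks is not None:
            msks.append(mk)
    x = np.stack(imgs)[:, None].astype(np.float32)
    if masks is None:
        return x
    return x, np.stack(msks)[:, None].astype(np.float32)
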