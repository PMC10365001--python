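"""Statistical shape prior: a per-pixel muscle probability map built from
training masks after moment-based similarity alignment.

Alignment uses only mask moments — centroid for translation, principal-axis
orientation for rotation, and root-area for isotropic scale — which is
deterministic and adequate for convex, thigh-like shapes.  At test time the
prior is registered onto a new image using the same transform computed from
an initial (e.g. GMM) segmentation of that image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image


@dataclass
class MomentFrame:
    """Similarity frame of a binary mask: centroid (row, col), angle, scale."""
    centroid: tuple[float, float]
    angle: float
    scale: float


@dataclass
class ShapePrior:
    prob_map: np.ndarray        # in [0, 1], in the reference frame
    reference_frame: MomentFrame


def mask_frame(mask: np.ndarray, hull: bool = True) -> MomentFrame:
    """Moment frame of a binary mask; angle is 0 for near-isotropic masks.

    Moments are computed on the convex hull by default: frames should
    describe a shape's extent, and initialization masks of infiltrated
    muscle are riddled with holes that would otherwise shrink the scale
    estimate and mis-place the registered prior.
    """
    m = np.asarray(mask, dtype=bool)
    if hull and m.any():
        m = convex_hull_image(m)
    area = float(m.sum())
    if area == 0:
        raise ValueError("empty mask")
    ys, xs = np.nonzero(m)
    cy, cx = float(ys.mean()), float(xs.mean())
    dy, dx = ys - cy, xs - cx
    mu20 = float((dy * dy).mean())
    mu02 = float((dx * dx).mean())
    mu11 = float((dy * dx).mean())
    aniso = (mu20 - mu02) ** 2 + 4.0 * mu11 ** 2
    if aniso < 1e-3 * (mu20 + mu02) ** 2:
        angle = 0.0
    else:
        angle = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return MomentFrame((cy, cx), angle, np.sqrt(area))


def _wrap_half_pi(a: float) -> float:
    """Wrap an angle difference into [-pi/2, pi/2) (axis ambiguity)."""
    return (a + np.pi / 2) % np.pi - np.pi / 2


def warp_between(src_frame: MomentFrame, dst_frame: MomentFrame,
                 values: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resample ``values`` (living in ``src_frame``) onto ``dst_frame``.

    For each output pixel y in the destination frame, the source point is
    c_src + s * R(dtheta) (y - c_dst) with s = scale_src / scale_dst.
    """
    dtheta = _wrap_half_pi(src_frame.angle - dst_frame.angle)
    s = src_frame.scale / dst_frame.scale
    c, sn = np.cos(dtheta), np.sin(dtheta)
    mat = s * np.array([[c, -sn], [sn, c]])
    offset = np.asarray(src_frame.centroid) - mat @ np.asarray(dst_frame.centroid)
    return ndimage.affine_transform(
        np.asarray(values, dtype=np.float64), mat, offset=offset,
        output_shape=out_shape, order=1, mode="constant", cval=0.0)


def build_shape_prior(training_masks) -> ShapePrior:
    """Mean of training masks after alignment to the first mask's frame."""
    masks = [np.asarray(m, dtype=bool) for m in training_masks]
    if len(masks) < 2:
        raise ValueError("need at least two training masks")
    ref = mask_frame(masks[0])
    shape = masks[0].shape
    acc = np.zeros(shape, dtype=np.float64)
    for m in masks:
        acc += warp_between(mask_frame(m), ref, m.astype(np.float64), shape)
    return ShapePrior(prob_map=np.clip(acc / len(masks), 0.0, 1.0),
                      reference_frame=ref)


def register_prior(prior: ShapePrior, init_mask: np.ndarray) -> np.ndarray:
    """Register the prior map onto a test image via its initial segmentation.

    ``init_mask`` is a rough muscle mask of the test image (in practice the
    GMM output); its moment frame carries the prior into image coordinates.
    """
    dst = mask_frame(init_mask)
    warped = warp_between(prior.reference_frame, dst, prior.prob_map,
                          np.asarray(init_mask).shape)
    return np.clip(warped, 0.0, 1.0)
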