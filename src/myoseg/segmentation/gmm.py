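"""Unsupervised three-class Gaussian-mixture muscle segmentation.

The mixture separates muscle, fat, and bone/vessels inside the body
foreground.  Initial component centers are pinned to the observed gray-value
range: the minimum, the maximum, and a point one sixth of the range above
the minimum — the low middle center encodes that muscle is only slightly
brighter than the darkest tissue while fat sits at the top of the range.
The muscle mask is the set of foreground pixels assigned to the component
whose converged mean lies closest to that initial middle center.

This segmenter needs no training data, which is exactly why it fails on
fat-infiltrated muscle: infiltration shares the fat gray level and is
assigned to the fat component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture


class DegenerateImageError(ValueError):
    """Raised when an image has too few distinct gray values to cluster."""


@dataclass
class GMMParams:
    n_components: int = 3
    max_iter: int = 100
    tol: float = 1e-4


def gmm_init_centers(image: np.ndarray) -> tuple[float, float, float]:
    """Fixed initial centers (s_min, s_min + (s_max - s_min)/6, s_max)."""
    s_min = float(np.min(image))
    s_max = float(np.max(image))
    if s_min == s_max:
        raise DegenerateImageError("constant image: no gray-value range")
    return s_min, s_min + (s_max - s_min) / 6.0, s_max


def body_foreground_mask(image: np.ndarray) -> np.ndarray:
    """Separate the body from the dark background.

    Threshold at the midpoint of a two-class k-means on intensities, keep the
    largest connected component, and fill interior holes (the dark bone).
    """
    vals = np.asarray(image, dtype=np.float64).reshape(-1, 1)
    if vals.min() == vals.max():
        raise DegenerateImageError("constant image: no foreground/background split")
    init = np.array([[vals.min()], [vals.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=50).fit(vals)
    thr = float(km.cluster_centers_.mean())
    fg = image > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise DegenerateImageError("no foreground found")
    sizes = ndimage.sum(fg, labels, index=range(1, n + 1))
    fg = labels == (1 + int(np.argmax(sizes)))
    # the thigh cross-section is convex: the hull recovers the interior even
    # when the bright rim is interrupted (fill_holes alone would not)
    return convex_hull_image(fg)


def gmm_segment(image: np.ndarray, params: GMMParams | None = None,
                foreground: np.ndarray | None = None) -> np.ndarray:
    """Segment muscle by a 3-component spherical GMM inside the foreground.

    Returns a binary mask (True = muscle) of the image's shape.
    """
    params = params or GMMParams()
    if foreground is None:
        foreground = body_foreground_mask(image)
    vals = np.asarray(image, dtype=np.float64)[foreground]
    if np.unique(vals).size < params.n_components:
        raise DegenerateImageError("fewer distinct gray values than components")
    c_low, c_mid, c_high = gmm_init_centers(vals)
    var0 = ((c_high - c_low) / 10.0) ** 2
    gm = GaussianMixture(
        n_components=params.n_components,
        covariance_type="spherical",
        means_init=np.array([[c_low], [c_mid], [c_high]]),
        precisions_init=np.full(params.n_components, 1.0 / var0),
        weights_init=np.full(params.n_components, 1.0 / params.n_components),
        max_iter=params.max_iter,
        tol=params.tol,
        reg_covar=1e-8,
    )
    gm.fit(vals.reshape(-1, 1))
    # muscle is the middle of the three converged means: bone/vessels sit at
    # the dark end, fat at the bright end (selection by rank is stable even
    # when noise drags the observed minimum well below the bone level)
    muscle_comp = int(np.argsort(gm.means_.ravel())[1])
    assign = gm.predict(vals.reshape(-1, 1))
    mask = np.zeros(image.shape, dtype=bool)
    mask[foreground] = assign == muscle_comp
    return mask
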