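"""Probabilistic graph-cut segmentation, optionally with a statistical
shape prior.

Energy minimized exactly by an s-t min-cut on the 4-connected pixel grid:

    E(L) = sum_p U_p(L_p)
         + lambda_s * sum_{(p,q) in N4} [L_p != L_q] * exp(-(I_p - I_q)^2 / (2 beta))

where the unary U_p is the negative log-likelihood of the observed
intensity under a per-label appearance model (plain graph-cut), or of a
blend of that likelihood with a registered per-pixel shape probability
(shape-prior graph-cut).  ``beta`` is the mean squared 4-neighbour gradient
of the (Gaussian-smoothed) image, the standard contrast estimator.  The cut
is computed with scipy's max-flow on integer-scaled capacities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow

EPS_PROB = 1e-6


@dataclass
class GraphCutParams:
    lambda_s: float = 0.1   # smoothness ("curvature") weight
    sigma: float = 1.0      # Gaussian low-pass width in pixels

    def __post_init__(self):
        if self.lambda_s < 0 or self.sigma < 0:
            raise ValueError("lambda_s and sigma must be non-negative")


@dataclass
class SPGCParams:
    lambda_sp: float = 0.5  # shape-prior weight in the unary blend
    p_n: float = 0.3        # neutral probability floor for the prior
    gc: GraphCutParams = field(default_factory=GraphCutParams)

    def __post_init__(self):
        if not 0.0 < self.p_n < 1.0:
            raise ValueError("p_n must lie in (0, 1)")
        if not 0.0 <= self.lambda_sp <= 1.0:
            raise ValueError("lambda_sp must lie in [0, 1]")


class AppearanceModel:
    """Histogram intensity likelihoods for muscle vs non-muscle.

    Per-label histograms over [0, 1] normalized to sum 1 and floored at a
    small epsilon so log-likelihoods stay finite.
    """

    def __init__(self, n_bins: int = 64):
        self.n_bins = n_bins
        self.hist = {}  # label -> (n_bins,) probabilities

    def fit(self, images, masks) -> "AppearanceModel":
        muscle_vals, other_vals = [], []
        for img, msk in zip(images, masks):
            img = np.asarray(img, dtype=np.float64)
            msk = np.asarray(msk, dtype=bool)
            muscle_vals.append(img[msk])
            other_vals.append(img[~msk])
        for label, vals in ((1, np.concatenate(muscle_vals)),
                            (0, np.concatenate(other_vals))):
            if vals.size == 0:
                raise ValueError(f"no labeled pixels for class {label}")
            h, _ = np.histogram(vals, bins=self.n_bins, range=(0.0, 1.0))
            p = h.astype(np.float64) + EPS_PROB
            self.hist[label] = p / p.sum()
        return self

    def log_likelihood(self, image: np.ndarray, label: int) -> np.ndarray:
        idx = np.clip((np.asarray(image) * self.n_bins).astype(int), 0, self.n_bins - 1)
        return np.log(self.hist[label][idx])

    def probability(self, image: np.ndarray, label: int) -> np.ndarray:
        idx = np.clip((np.asarray(image) * self.n_bins).astype(int), 0, self.n_bins - 1)
        return self.hist[label][idx]


def fit_appearance_model(images, masks, n_bins: int = 64) -> AppearanceModel:
    """Estimate per-label intensity likelihoods from annotated slices."""
    return AppearanceModel(n_bins=n_bins).fit(images, masks)


def _pairwise_weights(smoothed: np.ndarray):
    """Contrast-sensitive Potts weights for vertical/horizontal N4 edges."""
    dv = smoothed[1:, :] - smoothed[:-1, :]
    dh = smoothed[:, 1:] - smoothed[:, :-1]
    beta = float(np.mean(np.concatenate([dv.ravel() ** 2, dh.ravel() ** 2])))
    beta = max(beta, 1e-12)
    wv = np.exp(-(dv ** 2) / (2.0 * beta))
    wh = np.exp(-(dh ** 2) / (2.0 * beta))
    return wv, wh


def _min_cut_labeling(u0: np.ndarray, u1: np.ndarray, lambda_s: float,
                      wv: np.ndarray, wh: np.ndarray) -> np.ndarray:
    """Exact binary labeling minimizing unary + Potts energy.

    ``u0``/``u1`` are the costs of labeling a pixel 0 (non-muscle) or 1
    (muscle).  Label 1 corresponds to the source side of the cut.
    """
    h, w = u0.shape
    n = h * w
    src, snk = n, n + 1
    idx = np.arange(n).reshape(h, w)

    rows, cols, caps = [], [], []

    def add(r, c, cap):
        rows.append(r)
        cols.append(c)
        caps.append(cap)

    # t-links: cutting src->p pays u0 (p gets label 0); p->snk pays u1
    add(np.full(n, src), idx.ravel(), u0.ravel())
    add(idx.ravel(), np.full(n, snk), u1.ravel())
    if lambda_s > 0:
        pv, qv = idx[:-1, :].ravel(), idx[1:, :].ravel()
        cv = lambda_s * wv.ravel()
        add(pv, qv, cv)
        add(qv, pv, cv)
        ph, qh = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        ch = lambda_s * wh.ravel()
        add(ph, qh, ch)
        add(qh, ph, ch)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps_f = np.concatenate(caps)
    # scipy's max-flow works on int32 capacities; scale so that both every
    # arc capacity and an upper bound on the total flow stay below 2^31
    pair_sum = lambda_s * (float(wv.sum()) + float(wh.sum()))
    flow_bound = min(float(u0.sum()), float(u1.sum())) + 2.0 * pair_sum
    limit = max(flow_bound, float(caps_f.max(initial=0.0)), 1e-12)
    scale = 1.0e9 / limit
    caps_i = np.round(caps_f * scale).astype(np.int32)
    graph = csr_matrix((caps_i, (rows, cols)), shape=(n + 2, n + 2))
    res = maximum_flow(graph, src, snk)

    # source side of the residual graph = label 1
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = np.zeros(n + 2, dtype=bool)
    stack = [src]
    reach[src] = True
    indptr, indices, data = residual.indptr, residual.indices, residual.data
    while stack:
        v = stack.pop()
        for k in range(indptr[v], indptr[v + 1]):
            if data[k] > 0 and not reach[indices[k]]:
                reach[indices[k]] = True
                stack.append(indices[k])
    return reach[:n].reshape(h, w)


def labeling_energy(image: np.ndarray, labels: np.ndarray, u0: np.ndarray,
                    u1: np.ndarray, lambda_s: float, wv: np.ndarray,
                    wh: np.ndarray) -> float:
    """Float energy of an arbitrary labeling under the graph-cut objective."""
    lab = labels.astype(bool)
    e = float(np.where(lab, u1, u0).sum())
    e += lambda_s * float((wv * (lab[1:, :] != lab[:-1, :])).sum())
    e += lambda_s * float((wh * (lab[:, 1:] != lab[:, :-1])).sum())
    return e


def _gc_unaries(image: np.ndarray, model: AppearanceModel, sigma: float):
    smoothed = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma) \
        if sigma > 0 else np.asarray(image, dtype=np.float64)
    u0 = -model.log_likelihood(smoothed, 0)
    u1 = -model.log_likelihood(smoothed, 1)
    return smoothed, u0, u1


def gc_energy_terms(image: np.ndarray, model: AppearanceModel,
                    params: GraphCutParams):
    """(u0, u1, wv, wh) of the plain graph-cut energy, for independent
    energy recomputation."""
    smoothed, u0, u1 = _gc_unaries(image, model, params.sigma)
    wv, wh = _pairwise_weights(smoothed)
    return u0, u1, wv, wh


def spgc_energy_terms(image: np.ndarray, model: AppearanceModel,
                      prior_map: np.ndarray, params: SPGCParams):
    """(u0, u1, wv, wh) of the shape-prior graph-cut energy."""
    smoothed, u0, u1 = _spgc_unaries(image, model, prior_map, params)
    wv, wh = _pairwise_weights(smoothed)
    return u0, u1, wv, wh


def graph_cut_segment(image: np.ndarray, model: AppearanceModel,
                      params: GraphCutParams,
                      init: np.ndarray | None = None) -> np.ndarray:
    """Binary muscle segmentation by exact min-cut.

    ``init`` (e.g. a GMM mask) is accepted for interface compatibility; the
    energy itself does not depend on it.
    """
    smoothed, u0, u1 = _gc_unaries(image, model, params.sigma)
    if not (np.isfinite(u0).all() and np.isfinite(u1).all()):
        raise ValueError("non-finite unary costs")
    wv, wh = _pairwise_weights(smoothed)
    return _min_cut_labeling(u0, u1, params.lambda_s, wv, wh)


def _spgc_unaries(image: np.ndarray, model: AppearanceModel,
                  prior_map: np.ndarray, params: SPGCParams):
    smoothed, _, _ = _gc_unaries(image, model, params.gc.sigma)
    p_shape1 = params.p_n + (1.0 - params.p_n) * prior_map
    p_shape0 = 1.0 - p_shape1
    lam = params.lambda_sp
    b1 = (1.0 - lam) * model.probability(smoothed, 1) + lam * p_shape1
    b0 = (1.0 - lam) * model.probability(smoothed, 0) + lam * p_shape0
    # floor only guards log(0) for a degenerate {0,1} prior with lambda_sp=1;
    # it never binds for lambda_sp=0, keeping the reduction to plain GC exact
    u1 = -np.log(np.maximum(b1, 1e-30))
    u0 = -np.log(np.maximum(b0, 1e-30))
    return smoothed, u0, u1


def spgc_segment(image: np.ndarray, model: AppearanceModel,
                 prior_map: np.ndarray, params: SPGCParams) -> np.ndarray:
    """Graph-cut with shape-prior-blended unaries.

    ``prior_map`` must already be registered onto the image frame (see
    :mod:`myoseg.segmentation.shapeprior`).  With ``lambda_sp = 0`` this
    reduces exactly to :func:`graph_cut_segment`.
    """
    smoothed, u0, u1 = _spgc_unaries(image, model, prior_map, params)
    wv, wh = _pairwise_weights(smoothed)
    return _min_cut_labeling(u0, u1, params.gc.lambda_s, wv, wh)
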