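"""Graph-cut exactness against exhaustive enumeration, reductions, and the
shape-prior blend."""

import itertools

import numpy as np
import pytest

from myoseg import PhantomConfig, dice, generate_phantom_slice, sample_subject_geometry
from myoseg.segmentation import (AppearanceModel, GraphCutParams, SPGCParams,
                                 fit_appearance_model, gmm_segment,
                                 graph_cut_segment, labeling_energy,
                                 register_prior, spgc_segment)
from myoseg.segmentation.graphcut import gc_energy_terms, spgc_energy_terms

LAMBDA_S_GRID = [0.001, 0.002, 0.05, 0.1, 0.2, 0.5]


def _random_model(rng) -> AppearanceModel:
    imgs = [rng.uniform(0, 1, size=(6, 6)) for _ in range(2)]
    msks = [rng.uniform(size=(6, 6)) > 0.5 for _ in range(2)]
    msks[0][0, 0] = True
    msks[1][0, 0] = False   # both classes present
    return fit_appearance_model(imgs, msks, n_bins=16)


def _enumerate_min_energy(image, u0, u1, lam, wv, wh):
    h, w = image.shape
    best = np.inf
    for bits in itertools.product([0, 1], repeat=h * w):
        lab = np.array(bits, dtype=bool).reshape(h, w)
        best = min(best, labeling_energy(image, lab, u0, u1, lam, wv, wh))
    return best


@pytest.mark.parametrize("shape", [(3, 3), (3, 4)])
def test_graph_cut_energy_equals_enumeration(shape):
    """Min-cut energy matches brute force over all labelings, across the
    full smoothness grid, for plain and shape-prior unaries."""
    for inst in range(10):
        rng = np.random.default_rng(500 + inst)
        img = rng.uniform(0, 1, size=shape)
        model = _random_model(rng)
        prior = rng.uniform(0, 1, size=shape)
        for lam in LAMBDA_S_GRID:
            gc = GraphCutParams(lambda_s=lam, sigma=1.0)
            mask = graph_cut_segment(img, model, gc)
            u0, u1, wv, wh = gc_energy_terms(img, model, gc)
            e_cut = labeling_energy(img, mask, u0, u1, lam, wv, wh)
            e_min = _enumerate_min_energy(img, u0, u1, lam, wv, wh)
            assert e_cut == pytest.approx(e_min, abs=1e-6)

            sp = SPGCParams(lambda_sp=0.5, p_n=0.3, gc=gc)
            mask_sp = spgc_segment(img, model, prior, sp)
            u0s, u1s, wvs, whs = spgc_energy_terms(img, model, prior, sp)
            e_cut_sp = labeling_energy(img, mask_sp, u0s, u1s, lam, wvs, whs)
            e_min_sp = _enumerate_min_energy(img, u0s, u1s, lam, wvs, whs)
            assert e_cut_sp == pytest.approx(e_min_sp, abs=1e-6)


def test_lambda_zero_is_pixelwise_maximum_likelihood():
    rng = np.random.default_rng(4)
    for trial in range(10):
        img = rng.uniform(0, 1, size=(12, 12))
        model = _random_model(rng)
        gc = GraphCutParams(lambda_s=0.0, sigma=1.0)
        mask = graph_cut_segment(img, model, gc)
        u0, u1, _, _ = gc_energy_terms(img, model, gc)
        ml = u1 < u0  # ties go to non-muscle, as does the cut's source side
        tie = u1 == u0
        assert np.array_equal(mask[~tie], ml[~tie])


def test_spgc_lambda_zero_reduces_to_gc(small_datasets):
    easy, _ = small_datasets
    train = easy.slices[:6]
    model = fit_appearance_model([s.image for s in train],
                                 [s.muscle_mask for s in train])
    from myoseg.segmentation import build_shape_prior
    prior = build_shape_prior([s.muscle_mask for s in train])
    for s in easy.slices[6:10]:
        gc = GraphCutParams(lambda_s=0.1, sigma=1.0)
        init = gmm_segment(s.image)
        pmap = register_prior(prior, init)
        m_gc = graph_cut_segment(s.image, model, gc, init=init)
        m_sp = spgc_segment(s.image, model, pmap,
                            SPGCParams(lambda_sp=0.0, p_n=0.3, gc=gc))
        assert np.array_equal(m_gc, m_sp)


def test_spgc_prior_dominates_at_lambda_one():
    """lambda_sp = 1 with a {0,1} prior and lambda_s = 0 returns the prior."""
    rng = np.random.default_rng(11)
    img = rng.uniform(0, 1, size=(10, 10))
    model = _random_model(rng)
    prior = np.zeros((10, 10))
    prior[3:7, 2:8] = 1.0
    sp = SPGCParams(lambda_sp=1.0, p_n=0.3,
                    gc=GraphCutParams(lambda_s=0.0, sigma=0.0))
    mask = spgc_segment(img, model, prior, sp)
    assert np.array_equal(mask, prior > 0.5)


def test_smoothness_never_increases_boundary_length():
    rng = np.random.default_rng(21)
    img = rng.uniform(0, 1, size=(16, 16))
    model = _random_model(rng)

    def boundary_edges(mask):
        return int((mask[1:, :] != mask[:-1, :]).sum()
                   + (mask[:, 1:] != mask[:, :-1]).sum())

    lengths = []
    for lam in LAMBDA_S_GRID:
        mask = graph_cut_segment(img, model, GraphCutParams(lambda_s=lam, sigma=1.0))
        lengths.append(boundary_edges(mask))
    assert all(b <= a for a, b in zip(lengths, lengths[1:]))


def test_appearance_model_properties():
    rng = np.random.default_rng(2)
    img = np.concatenate([rng.normal(0.35, 0.03, 500),
                          rng.normal(0.85, 0.03, 500)]).reshape(25, 40)
    mask = np.zeros((25, 40), dtype=bool)
    mask.reshape(-1)[:500] = True
    model = fit_appearance_model([img], [mask])
    for label in (0, 1):
        assert model.hist[label].sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.hist[label] > 0).all()
    # likelihood ratio favors muscle at the muscle level
    p1 = model.probability(np.array([[0.35]]), 1)[0, 0]
    p0 = model.probability(np.array([[0.35]]), 0)[0, 0]
    assert p1 / p0 > 1.0
    with pytest.raises(ValueError):
        fit_appearance_model([img], [np.zeros((25, 40), dtype=bool)])


def test_spgc_recovers_infiltrated_muscle():
    """On a hard phantom where appearance mislabels infiltration as fat, the
    shape prior recovers strictly more infiltrated muscle pixels than GC."""
    cfg = PhantomConfig(seed=3)
    geo = sample_subject_geometry(cfg, np.random.default_rng(14))
    train = [generate_phantom_slice(PhantomConfig(seed=3), geo, s) for s in range(4)]
    hard = generate_phantom_slice(
        PhantomConfig(infiltration_fraction=0.5, seed=3), geo, 99)
    model = fit_appearance_model([s.image for s in train],
                                 [s.muscle_mask for s in train])
    from myoseg.segmentation import build_shape_prior
    prior = build_shape_prior([s.muscle_mask for s in train])
    gc = GraphCutParams(lambda_s=0.1, sigma=1.0)
    init = gmm_segment(hard.image)
    pmap = register_prior(prior, init)
    m_gc = graph_cut_segment(hard.image, model, gc, init=init)
    m_sp = spgc_segment(hard.image, model, pmap,
                        SPGCParams(lambda_sp=0.5, p_n=0.3, gc=gc))
    infil = hard.infiltration_mask
    assert (m_sp & infil).sum() > (m_gc & infil).sum()
    assert dice(m_sp, hard.muscle_mask) > dice(m_gc, hard.muscle_mask)
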