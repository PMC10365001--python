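"""Translation objectives against explicit-loop oracles and their laws."""

import numpy as np
import pytest

from myoseg.translation import (LossWeights, adversarial_losses,
                                cycle_consistency_loss, directional_relu_loss,
                                identity_loss, total_generator_objective)


def _loop_mean_abs(a, b):
    total, count = 0.0, 0
    for n in range(a.shape[0]):
        for i in range(a.shape[-2]):
            for j in range(a.shape[-1]):
                total += abs(float(a[n, ..., i, j]) - float(b[n, ..., i, j]))
                count += 1
    return total / count


def _loop_mean_relu(a):
    total, count = 0.0, 0
    for n in range(a.shape[0]):
        for i in range(a.shape[-2]):
            for j in range(a.shape[-1]):
                total += max(0.0, float(a[n, ..., i, j]))
                count += 1
    return total / count


def _random_maps(rng):
    """Random fixed 'generators' acting pixelwise on a batch."""
    dF = rng.normal(0, 0.2, size=(1, 4, 4))
    dG = rng.normal(0, 0.2, size=(1, 4, 4))
    return (lambda x: x + dF), (lambda x: x - dG)


@pytest.mark.parametrize("trial", range(50))
def test_losses_match_loop_oracles(trial):
    """Lc, Lr, Li and both adversarial objectives equal brute-force loops."""
    rng = np.random.default_rng(1000 + trial)
    e = rng.uniform(0, 1, size=(2, 4, 4))
    h = rng.uniform(0, 1, size=(2, 4, 4))
    F, G = _random_maps(rng)

    lc = cycle_consistency_loss(F, G, e, h)
    lc_ref = _loop_mean_abs(F(G(e)), e) + _loop_mean_abs(G(F(h)), h)
    assert lc == pytest.approx(lc_ref, abs=1e-6)

    li = identity_loss(F, G, e, h)
    li_ref = _loop_mean_abs(F(e), e) + _loop_mean_abs(G(h), h)
    assert li == pytest.approx(li_ref, abs=1e-6)

    lr = directional_relu_loss(F, G, e, h)
    lr_ref = _loop_mean_relu(F(h) - h) + _loop_mean_relu(e - G(e))
    assert lr == pytest.approx(lr_ref, abs=1e-6)

    # adversarial objectives with a fixed random patch scorer
    dh_map = rng.normal(0.5, 0.2, size=(2, 4, 4))
    de_map = rng.normal(0.5, 0.2, size=(2, 4, 4))
    D_H = lambda x: dh_map + 0.1 * x.mean()
    D_E = lambda x: de_map - 0.1 * x.mean()
    fake_h, fake_e = G(e), F(h)
    d_obj, g_adv = adversarial_losses(D_H, D_E, h, e, fake_h, fake_e)
    sh_r, sh_f = D_H(h), D_H(fake_h)
    se_r, se_f = D_E(e), D_E(fake_e)
    d_ref = (np.mean((sh_r - 1) ** 2) + np.mean(sh_f ** 2)
             + np.mean((se_r - 1) ** 2) + np.mean(se_f ** 2))
    g_ref = np.mean((sh_f - 1) ** 2) + np.mean((se_f - 1) ** 2)
    assert d_obj == pytest.approx(d_ref, abs=1e-6)
    assert g_adv == pytest.approx(g_ref, abs=1e-6)


def test_cycle_loss_worked_example():
    """1x2 image e=(0.2,0.6) reconstructed as (0.3,0.6), h term zero -> 0.05."""
    e = np.array([[[0.2, 0.6]]])
    h = np.array([[[0.6, 0.6]]])  # F is identity here, so the h term is 0
    F = lambda x: np.where(x.sum() < 1.0, x + 0.1 * np.array([[[1.0, 0.0]]]), x)
    # G(e) chosen so F(G(e)) = (0.3, 0.6); on hard images the cycle is exact
    G = lambda x: x
    assert cycle_consistency_loss(F, G, e, h) == pytest.approx(0.05)


def test_cycle_loss_perfect_inverses_and_permutation():
    rng = np.random.default_rng(0)
    e = rng.uniform(size=(3, 4, 4))
    h = rng.uniform(size=(3, 4, 4))
    ident = lambda x: x
    assert cycle_consistency_loss(ident, ident, e, h) == 0.0
    F, G = (lambda x: x + 0.05), (lambda x: x - 0.02)
    perm = [2, 0, 1]
    assert cycle_consistency_loss(F, G, e, h) == pytest.approx(
        cycle_consistency_loss(F, G, e[perm], h[perm]), abs=1e-12)


def test_identity_loss_examples():
    e = np.array([[[0.4]]])
    h = np.array([[[0.5]]])
    F = lambda x: np.full_like(x, 0.1)
    G = lambda x: x
    assert identity_loss(F, G, e, h) == pytest.approx(0.3)
    assert identity_loss(G, G, e, h) == 0.0
    assert identity_loss(F, G, e, h) > 0.0


def test_directional_loss_one_sided_laws():
    """Zero iff F never brightens hard pixels and G never darkens easy ones;
    invariant under common additive shifts; single-pixel worked example."""
    rng = np.random.default_rng(3)
    e = rng.uniform(size=(2, 4, 4))
    h = rng.uniform(size=(2, 4, 4))
    ident = lambda x: x
    assert directional_relu_loss(ident, ident, e, h) == 0.0

    darken = lambda x: x - rng.uniform(0, 0.5, size=x.shape)
    brighten = lambda x: x + rng.uniform(0, 0.5, size=x.shape)
    assert directional_relu_loss(darken, brighten, e, h) == 0.0

    h1 = np.array([[[0.5]]])
    e1 = np.array([[[0.0]]])
    F = lambda x: np.full_like(x, 0.8)
    G = lambda x: np.full_like(x, 0.0)
    assert directional_relu_loss(F, G, e1, h1) == pytest.approx(0.3)

    # additive shift applied to both the input and the mapped output
    F2 = lambda x: x + 0.2
    base = directional_relu_loss(F2, ident, e, h)
    shifted = directional_relu_loss(lambda x: (x - 5.0) + 0.2 + 5.0, ident, e, h)
    assert base == pytest.approx(shifted, abs=1e-12)

    # clamping F(h) to min(F(h), h) sends the hard term to exactly zero
    Fmin = lambda x: np.minimum(F2(x), x)
    assert directional_relu_loss(Fmin, ident, e, h) == 0.0


def test_adversarial_perfect_and_constant_scores():
    ones = lambda x: np.ones((1, 4, 4))
    zeros = lambda x: np.zeros((1, 4, 4))
    real = np.full((1, 4, 4), 0.5)
    fake = np.full((1, 4, 4), 0.5)

    class Split:
        """Scores 1 on the real batch, 0 on the fake batch (by identity)."""
        def __init__(self, real_ref):
            self.real_ref = real_ref
        def __call__(self, x):
            return np.ones_like(x) if x is self.real_ref else np.zeros_like(x)

    d_obj, _ = adversarial_losses(Split(real), Split(real), real, real, fake, fake)
    assert d_obj == 0.0

    half = lambda x: np.full((1, 4, 4), 0.5)
    d_obj, g_adv = adversarial_losses(half, half, real, real, fake, fake)
    assert d_obj == pytest.approx(4 * 0.25)     # 0.25 per term
    assert g_adv == pytest.approx(2 * 0.25)

    # generator term decreases as fakes push scores toward 1
    lo = lambda x: np.full((1, 4, 4), 0.2)
    hi = lambda x: np.full((1, 4, 4), 0.8)
    _, g_lo = adversarial_losses(lo, lo, real, real, fake, fake)
    _, g_hi = adversarial_losses(hi, hi, real, real, fake, fake)
    assert g_hi < g_lo


def test_total_objective_weighting_and_naming():
    w = LossWeights(1, 1, 0.5, 1)
    assert total_generator_objective(w, 0.2, 0.4, 0.1, 0.3) == pytest.approx(0.95)
    assert total_generator_objective(LossWeights(), 0, 0, 0, 0) == 0.0
    # weights (1,1,0,0): adversarial + cycle only
    assert total_generator_objective(LossWeights(1, 1, 0, 0), 0.3, 0.7, 9.9, 9.9) \
        == pytest.approx(1.0)
    # G_{n,m}: first index w_r, second w_i; w_d = w_c = 1
    cfgs = [(0, 0), (0, 1), (0.5, 1), (1, 1), (2, 1)]
    names = [LossWeights.config(*c).name for c in cfgs]
    assert names == ["G_{0,0}", "G_{0,1}", "G_{0.5,1}", "G_{1,1}", "G_{2,1}"]
    for (wr, wi), nm in zip(cfgs, names):
        cw = LossWeights.config(wr, wi)
        assert (cw.w_d, cw.w_c, cw.w_r, cw.w_i) == (1, 1, wr, wi)
    with pytest.raises(ValueError):
        LossWeights(w_r=-0.1)


def test_log_form_adversarial():
    """Logit scores: perfect separation drives the objective toward zero."""
    real = np.full((1, 2, 2), 0.5)
    fake = np.full((1, 2, 2), 0.5)
    big = lambda x: np.full((1, 2, 2), 50.0) if x is real else np.full((1, 2, 2), -50.0)
    d_obj, _ = adversarial_losses(big, big, real, real, fake, fake, form="log")
    assert d_obj == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        adversarial_losses(big, big, real, real, fake, fake, form="wgan")
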