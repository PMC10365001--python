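"""Unpaired cyclic image-to-image translation from the hard (fat-infiltrated)
to the easy (healthy-looking) domain.

Two generators are trained jointly — F mapping hard-domain images to the
easy domain and G mapping back — against per-domain patch discriminators,
under a weighted combination of four objectives:

* an adversarial term making translated images indistinguishable from real
  images of the target domain (least-squares form by default, with a
  logarithmic/cross-entropy alternative),
* a cycle-consistency term |F(G(e)) - e| + |G(F(h)) - h| (L1),
* a directional ReLU term  mean r(F(h) - h) + mean r(e - G(e)) with
  r(x) = max(0, x): translating hard -> easy may only darken voxels and
  easy -> hard may only brighten them, encoding that fatty infiltration is
  brighter than the healthy muscle it replaces,
* an identity term |F(e) - e| + |G(h) - h| keeping each generator
  near-identity on inputs already in its target domain (counteracting the
  global darkening pressure of the directional term).

Named weight configurations follow the G_{w_r, w_i} convention with the
adversarial and cycle weights fixed at 1.

Generators operate internally on the [-1, 1] scale (tanh output); all
external images are [0, 1].  The directional and identity losses are
computed on the internal scale — their semantics are preserved under the
affine rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import sample_batch
from .nn import Adam, Sequential, patch_discriminator, resnet_generator

# ---------------------------------------------------------------------------
# loss weights


@dataclass
class LossWeights:
    """Objective weights (w_d adversarial, w_c cycle, w_r directional,
    w_i identity).  Named configurations G_{n,m} fix w_d = w_c = 1 and set
    w_r = n, w_i = m."""

    w_d: float = 1.0
    w_c: float = 1.0
    w_r: float = 0.0
    w_i: float = 0.0

    def __post_init__(self):
        if min(self.w_d, self.w_c, self.w_r, self.w_i) < 0:
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def config(cls, w_r: float, w_i: float) -> "LossWeights":
        return cls(w_d=1.0, w_c=1.0, w_r=w_r, w_i=w_i)

    @property
    def name(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"
        return f"G_{{{fmt(self.w_r)},{fmt(self.w_i)}}}"


# ---------------------------------------------------------------------------
# loss functions (callable-based public surface; the trainer computes the
# same quantities inline on cached activations)


def _mean_abs(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(a, dtype=np.float64) - b)))


def cycle_consistency_loss(F, G, e_batch, h_batch) -> float:
    """L1 reconstruction error of both round trips, mean over pixels/batch."""
    e = np.asarray(e_batch, dtype=np.float64)
    h = np.asarray(h_batch, dtype=np.float64)
    if e.size == 0 or h.size == 0:
        raise ValueError("batches must be non-empty")
    return _mean_abs(F(G(e)), e) + _mean_abs(G(F(h)), h)


def identity_loss(F, G, e_batch, h_batch) -> float:
    """L1 deviation of F from identity on easy inputs and G on hard inputs."""
    e = np.asarray(e_batch, dtype=np.float64)
    h = np.asarray(h_batch, dtype=np.float64)
    return _mean_abs(F(e), e) + _mean_abs(G(h), h)


def directional_relu_loss(F, G, e_batch, h_batch) -> float:
    """One-sided intensity penalty: mean r(F(h) - h) + mean r(e - G(e))."""
    e = np.asarray(e_batch, dtype=np.float64)
    h = np.asarray(h_batch, dtype=np.float64)
    term_h = float(np.mean(np.maximum(np.asarray(F(h), dtype=np.float64) - h, 0.0)))
    term_e = float(np.mean(np.maximum(e - np.asarray(G(e), dtype=np.float64), 0.0)))
    return term_h + term_e


def adversarial_losses(D_H, D_E, real_h, real_e, fake_h, fake_e,
                       form: str = "lsgan") -> tuple[float, float]:
    """(discriminator objective, generator adversarial term).

    In the default least-squares form the discriminators target 1 on real
    and 0 on fake images; the generators are rewarded for pushing
    discriminator scores on their fakes toward 1.  The logarithmic form
    treats scores as logits of a realness probability.
    """
    sh_r = np.asarray(D_H(real_h), dtype=np.float64)
    sh_f = np.asarray(D_H(fake_h), dtype=np.float64)
    se_r = np.asarray(D_E(real_e), dtype=np.float64)
    se_f = np.asarray(D_E(fake_e), dtype=np.float64)
    if form == "lsgan":
        d_obj = float(np.mean((sh_r - 1) ** 2) + np.mean(sh_f ** 2)
                      + np.mean((se_r - 1) ** 2) + np.mean(se_f ** 2))
        g_adv = float(np.mean((sh_f - 1) ** 2) + np.mean((se_f - 1) ** 2))
        return d_obj, g_adv
    if form == "log":
        def sig(x):
            return 1.0 / (1.0 + np.exp(-x))
        d_obj = float(-np.mean(np.log(sig(sh_r))) - np.mean(np.log1p(-sig(sh_f)))
                      - np.mean(np.log(sig(se_r))) - np.mean(np.log1p(-sig(se_f))))
        g_adv = float(-np.mean(np.log(sig(sh_f))) - np.mean(np.log(sig(se_f))))
        return d_obj, g_adv
    raise ValueError(f"unknown adversarial form: {form}")


def total_generator_objective(weights: LossWeights, g_adv: float, l_c: float,
                              l_r: float, l_i: float) -> float:
    """Weighted sum w_d*adv + w_c*Lc + w_r*Lr + w_i*Li."""
    return (weights.w_d * g_adv + weights.w_c * l_c
            + weights.w_r * l_r + weights.w_i * l_i)


# ---------------------------------------------------------------------------
# training configuration and model


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 2e-4
    batch_size: int = 1
    n_blocks: int = 9
    base_channels: int = 64
    n_down: int = 2
    disc_layers: int = 3
    disc_channels: int = 64
    image_pad_to: int = 300
    crop_size: int = 256
    replay_size: int = 50
    lr_decay_start: int | None = None   # linear decay to 0 from this epoch
    adv_form: str = "lsgan"
    seed: int = 0

    def __post_init__(self):
        if self.crop_size > self.image_pad_to:
            raise ValueError("crop_size must not exceed image_pad_to")

    @classmethod
    def preset(cls, name: str, **overrides) -> "TrainConfig":
        """Presets: "paper" (full scale) and "tiny" (desk scale, 64x64)."""
        if name == "paper":
            base = cls()
        elif name == "tiny":
            # small nets at batch 4 tolerate (and need) a larger step size
            # than the full-scale default to converge within tens of epochs
            base = cls(epochs=20, learning_rate=5e-4, batch_size=4,
                       n_blocks=2, base_channels=8, n_down=1, disc_layers=2,
                       disc_channels=8, image_pad_to=72, crop_size=64,
                       replay_size=16)
        else:
            raise ValueError(f"unknown preset: {name}")
        for k, v in overrides.items():
            setattr(base, k, v)
        return base


class _ReplayBuffer:
    """Pool of past generator outputs fed to the discriminator."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        out = []
        for img in batch:
            if len(self.items) < self.size:
                self.items.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                j = int(self.rng.integers(len(self.items)))
                out.append(self.items[j].copy())
                self.items[j] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


@dataclass
class TranslationModel:
    """The trained mapping pair (F: hard->easy, G: easy->hard) plus the
    per-domain discriminators and training metadata."""

    F: Sequential
    G: Sequential
    D_H: Sequential
    D_E: Sequential
    weights: LossWeights
    cfg: TrainConfig
    loss_history: list[dict] = field(default_factory=list)

    def _run(self, net: Sequential, image01: np.ndarray) -> np.ndarray:
        img = np.asarray(image01, dtype=np.float32)
        h, w = img.shape
        mult = 2 ** self.cfg.n_down
        ph, pw = (-h) % mult, (-w) % mult
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
        y, _ = net.forward(img[None, None] * 2.0 - 1.0)
        return np.clip((y[0, 0, :h, :w].astype(np.float64) + 1.0) / 2.0, 0.0, 1.0)

    def translate_to_easy(self, h_image01: np.ndarray) -> np.ndarray:
        """F(h) on the [0,1] external scale, same shape as the input.

        The downstream segmentation mask is paired with the ORIGINAL image;
        the translated image is an intermediate representation only.
        """
        return self._run(self.F, h_image01)

    def translate_to_hard(self, e_image01: np.ndarray) -> np.ndarray:
        return self._run(self.G, e_image01)


def _l1_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return np.sign(pred - target).astype(np.float32) / pred.size


def train_translation(easy_images, hard_images, weights: LossWeights,
                      cfg: TrainConfig) -> TranslationModel:
    """Train the cyclic translation model on two unpaired image sets.

    ``easy_images`` / ``hard_images`` are sequences of [0,1] 2-D arrays.
    Per batch, the two generators are updated jointly on the weighted
    objective, then each discriminator on a real batch against a replay
    buffer of past fakes (least-squares targets 1/0).  Augmentation is
    random crop from reflect-padded images, 90-degree rotations, and flips.
    Fully reproducible for a fixed seed.
    """
    if len(easy_images) == 0 or len(hard_images) == 0:
        raise ValueError("both domains need at least one image")
    if cfg.adv_form != "lsgan":
        raise NotImplementedError("training uses the least-squares form")
    rng = np.random.default_rng(cfg.seed)
    net_rngs = [np.random.default_rng(s) for s in
                np.random.SeedSequence(cfg.seed).spawn(4)]
    F = resnet_generator(1, 1, cfg.base_channels, cfg.n_blocks, cfg.n_down, net_rngs[0])
    G = resnet_generator(1, 1, cfg.base_channels, cfg.n_blocks, cfg.n_down, net_rngs[1])
    D_H = patch_discriminator(1, cfg.disc_channels, cfg.disc_layers, net_rngs[2])
    D_E = patch_discriminator(1, cfg.disc_channels, cfg.disc_layers, net_rngs[3])
    model = TranslationModel(F, G, D_H, D_E, weights, cfg)

    opt_g = Adam(F.params() + G.params(), lr=cfg.learning_rate)
    opt_dh = Adam(D_H.params(), lr=cfg.learning_rate)
    opt_de = Adam(D_E.params(), lr=cfg.learning_rate)
    buf_h = _ReplayBuffer(cfg.replay_size, rng)
    buf_e = _ReplayBuffer(cfg.replay_size, rng)

    easy = [np.asarray(im, dtype=np.float32) for im in easy_images]
    hard = [np.asarray(im, dtype=np.float32) for im in hard_images]
    steps = max(1, min(len(easy), len(hard)) // cfg.batch_size)
    w = weights

    for epoch in range(cfg.epochs):
        if cfg.lr_decay_start is not None and epoch >= cfg.lr_decay_start:
            frac = 1.0 - (epoch - cfg.lr_decay_start) / max(
                1, cfg.epochs - cfg.lr_decay_start)
            for opt in (opt_g, opt_dh, opt_de):
                opt.lr = cfg.learning_rate * frac
        sums = {"L_d": 0.0, "L_adv": 0.0, "L_c": 0.0, "L_r": 0.0,
                "L_i": 0.0, "total": 0.0}
        for _ in range(steps):
            e = sample_batch(easy, rng, cfg.batch_size, cfg.image_pad_to,
                             cfg.crop_size) * 2.0 - 1.0
            h = sample_batch(hard, rng, cfg.batch_size, cfg.image_pad_to,
                             cfg.crop_size) * 2.0 - 1.0
            n = e.size

            # ---- forward passes ----
            # translation and identity inputs share one batched pass per
            # generator (instance norm is per-sample, so this is exact)
            b = e.shape[0]
            yF1, cF1 = F.forward(np.concatenate([h, e]) if w.w_i > 0 else h)
            yG1, cG1 = G.forward(np.concatenate([e, h]) if w.w_i > 0 else e)
            fake_e, idt_e = yF1[:b], yF1[b:]
            fake_h, idt_h = yG1[:b], yG1[b:]
            rec_h, cG2 = G.forward(fake_e)
            rec_e, cF2 = F.forward(fake_h)
            de_out, cDE = D_E.forward(fake_e)
            dh_out, cDH = D_H.forward(fake_h)

            l_c = float(np.mean(np.abs(rec_e - e)) + np.mean(np.abs(rec_h - h)))
            l_r = float(np.mean(np.maximum(fake_e - h, 0))
                        + np.mean(np.maximum(e - fake_h, 0)))
            l_i = (float(np.mean(np.abs(idt_e - e)) + np.mean(np.abs(idt_h - h)))
                   if w.w_i > 0 else 0.0)
            g_adv = float(np.mean((de_out - 1) ** 2) + np.mean((dh_out - 1) ** 2))

            opt_g.zero_grad()
            # cycle: back through the outer generator first
            g_fake_h = F.backward(w.w_c * _l1_grad(rec_e, e), cF2)
            g_fake_e = G.backward(w.w_c * _l1_grad(rec_h, h), cG2)
            # adversarial gradients through (frozen) discriminators
            g_fake_e = g_fake_e + D_E.backward(
                (w.w_d * 2.0 * (de_out - 1) / de_out.size).astype(np.float32), cDE)
            g_fake_h = g_fake_h + D_H.backward(
                (w.w_d * 2.0 * (dh_out - 1) / dh_out.size).astype(np.float32), cDH)
            # directional one-sided terms
            if w.w_r > 0:
                g_fake_e = g_fake_e + w.w_r * (fake_e > h).astype(np.float32) / n
                g_fake_h = g_fake_h - w.w_r * (e > fake_h).astype(np.float32) / n
            if w.w_i > 0:
                F.backward(np.concatenate([g_fake_e, w.w_i * _l1_grad(idt_e, e)]), cF1)
                G.backward(np.concatenate([g_fake_h, w.w_i * _l1_grad(idt_h, h)]), cG1)
            else:
                F.backward(g_fake_e, cF1)
                G.backward(g_fake_h, cG1)
            opt_g.step()
            # discriminator params picked up adversarial-path gradients; drop them
            for p in D_H.params() + D_E.params():
                p.zero_grad()

            # ---- discriminator updates (replay buffer, LSGAN, 0.5 factor) ----
            l_d = 0.0
            for D, opt_d, real, fake in ((D_E, opt_de, e, buf_e.query(fake_e)),
                                         (D_H, opt_dh, h, buf_h.query(fake_h))):
                opt_d.zero_grad()
                s_r, c_r = D.forward(real)
                s_f, c_f = D.forward(fake)
                l_d += 0.5 * float(np.mean((s_r - 1) ** 2) + np.mean(s_f ** 2))
                D.backward(((s_r - 1) / s_r.size).astype(np.float32), c_r)
                D.backward((s_f / s_f.size).astype(np.float32), c_f)
                opt_d.step()

            total = total_generator_objective(w, g_adv, l_c, l_r, l_i)
            if not np.isfinite(total) or not np.isfinite(l_d):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: "
                                   f"total={total}, L_d={l_d}")
            for k, v in (("L_d", l_d), ("L_adv", g_adv), ("L_c", l_c),
                         ("L_r", l_r), ("L_i", l_i), ("total", total)):
                sums[k] += v
        model.loss_history.append(
            {"epoch": epoch, **{k: v / steps for k, v in sums.items()}})
    return model
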