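"""Desk-scale study: the translate-then-segment effect on phantoms.

This module pins down one reproducible protocol: train the tiny-preset
translation model on 100 easy + 100 hard 64x64 phantom slices (25 subjects
per domain, 4 slices each), then score unsupervised GMM segmentation of 24
held-out hard slices (8 unseen subjects) on the original images versus
their hard-to-easy translations, against the original ground truth.  It
also measures the directional one-sided intensity excess mean r(F(h) - h)
that the directional loss is designed to suppress.

All randomness derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import dice
from .phantom import DomainDataset, PhantomConfig, generate_domain_datasets
from .segmentation import gmm_segment
from .translation import (LossWeights, TrainConfig, TranslationModel,
                          train_translation)

N_TRAIN_SUBJECTS = 25
SLICES_PER_SUBJECT = 4
N_HELDOUT_SUBJECTS = 8
HELDOUT_SLICES = 3


@dataclass
class DeskStudyResult:
    """Per-slice scores and intensity statistics of one study run."""

    dsc_original: list[float]
    dsc_translated: dict[str, list[float]]       # config name -> scores
    directional_excess: dict[str, float]         # config name -> mean r(F(h)-h)
    directional_excess_untrained: float
    identity_error: dict[str, float]             # mean |F(e)-e| on held-out easy
    identity_error_untrained: float
    hard_change: dict[str, float]                # mean |F(h)-h| on held-out hard
    models: dict[str, TranslationModel] = field(default_factory=dict)
    heldout: DomainDataset | None = None

    def median_benefit(self, config: str = "G_{0.5,1}") -> float:
        return (float(np.median(self.dsc_translated[config]))
                - float(np.median(self.dsc_original)))


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(np.random.default_rng(c).integers(2 ** 31)) for c in ss.spawn(n)]


def untrained_model(seed: int, cfg: TrainConfig | None = None) -> TranslationModel:
    """Randomly initialized mapping pair, the no-training baseline."""
    from .nn import patch_discriminator, resnet_generator
    cfg = cfg or TrainConfig.preset("tiny")
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]
    F = resnet_generator(1, 1, cfg.base_channels, cfg.n_blocks, cfg.n_down, rngs[0])
    G = resnet_generator(1, 1, cfg.base_channels, cfg.n_blocks, cfg.n_down, rngs[1])
    D_H = patch_discriminator(1, cfg.disc_channels, cfg.disc_layers, rngs[2])
    D_E = patch_discriminator(1, cfg.disc_channels, cfg.disc_layers, rngs[3])
    return TranslationModel(F, G, D_H, D_E, LossWeights(), cfg)


def run_desk_study(seed: int = 7, epochs: int = 20,
                   weight_configs: tuple[tuple[float, float], ...] = ((0.5, 1.0), (0.0, 1.0)),
                   ) -> DeskStudyResult:
    """Train one model per weight configuration and evaluate the benefit."""
    s_train, s_held, s_easyheld, s_model = _derive_seeds(seed, 4)
    easy, hard = generate_domain_datasets(
        N_TRAIN_SUBJECTS, N_TRAIN_SUBJECTS, SLICES_PER_SUBJECT,
        PhantomConfig(seed=s_train))
    _, heldout = generate_domain_datasets(
        2, N_HELDOUT_SUBJECTS, HELDOUT_SLICES, PhantomConfig(seed=s_held))
    easy_heldout, _ = generate_domain_datasets(
        4, 1, HELDOUT_SLICES, PhantomConfig(seed=s_easyheld))
    cfg = TrainConfig.preset("tiny", epochs=epochs, seed=s_model)

    dsc_orig = [dice(gmm_segment(s.image), s.muscle_mask) for s in heldout.slices]
    result = DeskStudyResult(
        dsc_original=dsc_orig, dsc_translated={}, directional_excess={},
        directional_excess_untrained=0.0, identity_error={},
        identity_error_untrained=0.0, hard_change={}, heldout=heldout)

    base = untrained_model(s_model, cfg)
    result.directional_excess_untrained = float(np.mean(
        [np.mean(np.maximum(base.translate_to_easy(s.image) - s.image, 0))
         for s in heldout.slices]))
    result.identity_error_untrained = float(np.mean(
        [np.mean(np.abs(base.translate_to_easy(s.image) - s.image))
         for s in easy_heldout.slices]))

    for w_r, w_i in weight_configs:
        weights = LossWeights.config(w_r, w_i)
        model = train_translation([s.image for s in easy.slices],
                                  [s.image for s in hard.slices], weights, cfg)
        name = weights.name
        translated = [model.translate_to_easy(s.image) for s in heldout.slices]
        result.dsc_translated[name] = [
            dice(gmm_segment(t), s.muscle_mask)
            for t, s in zip(translated, heldout.slices)]
        result.directional_excess[name] = float(np.mean(
            [np.mean(np.maximum(t - s.image, 0))
             for t, s in zip(translated, heldout.slices)]))
        result.hard_change[name] = float(np.mean(
            [np.mean(np.abs(t - s.image))
             for t, s in zip(translated, heldout.slices)]))
        result.identity_error[name] = float(np.mean(
            [np.mean(np.abs(model.translate_to_easy(s.image) - s.image))
             for s in easy_heldout.slices]))
        result.models[name] = model
    return result
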