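"""Dice scoring and the experiment protocol: per-method grid search with
leave-one-out cross-validation by subject, fourfold cross-validation for the
CNN segmenter, and the original-image (OI) vs translated comparison.

The evaluation contract for translated images: the mask produced on the
translated image is scored against the ORIGINAL image's ground truth
without modification — translation is an intermediate representation only.
DSCs are aggregated per subject (mean over that subject's annotated
slices); distributions over subjects are summarized by median, quartiles
(linear interpolation), min and max.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import DomainDataset, PhantomSlice
from .segmentation import (CNNConfig, GraphCutParams, SPGCParams,
                           build_shape_prior, fit_appearance_model,
                           gmm_segment, graph_cut_segment, register_prior,
                           spgc_segment, train_cnn_segmenter)
from .translation import LossWeights, TrainConfig, train_translation


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|a n b| / (|a| + |b|); 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between masks")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class GridSpec:
    """Candidate hyper-parameter values, defaulting to the printed grids."""

    values: dict = field(default_factory=lambda: {
        "lambda_s": [0.001, 0.002, 0.05, 0.1, 0.2, 0.5],
        "sigma": [1, 2],
        "lambda_sp": [0.1, 0.2, 0.5, 0.7, 1],
        "p_n": [0.2, 0.3, 0.4, 0.5],
    })

    def candidates(self, names: list[str]) -> list[dict]:
        for n in names:
            if not self.values.get(n):
                raise ValueError(f"empty grid for parameter {n}")
        combos = itertools.product(*(self.values[n] for n in names))
        return [dict(zip(names, c)) for c in combos]


_GRID_PARAMS = {"gmm": [], "gc": ["lambda_s", "sigma"],
                "spgc": ["lambda_s", "sigma", "lambda_sp", "p_n"]}


def _segment_slices(method: str, train_slices: list[PhantomSlice],
                    test_images: list[np.ndarray], params: dict) -> list[np.ndarray]:
    """Segment test images with ``method`` trained on ``train_slices``."""
    if method == "gmm":
        return [gmm_segment(img) for img in test_images]
    model = fit_appearance_model([s.image for s in train_slices],
                                 [s.muscle_mask for s in train_slices])
    gc = GraphCutParams(lambda_s=params["lambda_s"], sigma=params["sigma"])
    if method == "gc":
        return [graph_cut_segment(img, model, gc, init=gmm_segment(img))
                for img in test_images]
    if method == "spgc":
        prior = build_shape_prior([s.muscle_mask for s in train_slices])
        sp = SPGCParams(lambda_sp=params["lambda_sp"], p_n=params["p_n"], gc=gc)
        out = []
        for img in test_images:
            init = gmm_segment(img)
            out.append(spgc_segment(img, model, register_prior(prior, init), sp))
        return out
    raise ValueError(f"unknown method: {method}")


def _annotated(slices: list[PhantomSlice], step: int) -> list[PhantomSlice]:
    return slices[::step]


def _by_subject(dataset: DomainDataset) -> dict[str, list[PhantomSlice]]:
    groups: dict[str, list[PhantomSlice]] = {}
    for s in dataset.slices:
        groups.setdefault(s.subject_id, []).append(s)
    return groups


def _score_subject(method: str, train_slices, test_slices, params,
                   eval_images=None) -> float:
    """Mean DSC over a subject's annotated slices.

    ``eval_images`` substitutes translated images for segmentation while the
    ground-truth masks stay those of the original slices.
    """
    images = eval_images if eval_images is not None else [s.image for s in test_slices]
    masks = _segment_slices(method, train_slices, images, params)
    return float(np.mean([dice(m, s.muscle_mask)
                          for m, s in zip(masks, test_slices)]))


def grid_search(method: str, dataset: DomainDataset, grid: GridSpec,
                annotation_step: int = 4,
                eval_images: dict | None = None) -> tuple[dict, dict]:
    """Leave-one-out (by subject) grid search.

    For each held-out subject, hyper-parameters are selected by mean DSC over
    the remaining subjects (each scored with models trained without it), then
    the held-out subject is scored once with the selected parameters.
    Returns ``(per_subject_dsc, per_subject_selected_params)``.

    ``eval_images`` optionally maps subject_id -> list of images to segment
    in place of the stored ones (the translated-image pathway).
    """
    groups = _by_subject(dataset)
    subjects = list(groups)
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs at least two subjects")
    candidates = grid.candidates(_GRID_PARAMS[method]) or [{}]

    def images_of(subj, slices):
        if eval_images is None:
            return [s.image for s in slices]
        return [eval_images[subj][i] for i in range(0, len(groups[subj]),
                                                    annotation_step)]

    scores: dict[str, float] = {}
    selections: dict[str, dict] = {}
    for held in subjects:
        rest = [s for s in subjects if s != held]
        best, best_score = None, -np.inf
        for params in candidates:
            vals = []
            for j in rest:
                # inner LOO: models for scoring j never see j (nor the held-out)
                train = [sl for s2 in rest if s2 != j for sl in groups[s2]]
                if not train:  # two-subject corner: fall back to the other subject
                    train = [sl for s2 in rest for sl in groups[s2]]
                test = _annotated(groups[j], annotation_step)
                vals.append(_score_subject(method, train, test, params,
                                           images_of(j, test)))
            mean_val = float(np.mean(vals))
            if mean_val > best_score + 1e-12:
                best, best_score = params, mean_val
        train = [sl for s2 in rest for sl in groups[s2]]
        test = _annotated(groups[held], annotation_step)
        scores[held] = _score_subject(method, train, test, best,
                                      images_of(held, test))
        selections[held] = best
    return scores, selections


@dataclass
class ExperimentResult:
    """Per-(method, configuration, subject) DSCs plus run metadata."""

    rows: pd.DataFrame                 # method, config, subject_id, dsc
    selections: dict = field(default_factory=dict)
    seed: int = 0
    quartile_convention: str = "linear"

    def summary(self) -> pd.DataFrame:
        """One row per method x configuration: median/quartiles/min/max/n."""
        def agg(g):
            v = g["dsc"].to_numpy()
            return pd.Series({
                "median": float(np.percentile(v, 50)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "min": float(v.min()), "max": float(v.max()),
                "n": len(v),
            })
        out = (self.rows.groupby(["method", "config"], sort=False)
               .apply(agg, include_groups=False).reset_index())
        out["n"] = out["n"].astype(int)
        return out

    def save(self, path: str) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str) -> "ExperimentResult":
        return cls(rows=pd.read_csv(path))


def _cnn_fourfold(dataset: DomainDataset, cnn_cfg: CNNConfig,
                  annotation_step: int, eval_images: dict | None) -> dict[str, float]:
    """Fourfold (by subject) cross-validation of the CNN segmenter."""
    groups = _by_subject(dataset)
    subjects = list(groups)
    n_folds = min(4, len(subjects))
    folds = [subjects[i::n_folds] for i in range(n_folds)]
    scores: dict[str, float] = {}
    for k, fold in enumerate(folds):
        train = [sl for s in subjects if s not in fold
                 for sl in _annotated(groups[s], annotation_step)]
        timgs = [(eval_images[sl.subject_id][i] if eval_images is not None
                  else sl.image)
                 for s in subjects if s not in fold
                 for i, sl in enumerate(_annotated(groups[s], annotation_step))]
        model = train_cnn_segmenter(timgs, [sl.muscle_mask for sl in train], cnn_cfg)
        for s in fold:
            test = _annotated(groups[s], annotation_step)
            if eval_images is not None:
                imgs = [eval_images[s][i] for i in range(0, len(groups[s]),
                                                         annotation_step)]
            else:
                imgs = [sl.image for sl in test]
            preds = [model.predict(im) for im in imgs]
            scores[s] = float(np.mean([dice(p, sl.muscle_mask)
                                       for p, sl in zip(preds, test)]))
    return scores


def run_experiment(easy: DomainDataset, hard: DomainDataset,
                   weight_configs: list, methods: list[str],
                   train_cfg: TrainConfig, grid: GridSpec | None = None,
                   cnn_cfg: CNNConfig | None = None,
                   annotation_step: int = 1, seed: int = 0) -> ExperimentResult:
    """OI-vs-translated comparison over methods and GAN weight configurations.

    ``weight_configs`` mixes the string "OI" (segment original hard images)
    with :class:`LossWeights` instances (train a translation model with those
    weights, segment the translated hard images).  Masks are always scored
    against the original ground truth.
    """
    grid = grid or GridSpec()
    cnn_cfg = cnn_cfg or CNNConfig()
    records = []
    selections = {}
    easy_imgs = [s.image for s in easy.slices]
    hard_imgs = [s.image for s in hard.slices]
    groups = _by_subject(hard)

    for config in weight_configs:
        if isinstance(config, str) and config == "OI":
            name, eval_images = "OI", None
        else:
            assert isinstance(config, LossWeights)
            name = config.name
            model = train_translation(easy_imgs, hard_imgs, config, train_cfg)
            eval_images = {subj: [model.translate_to_easy(sl.image)
                                  for sl in slices]
                           for subj, slices in groups.items()}
        for method in methods:
            if method == "cnn":
                scores = _cnn_fourfold(hard, cnn_cfg, annotation_step, eval_images)
                sel = {}
            elif method == "gmm":
                scores = {}
                for subj, slices in groups.items():
                    test = _annotated(slices, annotation_step)
                    imgs = ([eval_images[subj][i] for i in
                             range(0, len(slices), annotation_step)]
                            if eval_images is not None
                            else [sl.image for sl in test])
                    scores[subj] = _score_subject("gmm", [], test, {}, imgs)
                sel = {}
            else:
                scores, sel = grid_search(method, hard, grid, annotation_step,
                                          eval_images)
            selections[(method, name)] = sel
            for subj, v in scores.items():
                records.append({"method": method, "config": name,
                                "subject_id": subj, "dsc": v})
    rows = pd.DataFrame(records, columns=["method", "config", "subject_id", "dsc"])
    return ExperimentResult(rows=rows, selections=selections, seed=seed)


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Tidy summary table (box-plot statistics per method x configuration)."""
    if result.rows.empty:
        raise ValueError("empty experiment result")
    return result.summary()
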