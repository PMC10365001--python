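"""Dice laws, leave-one-out grid search, and result summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from myoseg import GridSpec, dice, grid_search
from myoseg.evaluation import ExperimentResult, summarize


# ---------------------------------------------------------------------------
# dice

def test_dice_worked_examples():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    a[0, :4] = True                  # |a| = 4
    b[0, 2:4] = b[1, :2] = True      # |b| = 4, |a&b| = 2
    assert dice(a, b) == pytest.approx(0.5)
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0
    with pytest.raises(ValueError):
        dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(arrays(bool, (5, 5)), arrays(bool, (5, 5)))
def test_dice_symmetry_and_range(a, b):
    assert dice(a, b) == dice(b, a)
    assert 0.0 <= dice(a, b) <= 1.0


def test_dice_monotonicity_laws():
    rng = np.random.default_rng(0)
    a = rng.uniform(size=(6, 6)) > 0.5
    b = rng.uniform(size=(6, 6)) > 0.5
    base = dice(a, b)
    # adding a true positive (pixel in a, set in b) never decreases DSC
    tp = a & ~b
    if tp.any():
        b2 = b.copy()
        b2[tuple(np.argwhere(tp)[0])] = True
        assert dice(a, b2) >= base
    # adding a false positive (pixel outside a) never increases DSC
    fp = ~a & ~b
    if fp.any():
        b3 = b.copy()
        b3[tuple(np.argwhere(fp)[0])] = True
        assert dice(a, b3) <= base


# ---------------------------------------------------------------------------
# grid search / LOO

def test_loo_bookkeeping_and_single_candidate(small_datasets):
    _, hard = small_datasets
    grid = GridSpec(values={"lambda_s": [0.1], "sigma": [1]})
    scores, selections = grid_search("gc", hard, grid, annotation_step=2)
    assert len(scores) == hard.n_subjects          # one held-out score each
    assert all(sel == {"lambda_s": 0.1, "sigma": 1} for sel in selections.values())


def test_loo_selects_dominant_candidate(small_datasets):
    """With a degenerate-vs-sane smoothness pair, every fold must pick the
    sane one (huge lambda merges everything into one label)."""
    _, hard = small_datasets
    grid = GridSpec(values={"lambda_s": [0.1, 1e6], "sigma": [1]})
    _, selections = grid_search("gc", hard, grid, annotation_step=2)
    assert all(sel["lambda_s"] == 0.1 for sel in selections.values())


def test_loo_never_reads_held_out_subject(small_datasets, monkeypatch):
    """Instrument the scorer: no model is ever fitted on the subject it is
    scored on, and each held-out subject's final score uses a model trained
    on exactly the other subjects."""
    _, hard = small_datasets
    import myoseg.evaluation as ev
    calls = []
    orig = ev._score_subject

    def spy(method, train_slices, test_slices, params, eval_images=None):
        calls.append(({s.subject_id for s in train_slices},
                      {s.subject_id for s in test_slices}))
        return orig(method, train_slices, test_slices, params, eval_images)

    monkeypatch.setattr(ev, "_score_subject", spy)
    grid = GridSpec(values={"lambda_s": [0.1, 0.2], "sigma": [1]})
    subjects = set(hard.subjects())
    scores, _ = ev.grid_search("gc", hard, grid, annotation_step=3)
    assert calls, "scorer was never invoked"
    for trained_on, tested_on in calls:
        assert not trained_on & tested_on       # no self-leakage, ever
    for held in subjects:
        # the fold's final scoring: trained on exactly the other subjects
        assert (subjects - {held}, {held}) in calls


def test_grid_requires_two_subjects(small_datasets):
    from myoseg.phantom import DomainDataset
    _, hard = small_datasets
    one = DomainDataset(slices=[s for s in hard.slices
                                if s.subject_id == hard.subjects()[0]],
                        domain_label="hard")
    with pytest.raises(ValueError):
        grid_search("gc", one, GridSpec(values={"lambda_s": [0.1], "sigma": [1]}))
    with pytest.raises(ValueError):
        GridSpec(values={"lambda_s": [], "sigma": [1]}).candidates(["lambda_s"])


# ---------------------------------------------------------------------------
# summaries

def _toy_result():
    rows = pd.DataFrame([
        {"method": "gmm", "config": "OI", "subject_id": f"s{i}", "dsc": v}
        for i, v in enumerate([0.5, 0.6, 0.7, 0.9])
    ] + [
        {"method": "gmm", "config": "G_{0.5,1}", "subject_id": f"s{i}", "dsc": v}
        for i, v in enumerate([0.8, 0.85, 0.9, 0.95])
    ])
    return ExperimentResult(rows=rows)


def test_summary_statistics_match_independent_recomputation():
    res = _toy_result()
    summ = summarize(res)
    assert len(summ) == 2                       # methods x configs rows
    row = summ[summ["config"] == "OI"].iloc[0]
    v = sorted([0.5, 0.6, 0.7, 0.9])
    # linear-interpolation quartiles, recomputed by hand
    assert row["median"] == pytest.approx((v[1] + v[2]) / 2)
    assert row["q1"] == pytest.approx(v[0] + 0.75 * (v[1] - v[0]))
    assert row["q3"] == pytest.approx(v[2] + 0.25 * (v[3] - v[2]))
    assert row["min"] == 0.5 and row["max"] == 0.9 and row["n"] == 4


def test_run_experiment_oi_rows_and_cnn_fold_bookkeeping(small_datasets):
    from myoseg import TrainConfig, run_experiment
    from myoseg.segmentation import CNNConfig
    easy, hard = small_datasets
    res = run_experiment(easy, hard, ["OI"], ["gmm", "cnn"],
                         TrainConfig.preset("tiny", epochs=1),
                         cnn_cfg=CNNConfig(epochs=2, seed=3),
                         annotation_step=1, seed=3)
    # one DSC per subject for each method
    for method in ("gmm", "cnn"):
        sub = res.rows[res.rows["method"] == method]
        assert sorted(sub["subject_id"]) == sorted(hard.subjects())
        assert ((0 <= sub["dsc"]) & (sub["dsc"] <= 1)).all()
    assert set(res.rows["config"]) == {"OI"}
    assert len(summarize(res)) == 2


def test_result_csv_round_trip(tmp_path):
    res = _toy_result()
    path = tmp_path / "results.csv"
    res.save(str(path))
    back = ExperimentResult.load(str(path))
    pd.testing.assert_frame_equal(res.rows, back.rows)
    with pytest.raises(ValueError):
        summarize(ExperimentResult(rows=pd.DataFrame(
            columns=["method", "config", "subject_id", "dsc"])))
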