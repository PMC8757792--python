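"""Macro-F1 correctness, LOSO leakage guarantees, sweeps and the
summary statistics (Spearman GL correlation, Kruskal-Wallis)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import f1_score as sk_f1

from fogcast.classifiers import EnsembleConfig
from fogcast.evaluation import (
    SweepResult,
    class_weight_sweep,
    compare_classifiers,
    confusion_counts,
    gl_correlation,
    loso_evaluate,
    macro_f1,
    sweep,
)
from fogcast.stepsim import SimConfig, simulate_cohort
from fogcast.windowing import WindowingParams

FAST = EnsembleConfig(rf_n_estimators=15, seed=0)


# ---------------------------------------------------------------------------
# macro F1
# ---------------------------------------------------------------------------

def test_f1_perfect_and_all_wrong():
    y = np.array([1, 1, 0, 0])
    assert macro_f1(y, y) == 1.0
    assert macro_f1(y, 1 - y) == 0.0


def test_f1_hand_computed_eleven_fifteenths():
    truth = np.array([1, 1, 0, 0])
    pred = np.array([1, 0, 0, 0])
    # class 1: P=1, R=1/2 -> 2/3; class 0: P=2/3, R=1 -> 4/5; macro = 11/15
    assert macro_f1(truth, pred) == pytest.approx(11 / 15)


def test_f1_single_class_conventions():
    ones = np.ones(5, int)
    zeros = np.zeros(5, int)
    assert macro_f1(ones, ones) == 1.0  # absent class handled perfectly
    assert macro_f1(zeros, zeros) == 1.0
    assert 0.0 <= macro_f1(ones, zeros) <= 1.0  # never NaN
    with pytest.raises(ValueError):
        macro_f1(np.array([]), np.array([]))


def test_f1_matches_sklearn_on_random_pairs():
    """500 random label pairs containing both classes match sklearn's
    macro F1 exactly."""
    rng = np.random.default_rng(1)
    checked = 0
    while checked < 500:
        n = int(rng.integers(2, 60))
        t = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        if len(np.unique(t)) < 2 or len(np.unique(p)) < 2:
            continue
        assert macro_f1(t, p) == pytest.approx(
            sk_f1(t, p, average="macro", labels=[0, 1]))
        checked += 1


def test_confusion_counts_sum():
    t = np.array([0, 1, 0, 1, 1])
    p = np.array([1, 1, 0, 0, 1])
    c = confusion_counts(t, p)
    assert (c.TP, c.FP, c.TN, c.FN) == (2, 1, 1, 1)
    assert c.total == 5


# ---------------------------------------------------------------------------
# LOSO
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def loso_cohort():
    return simulate_cohort(SimConfig(n_subjects=4, trial_length=6000, seed=17))


@pytest.fixture(scope="module")
def loso_scores(loso_cohort):
    return loso_evaluate(loso_cohort, WindowingParams(IL=113),
                         classifiers=("nb", "rf"), config=FAST)


def test_loso_no_leakage(loso_scores):
    """Provenance audit: no fold's training pool contains the held-out
    subject."""
    for _, row in loso_scores.iterrows():
        assert row["subject"] not in row["train_subjects"].split(",")


def test_loso_one_row_per_classifier_subject(loso_scores, loso_cohort):
    assert len(loso_scores) == 2 * len(loso_cohort)
    assert set(loso_scores["classifier"]) == {"nb", "rf"}


def test_loso_scores_in_unit_interval(loso_scores):
    assert ((loso_scores["F1"] >= 0) & (loso_scores["F1"] <= 1)).all()


def test_loso_subject_permutation_invariance(loso_cohort):
    """Reordering the cohort leaves the per-subject score multiset
    unchanged."""
    a = loso_evaluate(loso_cohort, WindowingParams(IL=57),
                      classifiers=("nb",), config=FAST)
    b = loso_evaluate(loso_cohort[::-1], WindowingParams(IL=57),
                      classifiers=("nb",), config=FAST)
    sa = a.sort_values("subject")[["subject", "F1"]].reset_index(drop=True)
    sb = b.sort_values("subject")[["subject", "F1"]].reset_index(drop=True)
    pd.testing.assert_frame_equal(sa, sb)


def test_loso_identical_twins_score_high():
    """Two subjects with identical separable traces: the model trained on
    one scores highly on the other."""
    cfg = SimConfig(n_subjects=1, trial_length=9000, seed=2,
                    body_weight_sd=0, cycle_length_sd=0,
                    step_amplitude_rel_sd=0, tremble_rel_sd=0,
                    noise_sd=1.0, drift_sd=0.0, freeze_wander_sd=0.0,
                    tremble_amplitude=0.1)
    t = simulate_cohort(cfg)[0]
    from dataclasses import replace as dc_replace
    twin_a = dc_replace(t, subject_id="A")
    twin_b = dc_replace(t, subject_id="B")
    # class weight 1 here: the 100:1 weighting deliberately trades
    # precision for recall and is exercised in its own test
    df = loso_evaluate([twin_a, twin_b], WindowingParams(IL=113),
                       classifiers=("nb", "rf"),
                       config=EnsembleConfig(rf_n_estimators=15,
                                             rf_class_weight_true=1.0, seed=0))
    assert (df["F1"] >= 0.9).all()


def test_loso_requires_two_subjects(loso_cohort):
    with pytest.raises(ValueError, match="two distinct"):
        loso_evaluate(loso_cohort[:1], WindowingParams(IL=113))


# ---------------------------------------------------------------------------
# sweeps and statistics
# ---------------------------------------------------------------------------

def _toy_sweep(medians_by_gl, il_fixed=226):
    rows = []
    for gl, med in medians_by_gl.items():
        for s, f1 in enumerate(med):
            rows.append({"classifier": "nb", "subject": f"S{s}",
                         "IL": il_fixed, "GL": gl, "F1": f1})
    return SweepResult(scores=pd.DataFrame(rows), il_grid=(il_fixed,),
                       gl_grid=tuple(medians_by_gl), il_fixed=il_fixed)


def test_gl_correlation_perfect_monotone():
    res = _toy_sweep({0: [0.9], 28: [0.8], 57: [0.7], 113: [0.6]})
    rho, p = gl_correlation(res, "nb")
    assert rho == -1.0
    res_up = _toy_sweep({0: [0.6], 28: [0.7], 57: [0.8], 113: [0.9]})
    assert gl_correlation(res_up, "nb")[0] == 1.0


def test_gl_correlation_ties_match_scipy():
    med = {0: [0.9], 28: [0.8], 57: [0.8], 113: [0.6]}
    res = _toy_sweep(med)
    rho, _ = gl_correlation(res, "nb")
    expected, _ = stats.spearmanr([0, 28, 57, 113], [0.9, 0.8, 0.8, 0.6])
    assert rho == pytest.approx(expected)


def test_gl_correlation_constant_series_undefined():
    res = _toy_sweep({0: [0.5], 28: [0.5], 57: [0.5], 113: [0.5]})
    rho, p = gl_correlation(res, "nb")
    assert np.isnan(rho) and np.isnan(p)


def test_gl_correlation_needs_three_points():
    res = _toy_sweep({0: [0.9], 113: [0.6]})
    with pytest.raises(ValueError, match="3 GL points"):
        gl_correlation(res, "nb")


def test_kruskal_identical_groups_h_zero():
    h, p = compare_classifiers([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
    assert h == 0.0 and p == 1.0


def test_kruskal_separated_groups_significant():
    h, p = compare_classifiers([0.9, 0.91, 0.92], [0.1, 0.11, 0.12])
    assert p < 0.05
    h2, p2 = stats.kruskal([0.9, 0.91, 0.92], [0.1, 0.11, 0.12])
    assert h == pytest.approx(h2) and p == pytest.approx(p2)


def test_kruskal_insufficient_observations():
    with pytest.raises(ValueError):
        compare_classifiers([0.5], [0.6, 0.7])


def test_sweep_single_point_reduces_to_loso(loso_cohort):
    res = sweep(loso_cohort, il_grid=(113,), gl_grid=(), il_fixed=113,
                classifiers=("nb",), config=FAST)
    direct = loso_evaluate(loso_cohort, WindowingParams(IL=113),
                           classifiers=("nb",), config=FAST)
    np.testing.assert_allclose(
        np.sort(res.scores["F1"].to_numpy()), np.sort(direct["F1"].to_numpy()))


def test_sweep_deterministic(loso_cohort):
    kw = dict(il_grid=(57,), gl_grid=(0, 28), il_fixed=57,
              classifiers=("nb",), config=FAST)
    a = sweep(loso_cohort, **kw)
    b = sweep(loso_cohort, **kw)
    pd.testing.assert_frame_equal(a.scores, b.scores)


def test_sweep_requires_a_grid(loso_cohort):
    with pytest.raises(ValueError, match="non-empty"):
        sweep(loso_cohort, il_grid=(), gl_grid=())


# ---------------------------------------------------------------------------
# class-weight sweep
# ---------------------------------------------------------------------------

def test_class_weight_single_weight_sd_zero(loso_cohort):
    res = class_weight_sweep(loso_cohort, weights=(50,), config=FAST)
    assert res["median_sd"] == 0.0


def test_class_weight_order_invariant(loso_cohort):
    a = class_weight_sweep(loso_cohort, weights=(1, 50, 100), config=FAST)
    b = class_weight_sweep(loso_cohort, weights=(100, 1, 50), config=FAST)
    assert a["median_sd"] == pytest.approx(b["median_sd"])
    assert a["median_f1"] == pytest.approx(b["median_f1"])


def test_class_weight_robustness_on_easy_cohort():
    """On a separable synthetic cohort the RF is robust to the freeze
    class weight: median per-subject SD of F1 across weights is small
    relative to the median F1 itself."""
    easy = SimConfig(n_subjects=4, trial_length=6000, seed=17,
                     noise_sd=1.0, drift_sd=2.0, freeze_wander_sd=3.0,
                     tremble_amplitude=0.1, tremble_rel_sd=0.05,
                     step_amplitude_rel_sd=0.05, body_weight_sd=5.0)
    cohort = simulate_cohort(easy)
    res = class_weight_sweep(cohort, weights=(1, 30, 60, 100),
                             config=EnsembleConfig(rf_n_estimators=30, seed=0))
    assert res["median_sd"] < 0.2 * res["median_f1"]
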