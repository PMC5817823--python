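"""Confusion matrices, ROC/AUC, DeLong intervals, accuracy tables."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import naranjo as na
from helpers import mann_whitney_auc


def test_confusion_hand_built_six_records(scored_factory):
    # 3 gold-positives (one scored below cutoff), 3 gold-negatives (one above)
    scored = scored_factory([5, 6, 2, 1, 0, 5], [True, True, True, False, False, False])
    cm = na.confusion(scored, cutoff=5)
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 1, 2, 1)
    assert cm.n == 6


def test_confusion_all_predicted_positive(scored_factory):
    scored = scored_factory([3, 4, 5], [True, False, True])
    cm = na.confusion(scored, cutoff=-10)
    assert cm.fn == 0 and cm.tn == 0
    assert cm.tp + cm.fp == 3


def test_confusion_rejects_degenerate_inputs(scored_factory):
    with pytest.raises(ValueError, match="no scored records"):
        na.confusion([], 5)
    with pytest.raises(ValueError, match="gold-positive and one gold-negative"):
        na.confusion(scored_factory([1, 2], [True, True]), 1)
    unlabelled = scored_factory([1, 2], [True, False])
    unlabelled[0].gold_label = None
    with pytest.raises(ValueError, match="without gold labels"):
        na.confusion(unlabelled, 1)


@pytest.mark.parametrize(
    "cm, sens, spec",
    [
        (na.ConfusionMatrix(tp=866, fp=136, tn=446, fn=131), 0.87, 0.77),
        (na.ConfusionMatrix(tp=5, fp=2, tn=3, fn=0), 1.0, 0.6),
        (na.ConfusionMatrix(tp=1, fp=1, tn=3, fn=3), 0.25, 0.75),
    ],
)
def test_sensitivity_specificity_values(cm, sens, spec):
    assert na.round_half_up(na.sensitivity(cm)) == sens
    assert na.round_half_up(na.specificity(cm)) == spec


def test_rates_undefined_without_both_classes():
    with pytest.raises(ValueError, match="sensitivity undefined"):
        na.sensitivity(na.ConfusionMatrix(tp=0, fp=1, tn=1, fn=0))
    with pytest.raises(ValueError, match="specificity undefined"):
        na.specificity(na.ConfusionMatrix(tp=1, fp=0, tn=0, fn=1))


def test_roc_perfect_separation(scored_factory):
    scored = scored_factory([5, 6, 7, 1, 2, 3], [True] * 3 + [False] * 3)
    curve = na.roc(scored)
    assert curve.auc == 1.0


def test_roc_identical_scores_is_chance(scored_factory):
    scored = scored_factory([4] * 6, [True] * 3 + [False] * 3)
    curve = na.roc(scored)
    assert curve.auc == 0.5
    assert curve.points[0][1:] == (0.0, 0.0)
    assert curve.points[-1][1:] == (1.0, 1.0)


def test_roc_staircase_monotone_with_endpoints(scored_factory):
    rng = np.random.default_rng(3)
    scored = scored_factory(rng.integers(-2, 12, 60), rng.random(60) < 0.6)
    curve = na.roc(scored)
    fprs = [p[1] for p in curve.points]
    tprs = [p[2] for p in curve.points]
    assert fprs == sorted(fprs) and tprs == sorted(tprs)
    assert curve.points[0][1:] == (0.0, 0.0)
    assert curve.points[-1][1:] == (1.0, 1.0)
    thresholds = [p[0] for p in curve.points]
    assert thresholds == sorted(thresholds, reverse=True)


def test_auc_equals_mann_whitney_and_sklearn(scored_factory):
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(6, 30))
        scores = rng.integers(0, 10, n)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        scored = scored_factory(scores, labels)
        auc = na.roc(scored).auc
        assert auc == pytest.approx(mann_whitney_auc(scores[labels], scores[~labels]), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_invariant_to_score_shift(scored_factory):
    rng = np.random.default_rng(5)
    scores = rng.integers(-3, 9, 50)
    labels = rng.random(50) < 0.55
    base = na.roc(scored_factory(scores, labels))
    shifted = na.roc(scored_factory(scores + 7, labels))
    assert shifted.auc == pytest.approx(base.auc, abs=1e-12)
    assert [p[1:] for p in shifted.points] == [p[1:] for p in base.points]


def test_auc_label_flip_symmetry(scored_factory):
    rng = np.random.default_rng(8)
    scores = rng.integers(0, 12, 40)
    labels = rng.random(40) < 0.5
    auc = na.roc(scored_factory(scores, labels)).auc
    flipped = na.roc(scored_factory(scores, ~labels)).auc
    assert flipped == pytest.approx(1.0 - auc, abs=1e-12)


def test_delong_interval_matches_reference_implementation(scored_factory):
    """Frozen cross-check: interval computed by the pROC reference
    implementation (DeLong method) on this exact dataset."""
    rng = np.random.default_rng(20240915)
    pos = rng.integers(0, 9, size=40)
    neg = rng.integers(-2, 6, size=35)
    scored = scored_factory(
        np.concatenate([pos, neg]), np.array([True] * 40 + [False] * 35)
    )
    assert na.roc(scored).auc == pytest.approx(0.7371428571, abs=1e-9)
    lower, upper = na.auc_ci(scored)
    assert lower == pytest.approx(0.6258668403, abs=1e-6)
    assert upper == pytest.approx(0.8484188740, abs=1e-6)


def test_delong_interval_brackets_auc_and_clips(scored_factory):
    scored = scored_factory([5, 6, 7, 8, 1, 2, 3], [True] * 4 + [False] * 3)
    lower, upper = na.auc_ci(scored)
    assert upper == 1.0  # perfect separation: boundary-clipped
    assert 0.0 <= lower <= 1.0
    rng = np.random.default_rng(2)
    scored = scored_factory(rng.integers(0, 10, 80), rng.random(80) < 0.5)
    lower, upper = na.auc_ci(scored)
    assert lower <= na.roc(scored).auc <= upper


def test_delong_requires_two_per_class(scored_factory):
    with pytest.raises(ValueError, match="two records per class"):
        na.auc_ci(scored_factory([1, 2, 3], [True, False, False]))
    with pytest.raises(ValueError, match="confidence level"):
        na.auc_ci(scored_factory([1, 2, 3, 4], [True, True, False, False]), level=1.5)


def test_accuracy_table_monotone(scored_factory):
    rng = np.random.default_rng(21)
    scored = scored_factory(rng.integers(-2, 12, 200), rng.random(200) < 0.6)
    table = na.accuracy_table(scored)
    assert (table["cutoff"].diff().dropna() > 0).all()
    assert (table["sensitivity"].diff().dropna() <= 0).all()
    assert (table["specificity"].diff().dropna() >= 0).all()


def test_confusion_beyond_score_range(scored_factory):
    scored = scored_factory([0, 2, 5, 7], [True, False, True, False])
    below = na.confusion(scored, cutoff=-5)
    assert na.sensitivity(below) == 1.0 and na.specificity(below) == 0.0
    above = na.confusion(scored, cutoff=20)
    assert na.sensitivity(above) == 0.0 and na.specificity(above) == 1.0


def test_adr_rate_by_total(scored_factory):
    scored = scored_factory([5, 5, 3, 3, 1], [True, True, True, False, False])
    table = na.adr_rate_by_total(scored)
    assert table["n"].sum() == 5
    assert table.set_index("total").loc[5, "adr_fraction"] == 1.0
    assert table.set_index("total").loc[1, "adr_fraction"] == 0.0
    assert ((table["adr_fraction"] >= 0) & (table["adr_fraction"] <= 1)).all()


def test_round_half_up():
    assert na.round_half_up(0.865) == 0.87
    assert na.round_half_up(0.864) == 0.86
    assert na.round_half_up(0.5, 0) == 1.0
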