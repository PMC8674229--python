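import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oncotext.evaluation import (
    NOT_ENOUGH_VARIATION,
    InsufficientVariationError,
    attribute_false_positives,
    auprc,
    auroc,
    calibration_curve,
    evaluate_by_group,
    pick_operating_point,
)

# ---------------------------------------------------------------- oracles


def auroc_pairwise(scores, labels):
    """O(n^2) concordance count: P(random positive outscores random negative),
    ties 1/2."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = wins = 0.0
    for p in pos:
        for n in neg:
            total += 1
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


def auprc_step(scores, labels):
    """Step-wise precision-recall integration: sum (R_i - R_{i-1}) * P_i over
    descending-score prefixes."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    sorted_scores = scores[order]
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def best_threshold_bruteforce(scores, labels, criterion):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best_val, best_sens = -np.inf, -1.0
    for thr in candidates:
        pred = scores > thr
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        val = f1 if criterion == "best_f1" else sens + spec - 1
        if val > best_val + 1e-12 or (abs(val - best_val) <= 1e-12 and sens > best_sens):
            best_val, best_sens = val, sens
    return best_val, best_sens


# ------------------------------------------------------------------- tests


def test_perfectly_separated_scores():
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.2, 0.8, 0.9])
    assert auroc(s, y) == 1.0
    assert auprc(s, y) == 1.0
    op = pick_operating_point(s, y, "best_f1")
    assert op.f1 == 1.0 and 0.2 < op.threshold < 0.8


def test_all_tied_scores_give_half():
    y = np.array([0, 1, 0, 1, 1])
    s = np.zeros(5)
    assert auroc(s, y) == 0.5


def test_single_class_signals_not_enough_variation():
    with pytest.raises(InsufficientVariationError):
        auroc([0.1, 0.9], [1, 1])
    with pytest.raises(InsufficientVariationError):
        pick_operating_point([0.1, 0.9], [1, 1])


@pytest.mark.parametrize("seed", range(25))
def test_auroc_and_auprc_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = 20
    s = np.round(rng.normal(size=n), 1)  # rounding forces ties
    y = rng.integers(0, 2, size=n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    assert np.isclose(auroc(s, y), auroc_pairwise(s, y))
    assert np.isclose(auprc(s, y), auprc_step(s, y))


@pytest.mark.parametrize("criterion", ["best_f1", "best_youden"])
@pytest.mark.parametrize("seed", range(10))
def test_operating_point_matches_bruteforce(seed, criterion):
    rng = np.random.default_rng(seed)
    s = np.round(rng.normal(size=15), 1)
    y = rng.integers(0, 2, size=15)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    op = pick_operating_point(s, y, criterion)
    val, sens = best_threshold_bruteforce(s, y, criterion)
    got = op.f1 if criterion == "best_f1" else op.youden
    assert np.isclose(got, val)
    assert np.isclose(op.sensitivity, sens)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auroc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    s = rng.normal(size=30)
    y = rng.integers(0, 2, size=30)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    assert np.isclose(auroc(s, y), auroc(np.exp(2 * s) + 1, y))


def test_thresholds_lie_in_score_range_or_infinite():
    rng = np.random.default_rng(5)
    s = rng.normal(size=40)
    y = rng.integers(0, 2, size=40)
    for criterion in ("best_f1", "best_youden"):
        thr = pick_operating_point(s, y, criterion).threshold
        assert np.isinf(thr) or s.min() <= thr <= s.max()


def test_calibration_constant_probability_single_bin():
    p = np.full(200, 0.35)
    y = (np.arange(200) < 70).astype(int)  # prevalence 0.35
    curve = calibration_curve(p, y, n_bins=10)
    assert len(curve) == 1
    row = curve.iloc[0]
    assert np.isclose(row.mean_predicted, 0.35)
    assert np.isclose(row.observed_rate, 0.35)


def test_calibration_omits_empty_bins():
    p = np.array([0.05, 0.05, 0.95, 0.95])
    y = np.array([0, 0, 1, 1])
    curve = calibration_curve(p, y, n_bins=10)
    assert set(curve.bin) == {0, 9}


def test_evaluate_by_group_single_group_equals_global():
    rng = np.random.default_rng(2)
    s = rng.normal(size=50)
    y = rng.integers(0, 2, size=50)
    table = evaluate_by_group(s, y, ["all"] * 50)
    assert np.isclose(table.auroc.iloc[0], auroc(s, y))


def test_evaluate_by_group_marks_single_class_groups():
    s = np.array([0.2, 0.8, 0.3, 0.9])
    y = np.array([0, 1, 1, 1])
    g = np.array(["a", "a", "b", "b"])
    table = evaluate_by_group(s, y, g).set_index("group")
    assert table.loc["b", "note"] == NOT_ENOUGH_VARIATION
    assert np.isnan(table.loc["b", "auroc"])
    assert table.loc["a", "note"] == ""


def test_groupwise_confusion_counts_pool_to_global():
    rng = np.random.default_rng(3)
    p = rng.random(100)
    y = rng.integers(0, 2, size=100)
    g = rng.choice(["a", "b", "c"], size=100)
    thr = 0.5
    global_fp = np.sum((p > thr) & (y == 0))
    per_group = sum(
        np.sum((p[g == grp] > thr) & (y[g == grp] == 0)) for grp in ("a", "b", "c")
    )
    assert per_group == global_fp  # accounting identity behind the group table


class TestAttributeFalsePositives:
    def test_planted_annotation_error_rises_to_top(self):
        rng = np.random.default_rng(4)
        pids, probs, labels = [], [], []
        for i in range(20):
            pid = f"P{i}"
            truth = rng.integers(0, 2, size=10)
            p = np.clip(truth * 0.9 + rng.normal(0, 0.05, 10) + 0.05, 0, 1)
            lab = truth.copy()
            if pid == "P7":  # planted: labels inverted vs (correct) predictions
                lab = 1 - truth
            pids += [pid] * 10
            probs += list(p)
            labels += list(lab)
        table = attribute_false_positives(
            [f"d{i}" for i in range(len(probs))], pids, probs, labels, 0.5
        )
        assert table.iloc[0].patient_id == "P7"
        assert table.iloc[0].auroc_excluding > table.attrs["overall_auroc"]

    def test_fp_counts_sum_to_total(self):
        rng = np.random.default_rng(6)
        probs = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        pids = rng.choice(["a", "b", "c"], size=60)
        table = attribute_false_positives(
            [f"d{i}" for i in range(60)], pids, probs, labels, 0.4
        )
        assert table.false_positives.sum() == np.sum((probs > 0.4) & (labels == 0))

    def test_patient_without_fps_leaves_fp_count_unchanged(self):
        probs = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 0, 1, 0])
        pids = np.array(["a", "a", "b", "b"])
        table = attribute_false_positives(["1", "2", "3", "4"], pids, probs, labels, 0.5)
        t = table.set_index("patient_id")
        assert t.loc["b", "false_positives"] == 0
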