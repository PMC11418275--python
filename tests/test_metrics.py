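"""Detection metrics against brute-force oracles and closed-form cases."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlgyolo.boxes import iou_matrix
from mlgyolo.metrics import (average_precision, localization_errors,
                             match_predictions, precision, recall)


# ---------------------------------------------------------------------------
# precision / recall
# ---------------------------------------------------------------------------
def test_precision_examples():
    assert precision(5, 5) == pytest.approx(50.0)
    assert precision(0, 0) == 0.0                      # zero-denominator convention
    with pytest.raises(ValueError):
        precision(-1, 0)


def test_recall_examples():
    assert recall(9, 1) == pytest.approx(90.0)
    assert recall(0, 0) == 0.0
    with pytest.raises(ValueError):
        recall(3, -2)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------
def brute_force_ap(hits, n_gt, interpolated):
    """Independent PR-curve integration by explicit enumeration of ranks."""
    best = 0.0
    ap = 0.0
    tp = fp = 0
    prev_r = 0.0
    points = []
    for h in hits:
        tp, fp = tp + int(h), fp + int(not h)
        points.append((tp / n_gt, tp / (tp + fp)))
    if interpolated:
        for k, (r, p) in enumerate(points):
            points[k] = (r, max(q for rr, q in points[k:]))
    for r, p in points:
        ap += (r - prev_r) * p
        prev_r = r
    return 100.0 * ap


def _boxes_from_hits(hit_pattern):
    """One image; GT at disjoint slots, predictions at GT (hit) or far (miss)."""
    n_gt = sum(hit_pattern)
    gt = np.array([[10.0 * i, 0.0, 10.0 * i + 8, 8.0] for i in range(max(n_gt, 1))])
    preds = []
    gi = 0
    for rank, h in enumerate(hit_pattern):
        score = 1.0 - rank * 0.1
        if h:
            preds.append(("img", gt[gi], score))
            gi += 1
        else:
            preds.append(("img", np.array([500.0 + 20 * rank, 500, 508, 508]), score))
    return preds, {"img": gt}


def test_ap_perfect_predictions_is_100():
    gt = np.array([[0, 0, 10, 10], [20, 20, 40, 45], [100, 3, 130, 60]])
    preds = [("a", gt[i], s) for i, s in zip(range(3), (0.2, 0.9, 0.5))]
    assert average_precision(preds, {"a": gt}) == pytest.approx(100.0)


def test_ap_zero_predictions_is_0():
    assert average_precision([], {"a": np.array([[0, 0, 5, 5]])}) == 0.0


def test_ap_without_ground_truth_is_an_error():
    with pytest.raises(ValueError):
        average_precision([("a", np.array([0, 0, 5, 5]), 0.9)], {"a": np.zeros((0, 4))})


@pytest.mark.parametrize("interpolated", [True, False])
def test_ap_hand_case_hit_miss_hit_hit(interpolated):
    """3 GT, 4 ranked predictions (hit, miss, hit, hit): compare against the
    exhaustively enumerated PR staircase."""
    preds, gts = _boxes_from_hits([1, 0, 1, 1])
    expected = brute_force_ap([1, 0, 1, 1], 3, interpolated)
    got = average_precision(preds, gts, interpolated=interpolated)
    assert got == pytest.approx(expected, abs=1e-9)


@settings(derandomize=True, max_examples=40)
@given(seed=st.integers(0, 10_000))
def test_ap_matches_brute_force_on_random_cases(seed):
    """Random <=10-box single-image cases: the implementation must agree with
    an independent greedy-match + staircase integration to 1e-9."""
    rng = np.random.default_rng(seed)
    n_gt = int(rng.integers(1, 6))
    n_pred = int(rng.integers(0, 10))
    gt = np.sort(rng.uniform(0, 100, (n_gt, 4)), axis=-1)[:, [0, 2, 1, 3]]
    gt = np.stack([gt[:, 0], gt[:, 2], gt[:, 0] + np.maximum(gt[:, 1] - gt[:, 0], 1),
                   gt[:, 2] + np.maximum(gt[:, 3] - gt[:, 2], 1)], axis=1)
    preds = []
    for i in range(n_pred):
        if rng.uniform() < 0.6:
            j = int(rng.integers(n_gt))
            box = gt[j] + rng.normal(0, 2, 4)
            box = np.array([min(box[0], box[2] - 0.5), min(box[1], box[3] - 0.5),
                            max(box[2], box[0] + 0.5), max(box[3], box[1] + 0.5)])
        else:
            x, y = rng.uniform(0, 200, 2)
            box = np.array([x, y, x + rng.uniform(1, 30), y + rng.uniform(1, 30)])
        preds.append(("img", box, float(rng.uniform(0.01, 1))))
    # oracle: replay the documented greedy matching, then integrate
    scores = np.array([p[2] for p in preds])
    areas = np.array([(p[1][2] - p[1][0]) * (p[1][3] - p[1][1]) for p in preds])
    order = np.lexsort((np.arange(len(preds)), -areas, -scores))
    taken = np.zeros(n_gt, bool)
    hits = []
    for i in order:
        ious = iou_matrix(preds[i][1], gt)[0]
        ious[taken] = -1
        j = int(np.argmax(ious))
        ok = ious[j] >= 0.5
        hits.append(ok)
        if ok:
            taken[j] = True
    expected = brute_force_ap(hits, n_gt, interpolated=False) if hits else 0.0
    got = average_precision(preds, {"img": gt}, interpolated=False)
    assert got == pytest.approx(expected, abs=1e-9)


def test_ap_invariant_to_monotone_score_rescaling():
    preds, gts = _boxes_from_hits([1, 0, 1, 1, 0])
    a = average_precision(preds, gts)
    rescaled = [(i, b, 0.05 + 0.9 * s ** 3) for i, b, s in preds]
    assert average_precision(rescaled, gts) == pytest.approx(a, abs=1e-12)


def test_low_score_false_positive_never_increases_ap():
    for interp in (True, False):
        preds, gts = _boxes_from_hits([1, 1, 0, 1])
        base = average_precision(preds, gts, interpolated=interp)
        worse = preds + [("img", np.array([900.0, 900, 910, 910]), 0.001)]
        assert average_precision(worse, gts, interpolated=interp) <= base + 1e-12


def test_removing_true_positive_never_increases_recall():
    preds, gts = _boxes_from_hits([1, 1, 1])
    hits, n_gt = match_predictions(preds, gts)
    r_full = recall(int(hits.sum()), n_gt - int(hits.sum()))
    hits2, _ = match_predictions(preds[:-1], gts)
    r_less = recall(int(hits2.sum()), n_gt - int(hits2.sum()))
    assert r_less <= r_full


# ---------------------------------------------------------------------------
# localization error statistics
# ---------------------------------------------------------------------------
def test_mean_absolute_error_example():
    rep = localization_errors([[3, 3, 3], [-5, -5, -5], [4, 4, 4]])
    assert rep.mean_abs == pytest.approx((4.0, 4.0, 4.0))


def test_standard_error_example():
    # errors 1,2,3: s = 1, SE = 1/sqrt(3)
    rep = localization_errors([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
    assert rep.standard_error == pytest.approx((1 / np.sqrt(3),) * 3)


def test_zero_errors():
    rep = localization_errors(np.zeros((5, 3)))
    assert rep.mean_abs == (0.0, 0.0, 0.0)
    assert rep.standard_error == (0.0, 0.0, 0.0)


def test_standard_error_needs_two_points():
    with pytest.raises(ValueError):
        localization_errors([[1.0, 2.0, 3.0]])
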