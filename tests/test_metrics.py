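"""Metrics: confusion tallies, IoU/Dice closed forms, the mask-to-box
protocol, ranked AP hand cases plus a grid-integration oracle, and AUC
against Mann-Whitney pair counting."""

import dataclasses

import numpy as np
import pytest

from tomaformer.metrics import (InstanceBox, average_precision, box_iou,
                                confusion_matrix, iou_and_dice,
                                masks_to_instances, pixel_auc)


def test_confusion_perfect_prediction_is_diagonal(rng):
    truth = rng.integers(0, 4, size=(8, 8))
    cm = confusion_matrix(truth, truth)
    assert (cm == np.diag(np.bincount(truth.ravel(), minlength=4))).all()


def test_confusion_matches_explicit_tally(rng):
    pred = rng.integers(0, 4, size=(6, 7))
    truth = rng.integers(0, 4, size=(6, 7))
    cm = confusion_matrix(pred, truth)
    expected = np.zeros((4, 4), dtype=int)
    for r in range(6):
        for c in range(7):
            expected[truth[r, c], pred[r, c]] += 1
    assert (cm == expected).all()
    assert cm.sum() == 42


def test_confusion_rejects_bad_labels():
    with pytest.raises(ValueError):
        confusion_matrix(np.array([[4]]), np.array([[0]]))
    with pytest.raises(ValueError):
        confusion_matrix(np.zeros((2, 2), int), np.zeros((3, 3), int))


def test_iou_identical_masks_score_one(rng):
    truth = rng.integers(0, 4, size=(10, 10))
    classwise, miou, mdice = iou_and_dice(confusion_matrix(truth, truth))
    assert miou == pytest.approx(1.0) and mdice == pytest.approx(1.0)
    for cls in (1, 2, 3):
        if (truth == cls).any():
            assert classwise[cls] == pytest.approx(1.0)


def test_iou_disjoint_masks_score_zero():
    truth = np.full((4, 4), 1)
    pred = np.full((4, 4), 2)
    _, miou, mdice = iou_and_dice(confusion_matrix(pred, truth))
    assert miou == 0.0 and mdice == 0.0


def test_iou_shifted_square_closed_form():
    """A 4x4 class-1 square against a copy shifted by two columns overlaps
    on 8 of 24 pixels: IoU 1/3, Dice 1/2."""
    truth = np.zeros((8, 10), dtype=int)
    pred = np.zeros((8, 10), dtype=int)
    truth[2:6, 2:6] = 1
    pred[2:6, 4:8] = 1
    classwise, miou, mdice = iou_and_dice(confusion_matrix(pred, truth))
    assert classwise[1] == pytest.approx(1 / 3)
    assert miou == pytest.approx(1 / 3)
    assert mdice == pytest.approx(1 / 2)


def test_dice_is_harmonic_of_iou(rng):
    """Dice = 2*IoU / (1 + IoU) for every class, on random masks."""
    for _ in range(10):
        pred = rng.integers(0, 4, size=(12, 12))
        truth = rng.integers(0, 4, size=(12, 12))
        cm = confusion_matrix(pred, truth)
        tp = np.diag(cm).astype(float)
        fp, fn = cm.sum(axis=0) - tp, cm.sum(axis=1) - tp
        present = [c for c in (1, 2, 3) if tp[c] + fp[c] + fn[c] > 0]
        iou = np.array([tp[c] / (tp[c] + fp[c] + fn[c]) for c in present])
        _, _, mdice = iou_and_dice(cm)
        assert mdice == pytest.approx(np.mean(2 * iou / (1 + iou)))


def test_masks_to_instances_rectangle_and_score():
    mask = np.zeros((10, 10), dtype=int)
    mask[2:5, 3:8] = 2
    probs = np.full((10, 10, 4), 0.05)
    probs[2:5, 3:8, 2] = 0.8
    (box,) = masks_to_instances(mask, probs)
    assert (box.class_label, box.row_min, box.col_min, box.row_max, box.col_max) \
        == (2, 2, 3, 4, 7)
    assert box.score == pytest.approx(0.8)
    assert box.area == 3 * 5


def test_masks_to_instances_empty_mask():
    assert masks_to_instances(np.zeros((8, 8), dtype=int)) == []


def test_masks_to_instances_connectivity_choice():
    """A diagonal pair of pixels is one component under 8-connectivity but
    two under 4-connectivity; verified against a flood-fill oracle."""
    mask = np.zeros((6, 6), dtype=int)
    mask[1, 1] = 1
    mask[2, 2] = 1
    assert len(masks_to_instances(mask, connectivity=8)) == 1
    assert len(masks_to_instances(mask, connectivity=4)) == 2

    def flood_count(binary, neighbors):
        seen, count = set(), 0
        for start in zip(*np.nonzero(binary)):
            if start in seen:
                continue
            count += 1
            stack = [start]
            while stack:
                r, c = stack.pop()
                if (r, c) in seen:
                    continue
                seen.add((r, c))
                for dr, dc in neighbors:
                    p = (r + dr, c + dc)
                    if 0 <= p[0] < 6 and 0 <= p[1] < 6 and binary[p] \
                            and p not in seen:
                        stack.append(p)
        return count

    n4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n8 = n4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    assert flood_count(mask == 1, n8) == 1
    assert flood_count(mask == 1, n4) == 2


def test_masks_to_instances_rejects_bad_args():
    with pytest.raises(ValueError):
        masks_to_instances(np.zeros((4, 4), int), connectivity=6)
    with pytest.raises(ValueError):
        masks_to_instances(np.zeros((4, 4), int), probs=np.zeros((5, 5, 4)))


def test_box_iou_closed_forms():
    a = InstanceBox(1, 0, 0, 3, 3)       # 4x4 = 16 px
    b = InstanceBox(1, 0, 2, 3, 5)       # shifted: overlap 4x2 = 8
    assert box_iou(a, a) == 1.0
    assert box_iou(a, b) == pytest.approx(8 / 24)
    assert box_iou(a, InstanceBox(1, 10, 10, 12, 12)) == 0.0


def test_ap_perfect_detection_is_one():
    gt = [InstanceBox(1, 0, 0, 5, 5), InstanceBox(1, 10, 10, 15, 15)]
    preds = [InstanceBox(1, 0, 0, 5, 5, score=0.9),
             InstanceBox(1, 10, 10, 15, 15, score=0.8)]
    per_class, mean_ap = average_precision(preds, gt)
    assert per_class[1] == pytest.approx(1.0) and mean_ap == pytest.approx(1.0)


def test_ap_no_predictions_is_zero():
    gt = [InstanceBox(1, 0, 0, 5, 5)]
    per_class, mean_ap = average_precision([], gt)
    assert per_class[1] == 0.0 and mean_ap == 0.0


def test_ap_unscoreable_returns_none():
    assert average_precision([], []) == ({}, None)
    # predictions without any ground truth are also unscoreable
    assert average_precision([InstanceBox(1, 0, 0, 2, 2)], []) == ({}, None)


def test_ap_hand_ranked_cases():
    gt = [InstanceBox(1, 0, 0, 5, 5)]
    far = InstanceBox(1, 20, 20, 25, 25, score=0.0)

    # [match, miss, duplicate] in score order: AP stays 1.0
    preds = [InstanceBox(1, 0, 0, 5, 5, score=0.9),
             InstanceBox(1, 20, 20, 25, 25, score=0.8),
             InstanceBox(1, 0, 0, 5, 5, score=0.7)]
    assert average_precision(preds, gt)[0][1] == pytest.approx(1.0)

    # [miss, match]: the hit arrives at rank 2 -> precision 1/2 at recall 1
    preds = [InstanceBox(1, 20, 20, 25, 25, score=0.9),
             InstanceBox(1, 0, 0, 5, 5, score=0.8)]
    assert average_precision(preds, gt)[0][1] == pytest.approx(0.5)

    # two GT, hits at ranks 1 and 3: AP = 0.5*1 + 0.5*(2/3)
    gt2 = [InstanceBox(1, 0, 0, 5, 5), InstanceBox(1, 10, 10, 15, 15)]
    preds = [InstanceBox(1, 0, 0, 5, 5, score=0.9),
             dataclasses.replace(far, score=0.8),
             InstanceBox(1, 10, 10, 15, 15, score=0.7)]
    assert average_precision(preds, gt2)[0][1] == pytest.approx(0.5 + 0.5 * 2 / 3)

    # matching never crosses image ids
    preds = [InstanceBox(1, 0, 0, 5, 5, score=0.9, image_id=1)]
    assert average_precision(preds, gt)[0][1] == 0.0


def _ap_grid_oracle(tp_flags, n_gt, grid=100_000):
    """Numerically integrate max precision at recall >= r over a fine grid."""
    cum = np.cumsum(tp_flags)
    recall = cum / n_gt
    precision = cum / np.arange(1, len(tp_flags) + 1)
    rs = np.linspace(0, 1, grid, endpoint=False) + 0.5 / grid
    total = 0.0
    for r in rs:
        feasible = precision[recall >= r]
        total += feasible.max() if feasible.size else 0.0
    return total / grid


def test_ap_matches_grid_integration_oracle(rng):
    """Random detection outcomes: closed-form all-point AP equals the
    numeric integral of the precision envelope."""
    for _ in range(8):
        n_gt = int(rng.integers(2, 6))
        n_pred = int(rng.integers(2, 10))
        # synthesize sorted-by-score TP/FP flags with at most n_gt hits
        flags = np.zeros(n_pred)
        hits = rng.choice(n_pred, size=min(n_gt, int(rng.integers(1, n_pred + 1))),
                          replace=False)
        flags[hits] = 1.0
        # build geometry realizing exactly those flags: hits get their own
        # GT box, misses land far away
        gt, preds = [], []
        for g in range(n_gt):
            gt.append(InstanceBox(1, 100 * g, 0, 100 * g + 5, 5))
        hit_iter = iter(range(n_gt))
        for rank, f in enumerate(flags):
            score = 1.0 - rank / n_pred
            if f:
                g = next(hit_iter)
                preds.append(InstanceBox(1, 100 * g, 0, 100 * g + 5, 5, score=score))
            else:
                preds.append(InstanceBox(1, 10_000 + 100 * rank, 0,
                                         10_005 + 100 * rank, 5, score=score))
        per_class, _ = average_precision(preds, gt)
        assert per_class[1] == pytest.approx(_ap_grid_oracle(flags, n_gt),
                                             abs=1e-3)


def test_ap_adding_low_scored_false_positive_never_raises_ap():
    gt = [InstanceBox(1, 0, 0, 5, 5)]
    preds = [InstanceBox(1, 0, 0, 5, 5, score=0.9)]
    base = average_precision(preds, gt)[0][1]
    worse = preds + [InstanceBox(1, 50, 50, 55, 55, score=0.1)]
    assert average_precision(worse, gt)[0][1] <= base


def test_auc_perfect_and_inverted():
    truth = np.array([[0, 0], [1, 1]])
    probs = np.zeros((2, 2, 4))
    probs[..., 1] = [[0.1, 0.2], [0.8, 0.9]]
    assert pixel_auc(probs, truth) == pytest.approx(1.0)
    probs[..., 1] = [[0.8, 0.9], [0.1, 0.2]]
    assert pixel_auc(probs, truth) == pytest.approx(0.0)


def test_auc_matches_mann_whitney_pair_counting(rng):
    truth = rng.integers(0, 2, size=(8, 8))   # labels 0 and 1 only
    probs = np.zeros((8, 8, 4))
    probs[..., 1] = rng.choice([0.1, 0.3, 0.5, 0.7], size=(8, 8))  # ties occur
    auc = pixel_auc(probs, truth)
    pos = probs[..., 1][truth == 1].ravel()
    neg = probs[..., 1][truth == 0].ravel()
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert auc == pytest.approx(wins / (len(pos) * len(neg)))


def test_auc_none_when_unscoreable():
    assert pixel_auc(np.zeros((4, 4, 4)), np.zeros((4, 4), dtype=int)) is None
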