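"""IoU, NMS, matching, COCO-style AP/AR, confusion matrix, oracle detector.

Brute-force oracles: IoU by pixel-grid counting, NMS by an O(n^2) reference,
AP by exhaustive precision-recall construction.
"""

import itertools
import math

import numpy as np
import pytest

from benthofind import (DetectionRecord, GroundTruth, confusion_matrix,
                        evaluate, greedy_nms, iou, oracle_detector)
from benthofind.detection_eval import (AREA_RANGES, RECALL_POINTS,
                                       average_precision, average_recall,
                                       match_detections)


def det(scene, box, label="a", conf=0.9):
    return DetectionRecord(scene, box, label, conf)


def gt(scene, box, label="a"):
    return GroundTruth(scene, box, label)


def pixel_iou(box_a, box_b) -> float:
    """Brute-force IoU by counting integer pixel cells."""
    xs = range(int(min(box_a[0], box_b[0])), int(max(box_a[2], box_b[2])))
    ys = range(int(min(box_a[1], box_b[1])), int(max(box_a[3], box_b[3])))
    inter = union = 0
    for x, y in itertools.product(xs, ys):
        in_a = box_a[0] <= x < box_a[2] and box_a[1] <= y < box_a[3]
        in_b = box_b[0] <= x < box_b[2] and box_b[1] <= y < box_b[3]
        inter += in_a and in_b
        union += in_a or in_b
    return inter / union if union else 0.0


def brute_force_ap(conf_tp: list[tuple[float, bool]], n_truth: int) -> float:
    """101-point AP from (confidence, is-TP) pairs via direct construction."""
    pairs = sorted(conf_tp, key=lambda p: -p[0])
    tp = fp = 0
    pr = []
    for _, is_tp in pairs:
        tp += is_tp
        fp += not is_tp
        pr.append((tp / n_truth, tp / (tp + fp)))
    total = 0.0
    for r in RECALL_POINTS:
        best = max((p for rec, p in pr if rec >= r), default=0.0)
        total += best
    return total / len(RECALL_POINTS)


class TestIou:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_partial_overlap_closed_form(self):
        assert iou((0, 0, 10, 10), (5, 5, 15, 15)) == pytest.approx(1 / 7)

    def test_symmetry_and_pixel_counting_oracle(self, rng):
        for _ in range(20):
            a = np.sort(rng.integers(0, 30, size=4).reshape(2, 2), axis=0)
            b = np.sort(rng.integers(0, 30, size=4).reshape(2, 2), axis=0)
            box_a = (a[0, 0], a[0, 1], a[1, 0] + 1, a[1, 1] + 1)
            box_b = (b[0, 0], b[0, 1], b[1, 0] + 1, b[1, 1] + 1)
            assert iou(box_a, box_b) == pytest.approx(iou(box_b, box_a))
            assert iou(box_a, box_b) == pytest.approx(pixel_iou(box_a, box_b))


class TestGreedyNms:
    def test_overlapping_pair_keeps_highest(self):
        d = [det("s", (0, 0, 10, 10), conf=0.9), det("s", (1, 1, 11, 11), conf=0.8)]
        assert iou(d[0].bbox, d[1].bbox) == pytest.approx(81 / 119)
        kept = greedy_nms(d, 0.5)
        assert [k.confidence for k in kept] == [0.9]

    def test_disjoint_boxes_both_kept(self):
        d = [det("s", (0, 0, 10, 10)), det("s", (20, 20, 30, 30))]
        assert len(greedy_nms(d)) == 2

    def test_equal_confidence_identical_boxes_keep_one(self):
        d = [det("s", (0, 0, 10, 10), conf=0.7), det("s", (0, 0, 10, 10), conf=0.7)]
        kept = greedy_nms(d)
        assert kept == [d[0]]  # earliest-index tie-break

    def test_different_classes_not_suppressed(self):
        d = [det("s", (0, 0, 10, 10), "a", 0.9), det("s", (0, 0, 10, 10), "b", 0.8)]
        assert len(greedy_nms(d)) == 2

    def test_matches_quadratic_reference(self, rng):
        def reference_nms(dets, thr):
            order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
            kept = []
            for i in order:
                if all(dets[j].label != dets[i].label
                       or iou(dets[i].bbox, dets[j].bbox) <= thr for j in kept):
                    kept.append(i)
            return sorted(kept)

        for _ in range(20):
            dets = []
            for k in range(12):
                x0, y0 = rng.uniform(0, 40, size=2)
                w, h = rng.uniform(5, 20, size=2)
                dets.append(det("s", (x0, y0, x0 + w, y0 + h),
                                label=rng.choice(["a", "b"]),
                                conf=float(rng.uniform())))
            assert (greedy_nms(dets, 0.4)
                    == [dets[i] for i in reference_nms(dets, 0.4)])


class TestMatchDetections:
    def test_perfect_detection(self):
        m, fd, ft = match_detections([det("s", (0, 0, 10, 10))],
                                     [gt("s", (0, 0, 10, 10))])
        assert (len(m), len(fd), len(ft)) == (1, 0, 0)

    def test_duplicate_detection_is_false_positive(self):
        m, fd, ft = match_detections(
            [det("s", (0, 0, 10, 10), conf=0.9), det("s", (0, 0, 10, 10), conf=0.8)],
            [gt("s", (0, 0, 10, 10))])
        assert (len(m), len(fd), len(ft)) == (1, 1, 0)

    def test_no_detections_all_false_negatives(self):
        m, fd, ft = match_detections([], [gt("s", (0, 0, 5, 5))] * 3)
        assert (len(m), len(fd), len(ft)) == (0, 0, 3)

    def test_scene_and_class_respected(self):
        m, _, ft = match_detections([det("s1", (0, 0, 10, 10), "a")],
                                    [gt("s2", (0, 0, 10, 10), "a"),
                                     gt("s1", (0, 0, 10, 10), "b")])
        assert len(m) == 0 and len(ft) == 2


class TestAveragePrecision:
    def test_tp_before_fp_gives_ap_one(self):
        dets = [det("s", (0, 0, 10, 10), conf=0.9),
                det("s", (30, 30, 40, 40), conf=0.8)]
        _, ap = average_precision(dets, [gt("s", (0, 0, 10, 10))],
                                  iou_thresholds=[0.5])
        assert ap == pytest.approx(1.0)

    def test_fp_before_tp_gives_ap_half(self):
        dets = [det("s", (30, 30, 40, 40), conf=0.9),
                det("s", (0, 0, 10, 10), conf=0.8)]
        _, ap = average_precision(dets, [gt("s", (0, 0, 10, 10))],
                                  iou_thresholds=[0.5])
        assert ap == pytest.approx(0.5)

    def test_no_detections_ap_zero(self):
        _, ap = average_precision([], [gt("s", (0, 0, 10, 10))],
                                  iou_thresholds=[0.5])
        assert ap == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        """>= 20 random small instances agree with the exhaustive PR oracle
        to 1e-6 (single class, IoU 0.5)."""
        for trial in range(25):
            truths = [gt("s", tuple(b))
                      for b in _random_boxes(rng, rng.integers(1, 6))]
            dets = [det("s", tuple(b), conf=float(rng.uniform()))
                    for b in _random_boxes(rng, rng.integers(0, 10))]
            _, ap = average_precision(dets, truths, iou_thresholds=[0.5])
            # oracle: replay the same greedy confidence-ordered matching
            order = sorted(dets, key=lambda d: -d.confidence)
            unmatched = list(truths)
            conf_tp = []
            for d in order:
                best, bi = None, 0.0
                for t in unmatched:
                    i = iou(d.bbox, t.bbox)
                    if i >= 0.5 and i > bi:
                        best, bi = t, i
                if best is not None:
                    unmatched.remove(best)
                conf_tp.append((d.confidence, best is not None))
            expected = brute_force_ap(conf_tp, len(truths)) if dets else 0.0
            assert ap == pytest.approx(expected, abs=1e-6), f"trial {trial}"

    def test_translation_invariance(self, rng):
        truths = [gt("s", tuple(b)) for b in _random_boxes(rng, 5)]
        dets = [det("s", tuple(b), conf=float(rng.uniform()))
                for b in _random_boxes(rng, 8)]
        shift = lambda b: (b[0] + 500, b[1] - 300, b[2] + 500, b[3] - 300)
        truths2 = [gt("s", shift(t.bbox)) for t in truths]
        dets2 = [det("s", shift(d.bbox), conf=d.confidence) for d in dets]
        assert (evaluate(dets, truths).as_dict()
                == pytest.approx(evaluate(dets2, truths2).as_dict(), nan_ok=True))


def _random_boxes(rng, n):
    boxes = []
    for _ in range(int(n)):
        x0, y0 = rng.uniform(0, 50, size=2)
        w, h = rng.uniform(4, 25, size=2)
        boxes.append((x0, y0, x0 + w, y0 + h))
    return boxes


class TestSizeStrataAndRecall:
    def test_empty_strata_are_undefined_not_zero(self):
        truths = [gt("s", (0, 0, 10, 10))]  # area 100 < 32^2: small only
        dets = [det("s", (0, 0, 10, 10))]
        summary = evaluate(dets, truths)
        assert math.isnan(summary.AP_medium) and math.isnan(summary.AP_large)
        assert summary.AP_small == pytest.approx(100.0)

    def test_perfect_detector_ar100(self):
        truths = [gt("s", (i * 50, 0, i * 50 + 40, 40)) for i in range(3)]
        dets = [det("s", t.bbox, conf=1.0) for t in truths]
        assert average_recall(dets, truths, max_dets=100) == pytest.approx(1.0)

    def test_ar_monotone_in_max_dets(self, rng):
        truths = [gt("s", tuple(b)) for b in _random_boxes(rng, 8)]
        dets = [det("s", tuple(b), conf=float(rng.uniform()))
                for b in _random_boxes(rng, 20)]
        dets += [det("s", t.bbox, conf=float(rng.uniform())) for t in truths[:4]]
        ars = [average_recall(dets, truths, max_dets=k) for k in (1, 10, 100)]
        assert ars[0] <= ars[1] <= ars[2]


class TestConfusionMatrix:
    def test_wrong_label_counts_off_diagonal(self):
        mat, names = confusion_matrix([det("s", (0, 0, 10, 10), "b")],
                                      [gt("s", (0, 0, 10, 10), "a")],
                                      labels=["a", "b"])
        assert mat[names.index("a"), names.index("b")] == 1

    def test_missed_truth_goes_to_background_column(self):
        mat, names = confusion_matrix([], [gt("s", (0, 0, 10, 10), "a")],
                                      labels=["a"])
        assert mat[names.index("a"), -1] == 1

    def test_row_sums_conserve_truth_counts(self, rng):
        labels = ["a", "b", "c"]
        truths = [gt("s", tuple(b), label=str(rng.choice(labels)))
                  for b in _random_boxes(rng, 10)]
        dets = [det("s", tuple(b), label=str(rng.choice(labels)),
                    conf=float(rng.uniform())) for b in _random_boxes(rng, 12)]
        mat, names = confusion_matrix(dets, truths, labels=labels)
        for i, lbl in enumerate(labels):
            assert mat[i].sum() == sum(t.label == lbl for t in truths)


class TestOracleDetector:
    def _truths(self, n, scene="s"):
        return [gt(scene, (10 * i, 10, 10 * i + 8, 18)) for i in range(n)]

    def test_zero_noise_is_identity_with_full_ap(self):
        truths = self._truths(5)
        dets = oracle_detector(truths, seed=0)
        assert [(d.bbox, d.label, d.confidence) for d in dets] == \
               [(t.bbox, t.label, 1.0) for t in truths]
        assert evaluate(dets, truths).AP50 == pytest.approx(100.0)

    def test_full_miss_rate_detects_nothing(self):
        dets = oracle_detector(self._truths(10), miss_rate=1.0, seed=0)
        assert dets == []

    def test_miss_rate_recall_within_binomial_bounds(self):
        truths = [gt(f"s{i}", (5, 5, 20, 20)) for i in range(1000)]
        dets = oracle_detector(truths, miss_rate=0.2, seed=3)
        recall = len(dets) / len(truths)
        assert abs(recall - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / 1000)

    def test_label_confusion_applied(self):
        truths = [gt(f"s{i}", (0, 0, 10, 10), "a") for i in range(500)]
        dets = oracle_detector(truths, label_confusion={"a": {"a": 0.5, "b": 0.5}},
                               seed=1)
        frac_b = sum(d.label == "b" for d in dets) / len(dets)
        assert abs(frac_b - 0.5) <= 3 * math.sqrt(0.25 / 500)
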