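"""Weak-annotation filtering, labeling, splitting and export."""

import numpy as np
import pytest

from benthofind import (AnnotationRecord, AnomalyResult, LabelSet,
                        SuperpixelPatch, assign_labels, classifier_filter,
                        review_queue, split_annotations, threshold_filter,
                        train_patch_classifier)
from benthofind.errors import ArgumentError
from benthofind.weak_annotations import (UNLABELED, read_annotations_csv,
                                         write_annotations_coco,
                                         write_annotations_csv)
from conftest import make_colored_patches


def results(scores):
    return [AnomalyResult(f"p{i:02d}", s) for i, s in enumerate(scores)]


def patch(pid_num, bbox=(0, 0, 10, 10), color=0.5, scene="sc0"):
    return SuperpixelPatch(parent_id=scene, segment_id=pid_num, bbox=bbox,
                           patch=np.full((32, 32, 3), color, dtype=np.float32),
                           area=64)


class TestThresholdFilter:
    def test_linear_interpolation_quantile(self):
        # percentile 75 of {1,2,3,4} = 3.25; only the 4 exceeds it
        res = results([1.0, 2.0, 3.0, 4.0])
        assert threshold_filter(res, 75) == ["p03"]

    def test_tiny_percentile_keeps_all_but_minimum(self):
        res = results([0.1, 0.5, 0.9])
        assert threshold_filter(res, 1e-9) == ["p01", "p02"]

    def test_equal_scores_retain_nothing(self):
        assert threshold_filter(results([0.5] * 8), 75) == []

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            threshold_filter([], 75)


class TestPatchClassifier:
    def test_separable_toy_fixture_high_accuracy(self):
        reds = make_colored_patches(64, (0.9, 0.1, 0.1), 0.08, seed=1)
        grays = make_colored_patches(64, (0.5, 0.5, 0.5), 0.08, seed=2)
        clf = train_patch_classifier(reds[:48], grays[:48], seed=0)
        p_pos = clf.predict_proba(reds[48:])
        p_neg = clf.predict_proba(grays[48:])
        acc = (np.sum(p_pos >= 0.5) + np.sum(p_neg < 0.5)) / 32
        assert acc >= 0.95

    def test_probabilities_in_unit_interval(self):
        reds = make_colored_patches(16, (0.9, 0.1, 0.1), 0.05)
        grays = make_colored_patches(16, (0.4, 0.4, 0.4), 0.05)
        clf = train_patch_classifier(reds, grays, seed=0)
        p = clf.predict_proba(reds + grays)
        assert (p >= 0).all() and (p <= 1).all()

    def test_duplicate_patch_in_both_classes_tolerated(self):
        shared = make_colored_patches(8, (0.6, 0.6, 0.6), 0.05)
        reds = make_colored_patches(8, (0.9, 0.1, 0.1), 0.05)
        clf = train_patch_classifier(reds + shared, shared + reds[:8], seed=0)
        assert clf.predict_proba(shared).shape == (8,)

    def test_too_few_examples_rejected(self):
        a = make_colored_patches(4, (0.9, 0.1, 0.1), 0.05)
        b = make_colored_patches(8, (0.5, 0.5, 0.5), 0.05)
        with pytest.raises(ArgumentError):
            train_patch_classifier(a, b)


class _ConstantClassifier:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, patches):
        return np.full(len(patches), self.p)


class TestClassifierFilter:
    def test_accept_all_passes_every_patch_through(self):
        pats = [patch(i, bbox=(i, 0, i + 5, 5)) for i in range(4)]
        scores = {p.patch_id: 0.8 for p in pats}
        recs = classifier_filter(_ConstantClassifier(1.0), pats, scores)
        assert len(recs) == 4
        assert all(r.label == UNLABELED and r.source == "weak" for r in recs)
        assert all(r.anomaly_score == 0.8 for r in recs)

    def test_reject_all_yields_empty(self):
        pats = [patch(i) for i in range(4)]
        assert classifier_filter(_ConstantClassifier(0.0), pats) == []

    def test_no_box_invention(self):
        pats = [patch(i, bbox=(2 * i, 1, 2 * i + 6, 8)) for i in range(5)]
        recs = classifier_filter(_ConstantClassifier(1.0), pats)
        assert {r.bbox for r in recs} <= {p.bbox for p in pats}


class TestReviewQueue:
    def test_descending_score_order(self):
        res = results([0.2, 0.9, 0.5])
        assert review_queue(res) == ["p01", "p02", "p00"]

    def test_ties_by_patch_id(self):
        assert review_queue(results([0.5, 0.5, 0.5])) == ["p00", "p01", "p02"]

    def test_is_permutation(self):
        res = results([0.3, 0.1, 0.8, 0.4])
        assert sorted(review_queue(res)) == sorted(r.patch_id for r in res)


class TestAssignLabels:
    def _rec(self, scene="sc0", bbox=(0, 0, 5, 5)):
        return AnnotationRecord(scene_id=scene, bbox=bbox)

    def test_label_attached_source_stays_weak(self):
        rec = self._rec()
        out = assign_labels([rec], {rec.record_id: "ophiuroid"})
        assert out[0].label == "ophiuroid" and out[0].source == "weak"

    def test_unknown_label_lists_allowed_names(self):
        rec = self._rec()
        with pytest.raises(ArgumentError, match="kraken"):
            assign_labels([rec], {rec.record_id: "kraken"})

    def test_manual_record_keeps_provenance(self):
        rec = AnnotationRecord("sc0", (1, 1, 9, 9), label="sponge", source="manual")
        out = assign_labels([rec], {})
        assert out[0].source == "manual" and out[0].label == "sponge"

    def test_drop_unlabeled_flag(self):
        recs = [self._rec(bbox=(0, 0, 5, 5)), self._rec(bbox=(5, 5, 9, 9))]
        table = {recs[0].record_id: "coral"}
        assert len(assign_labels(recs, table, drop_unlabeled=True)) == 1

    def test_label_set_uniqueness_enforced(self):
        with pytest.raises(ArgumentError):
            LabelSet(names=("a", "a"))


class TestSplitAnnotations:
    def _records(self, n, scenes=None):
        out = []
        for i in range(n):
            scene = scenes[i % len(scenes)] if scenes else f"sc{i}"
            out.append(AnnotationRecord(scene, (i, 0, i + 4, 4), label="coral"))
        return out

    def test_floor_arithmetic_on_ungrouped_records(self):
        # 2118 records, one per scene: 90/10 split -> 1906 / 212
        train, val = split_annotations(self._records(2118), 0.9, seed=0)
        assert (len(train), len(val)) == (1906, 212)

    def test_seeded_reproducibility(self):
        recs = self._records(50)
        a = split_annotations(recs, 0.9, seed=3)
        b = split_annotations(recs, 0.9, seed=3)
        assert a == b

    def test_partition_property(self):
        recs = self._records(40, scenes=[f"s{i}" for i in range(10)])
        train, val = split_annotations(recs, 0.8, seed=1)
        key = lambda r: (r.scene_id, r.bbox)
        assert sorted(map(key, train + val)) == sorted(map(key, recs))
        assert not ({key(r) for r in train} & {key(r) for r in val})

    def test_no_scene_on_both_sides(self):
        recs = self._records(60, scenes=[f"s{i}" for i in range(12)])
        train, val = split_annotations(recs, 0.9, seed=2)
        assert not ({r.scene_id for r in train} & {r.scene_id for r in val})

    def test_single_scene_rejected(self):
        with pytest.raises(ArgumentError):
            split_annotations(self._records(5, scenes=["only"]), 0.9, seed=0)


class TestAnnotationIO:
    def test_csv_roundtrip(self, tmp_path):
        recs = [AnnotationRecord("sc0", (1, 2, 11, 12), "sponge", "weak", 0.77),
                AnnotationRecord("sc1", (3, 4, 13, 14), "coral", "manual", None)]
        path = write_annotations_csv(recs, tmp_path / "ann.csv")
        assert read_annotations_csv(path) == recs

    def test_coco_export_structure(self, tmp_path):
        import json
        recs = [AnnotationRecord("sc0", (1, 2, 11, 12), "sponge", "weak", 0.5)]
        path = write_annotations_coco(recs, tmp_path / "ann.json")
        coco = json.loads(path.read_text())
        assert {c["name"] for c in coco["categories"]} >= {"sponge"}
        ann = coco["annotations"][0]
        assert ann["bbox"] == [1, 2, 10, 10]
        assert ann["area"] == 100
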