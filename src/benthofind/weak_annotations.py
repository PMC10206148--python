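"""Weak bounding-box annotations from flagged anomalous superpixels.

The boxes of superpixels flagged by the isolation forest are proposed as weak
annotations after false-positive removal, by either (a) a percentile
threshold on the anomaly scores, or (b) a small trainable binary patch
classifier (the strategy the workflow prefers: thresholding retains laser
points and dark water-column patches that score high but are not fauna).
Labeling, scene-grouped train/validation splitting, and CSV/COCO export
round out the data contract of the downstream detector.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.neural_network import MLPClassifier

from .errors import ArgumentError
from .iforest import AnomalyResult
from .superpixels import SuperpixelPatch

UNLABELED = "UNLABELED"

#: The ten morphotype classes used for semantic labeling.
DEFAULT_MORPHOTYPES = (
    "anemone", "coral", "fish", "gastropod", "holothurian",
    "ophiuroid", "sea urchin", "shrimp", "sponge", "xenophyophore",
)


@dataclass(frozen=True)
class LabelSet:
    names: tuple[str, ...] = DEFAULT_MORPHOTYPES

    def __post_init__(self) -> None:
        if not self.names:
            raise ArgumentError("label set must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ArgumentError("label set names must be unique")

    def validate(self, label: str) -> None:
        if label != UNLABELED and label not in self.names:
            raise ArgumentError(
                f"unknown label {label!r}; allowed: {sorted(self.names)}")


@dataclass
class AnnotationRecord:
    scene_id: str
    bbox: tuple[int, int, int, int]
    label: str = UNLABELED
    source: str = "weak"  # weak | manual
    anomaly_score: float | None = None

    @property
    def record_id(self) -> str:
        return f"{self.scene_id}:{self.bbox[0]}:{self.bbox[1]}:{self.bbox[2]}:{self.bbox[3]}"


def threshold_filter(results: Sequence[AnomalyResult], percentile: float = 75.0) -> list[str]:
    """Patch ids whose score strictly exceeds the given score percentile.

    The percentile is the linear-interpolation quantile of the score vector;
    if all scores are equal the retained set is empty (strict inequality).
    """
    if not results:
        raise ArgumentError("results must be non-empty")
    if not (0 < percentile < 100):
        raise ArgumentError(f"percentile must be in (0, 100), got {percentile}")
    scores = np.array([r.score for r in results])
    thr = np.percentile(scores, percentile)
    return [r.patch_id for r in results if r.score > thr]


class PatchClassifier:
    """Binary fauna / not-fauna classifier over square patches.

    Any object with a ``predict_proba(patches) -> array in [0,1]`` contract
    can stand in; this implementation downsamples each patch to 16x16 RGB and
    feeds the flattened pixels to a small multilayer perceptron.
    """

    _FEAT_SIDE = 16

    def __init__(self, epochs: int = 300, learning_rate: float = 1e-3, seed: int = 0):
        self._mlp = MLPClassifier(hidden_layer_sizes=(64,), max_iter=epochs,
                                  learning_rate_init=learning_rate,
                                  random_state=seed, early_stopping=False)

    def _features(self, patches: Sequence) -> np.ndarray:
        rows = []
        for p in patches:
            a = p.patch if hasattr(p, "patch") else np.asarray(p)
            small = resize(a, (self._FEAT_SIDE, self._FEAT_SIDE), order=1,
                           preserve_range=True, anti_aliasing=False)
            rows.append(small.ravel())
        return np.asarray(rows, dtype=np.float64)

    def fit(self, positives: Sequence, negatives: Sequence) -> "PatchClassifier":
        x = np.vstack([self._features(positives), self._features(negatives)])
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
            self._mlp.fit(x, y)
        return self

    def predict_proba(self, patches: Sequence) -> np.ndarray:
        proba = self._mlp.predict_proba(self._features(patches))
        idx = list(self._mlp.classes_).index(1.0)
        return proba[:, idx]


def train_patch_classifier(positives: Sequence, negatives: Sequence,
                           epochs: int = 300, learning_rate: float = 1e-3,
                           seed: int = 0) -> PatchClassifier:
    """Train the false-positive-removal classifier on example patches.

    Positives are truly anomalous (fauna) patches, negatives are background /
    distractor patches; in practice both are picked quickly from the
    score-sorted review queue.  Requires at least 8 examples per class.
    """
    if len(positives) < 8 or len(negatives) < 8:
        raise ArgumentError(
            f"need >= 8 examples per class, got {len(positives)} positive / "
            f"{len(negatives)} negative")
    return PatchClassifier(epochs=epochs, learning_rate=learning_rate, seed=seed).fit(
        positives, negatives)


def classifier_filter(classifier, flagged_patches: Sequence[SuperpixelPatch],
                      scores: Mapping[str, float] | None = None,
                      prob_cutoff: float = 0.5) -> list[AnnotationRecord]:
    """Weak annotations for flagged patches the classifier accepts.

    Each retained patch contributes exactly one record with the superpixel's
    own bbox (no box invention) and its anomaly score carried through.
    """
    if not flagged_patches:
        return []
    proba = classifier.predict_proba(flagged_patches)
    records = []
    for patch, p in zip(flagged_patches, proba):
        if p >= prob_cutoff:
            sc = scores.get(patch.patch_id) if scores else None
            records.append(AnnotationRecord(scene_id=patch.parent_id,
                                            bbox=patch.bbox,
                                            anomaly_score=sc))
    return records


def review_queue(results: Sequence[AnomalyResult]) -> list[str]:
    """Patch ids in descending score order (ties by id) for manual review."""
    if not results:
        raise ArgumentError("results must be non-empty")
    return [r.patch_id for r in sorted(results, key=lambda r: (-r.score, r.patch_id))]


def assign_labels(records: Sequence[AnnotationRecord],
                  label_table: Mapping[str, str],
                  label_set: LabelSet | None = None,
                  drop_unlabeled: bool = False) -> list[AnnotationRecord]:
    """Attach morphotype labels from a record-id -> label table.

    Unknown label names raise an error listing the allowed names.  Records
    absent from the table stay UNLABELED and are dropped when
    ``drop_unlabeled`` is set.
    """
    label_set = label_set or LabelSet()
    for lbl in label_table.values():
        label_set.validate(lbl)
    out = []
    for rec in records:
        lbl = label_table.get(rec.record_id)
        if lbl is not None:
            out.append(replace(rec, label=lbl))
        elif not drop_unlabeled:
            out.append(rec)
    return out


def split_annotations(records: Sequence[AnnotationRecord],
                      train_fraction: float = 0.9,
                      seed: int = 0) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Scene-grouped train/validation split.

    Scenes are shuffled and assigned whole to the training side until it
    holds at least floor(train_fraction * n) records, so no image contributes
    annotations to both sides.  With one record per scene this hits the floor
    target exactly.
    """
    if len(records) < 2:
        raise ArgumentError(f"need >= 2 records to split, got {len(records)}")
    scenes = sorted({r.scene_id for r in records})
    if len(scenes) < 2:
        raise ArgumentError("need records from >= 2 scenes for a grouped split")
    rng = np.random.default_rng(seed)
    order = [scenes[i] for i in rng.permutation(len(scenes))]
    target = math.floor(train_fraction * len(records))
    by_scene = {s: [r for r in records if r.scene_id == s] for s in scenes}
    train: list[AnnotationRecord] = []
    val: list[AnnotationRecord] = []
    for s in order:
        if len(train) < target:
            train.extend(by_scene[s])
        else:
            val.extend(by_scene[s])
    if not val:  # ensure both sides non-empty
        val.extend(by_scene[order[-1]])
        del train[-len(val):]
    return train, val


# -- I/O ---------------------------------------------------------------------

_CSV_FIELDS = ["scene_id", "x_min", "y_min", "x_max", "y_max",
               "label", "source", "anomaly_score"]


def write_annotations_csv(records: Sequence[AnnotationRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(_CSV_FIELDS)
        for r in records:
            wr.writerow([r.scene_id, *r.bbox, r.label, r.source,
                         "" if r.anomaly_score is None else f"{r.anomaly_score:.6f}"])
    return path


def read_annotations_csv(path: str | Path) -> list[AnnotationRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sc = row["anomaly_score"]
            out.append(AnnotationRecord(
                scene_id=row["scene_id"],
                bbox=(int(row["x_min"]), int(row["y_min"]),
                      int(row["x_max"]), int(row["y_max"])),
                label=row["label"], source=row["source"],
                anomaly_score=float(sc) if sc else None))
    return out


def write_annotations_coco(records: Sequence[AnnotationRecord], path: str | Path,
                           label_set: LabelSet | None = None) -> Path:
    """COCO-style export (images/annotations/categories, bbox [x,y,w,h])."""
    label_set = label_set or LabelSet()
    cat_ids = {name: i + 1 for i, name in enumerate(label_set.names)}
    scene_ids = sorted({r.scene_id for r in records})
    img_ids = {s: i + 1 for i, s in enumerate(scene_ids)}
    coco = {
        "images": [{"id": i, "file_name": f"images/{s}.png"} for s, i in img_ids.items()],
        "categories": [{"id": i, "name": n} for n, i in cat_ids.items()],
        "annotations": [],
    }
    for k, r in enumerate(records, start=1):
        x0, y0, x1, y1 = r.bbox
        coco["annotations"].append({
            "id": k, "image_id": img_ids[r.scene_id],
            "category_id": cat_ids.get(r.label, 0),
            "bbox": [x0, y0, x1 - x0, y1 - y0],
            "area": (x1 - x0) * (y1 - y0), "iscrowd": 0,
            "attributes": {"source": r.source, "anomaly_score": r.anomaly_score},
        })
    path = Path(path)
    path.write_text(json.dumps(coco, indent=1, sort_keys=True))
    return path
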