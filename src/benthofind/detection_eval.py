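"""Detector-agnostic COCO-style evaluation and a configurable oracle detector.

Boxes follow the global convention: half-open ``[x_min, x_max) x
[y_min, y_max)`` in 0-based pixel coordinates, area ``(x1-x0)*(y1-y0)``.

Average precision uses 101-point interpolated precision-recall integration
per class; AP@[.50:.95] averages the ten IoU thresholds 0.50, 0.55, ...,
0.95.  Size strata use the COCO area bounds: small < 32^2, medium in
[32^2, 96^2), large >= 96^2.  Average recall AR_k caps detections per scene
at k in {1, 10, 100} and averages recall over the ten IoU thresholds.
Strata without ground truth report NaN (undefined), never 0, and means skip
undefined entries.

Because training a full two-stage detector is out of scope here, the
``oracle_detector`` turns ground truth into detections with configurable
miss rate, per-image false-positive rate, corner jitter and label confusion,
so evaluation and ecology can be exercised end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError

Box = tuple[float, float, float, float]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))
RECALL_POINTS = np.linspace(0.0, 1.0, 101)
AREA_RANGES = {"all": (0.0, math.inf), "small": (0.0, 32 ** 2),
               "medium": (32 ** 2, 96 ** 2), "large": (96 ** 2, math.inf)}


@dataclass
class DetectionRecord:
    scene_id: str
    bbox: Box
    label: str
    confidence: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if x1 <= x0 or y1 <= y0:
            raise ArgumentError(f"invalid box {self.bbox}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ArgumentError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class GroundTruth:
    scene_id: str
    bbox: Box
    label: str


@dataclass
class EvalSummary:
    """COCO-style metric family, all values as percentages (NaN = undefined)."""

    AP50: float
    AP50_95: float
    AP_small: float
    AP_medium: float
    AP_large: float
    AR_1: float
    AR_10: float
    AR_100: float
    AR_small: float
    AR_medium: float
    AR_large: float
    per_class_ap50: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("AP50", "AP50_95", "AP_small", "AP_medium", "AP_large",
                 "AR_1", "AR_10", "AR_100", "AR_small", "AR_medium", "AR_large")}


def box_area(box: Box) -> float:
    return (box[2] - box[0]) * (box[3] - box[1])


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two boxes; symmetric, 0 when disjoint."""
    ix0 = max(box_a[0], box_b[0])
    iy0 = max(box_a[1], box_b[1])
    ix1 = min(box_a[2], box_b[2])
    iy1 = min(box_a[3], box_b[3])
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    inter = (ix1 - ix0) * (iy1 - iy0)
    union = box_area(box_a) + box_area(box_b) - inter
    return inter / union


def greedy_nms(detections: Sequence[DetectionRecord],
               iou_threshold: float = 0.5) -> list[DetectionRecord]:
    """Greedy non-maximum suppression within one scene, per class.

    Iterates in descending confidence (ties broken by input order) and drops
    any box overlapping an already-retained box of the same class with
    IoU > threshold.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    kept: list[int] = []
    for i in order:
        d = detections[i]
        if all(detections[j].label != d.label
               or iou(d.bbox, detections[j].bbox) <= iou_threshold
               for j in kept):
            kept.append(i)
    return [detections[i] for i in sorted(kept)]


def match_detections(detections: Sequence[DetectionRecord],
                     truths: Sequence[GroundTruth],
                     iou_threshold: float = 0.5,
                     max_dets: int = 100,
                     class_agnostic: bool = False):
    """Greedy confidence-ordered matching per scene (and per class).

    Each detection, in descending confidence, matches the unmatched truth of
    its class (any class when ``class_agnostic``) with the highest
    IoU >= threshold in the same scene.  At most ``max_dets`` detections per
    scene are considered.  Returns (matched pairs, unmatched detections,
    unmatched truths); duplicate detections of one truth are false positives.
    """
    by_scene: dict[str, list[DetectionRecord]] = {}
    for d in detections:
        by_scene.setdefault(d.scene_id, []).append(d)
    considered: list[DetectionRecord] = []
    for scene, dets in by_scene.items():
        dets = sorted(dets, key=lambda d: -d.confidence)[:max_dets]
        considered.extend(dets)
    considered.sort(key=lambda d: -d.confidence)

    unmatched_truths = list(truths)
    matches: list[tuple[DetectionRecord, GroundTruth]] = []
    unmatched_dets: list[DetectionRecord] = []
    for d in considered:
        best, best_iou = None, 0.0
        for t in unmatched_truths:
            if t.scene_id != d.scene_id:
                continue
            if not class_agnostic and t.label != d.label:
                continue
            i = iou(d.bbox, t.bbox)
            if i >= iou_threshold and i > best_iou:
                best, best_iou = t, i
        if best is not None:
            matches.append((d, best))
            unmatched_truths.remove(best)
        else:
            unmatched_dets.append(d)
    return matches, unmatched_dets, unmatched_truths


def _class_pr(detections: Sequence[DetectionRecord],
              truths: Sequence[GroundTruth],
              iou_threshold: float, max_dets: int,
              area_range: tuple[float, float]) -> float | None:
    """101-point interpolated AP for one class at one IoU threshold.

    Truths outside the area stratum are ignorable: detections matching them
    count neither as TP nor FP (COCO semantics).  Returns None when the
    stratum holds no truth.
    """
    lo, hi = area_range
    in_range = [t for t in truths if lo <= box_area(t.bbox) < hi]
    if not in_range:
        return None
    ignored = [t for t in truths if not (lo <= box_area(t.bbox) < hi)]

    by_scene: dict[str, list[DetectionRecord]] = {}
    for d in detections:
        by_scene.setdefault(d.scene_id, []).append(d)
    considered: list[DetectionRecord] = []
    for dets in by_scene.values():
        considered.extend(sorted(dets, key=lambda d: -d.confidence)[:max_dets])
    considered.sort(key=lambda d: -d.confidence)

    unmatched = list(in_range)
    unmatched_ignored = list(ignored)
    tp_flags, fp_flags = [], []
    for d in considered:
        best, best_iou = None, -1.0
        for t in unmatched:
            if t.scene_id != d.scene_id:
                continue
            i = iou(d.bbox, t.bbox)
            if i >= iou_threshold and i > best_iou:
                best, best_iou = t, i
        if best is not None:
            unmatched.remove(best)
            tp_flags.append(1)
            fp_flags.append(0)
            continue
        # try ignored truths: matching one makes the detection ignorable
        hit_ignored = False
        for t in unmatched_ignored:
            if t.scene_id == d.scene_id and iou(d.bbox, t.bbox) >= iou_threshold:
                unmatched_ignored.remove(t)
                hit_ignored = True
                break
        if hit_ignored:
            continue
        tp_flags.append(0)
        fp_flags.append(1)

    if not tp_flags:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(fp_flags)
    recall = tp / len(in_range)
    precision = tp / (tp + fp)
    # precision envelope: max precision at recall >= r
    prec_at = np.zeros_like(RECALL_POINTS)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_POINTS, side="left")
    valid = idx < len(env)
    prec_at[valid] = env[idx[valid]]
    return float(prec_at.mean())


def average_precision(detections: Sequence[DetectionRecord],
                      truths: Sequence[GroundTruth],
                      iou_thresholds: Sequence[float] = IOU_THRESHOLDS,
                      max_dets: int = 100,
                      area_range: tuple[float, float] = AREA_RANGES["all"],
                      ) -> tuple[dict[str, dict[float, float]], float]:
    """Per-class AP at each IoU threshold, plus the grand mean.

    Classes with no ground truth in the stratum are undefined and skipped in
    the mean; the grand mean is NaN when every class is undefined.
    """
    classes = sorted({t.label for t in truths})
    per_class: dict[str, dict[float, float]] = {}
    vals = []
    for cls in classes:
        cls_d = [d for d in detections if d.label == cls]
        cls_t = [t for t in truths if t.label == cls]
        per_class[cls] = {}
        for thr in iou_thresholds:
            ap = _class_pr(cls_d, cls_t, thr, max_dets, area_range)
            per_class[cls][thr] = math.nan if ap is None else ap
        cls_vals = [v for v in per_class[cls].values() if not math.isnan(v)]
        if cls_vals:
            vals.append(float(np.mean(cls_vals)))
    return per_class, (float(np.mean(vals)) if vals else math.nan)


def _class_recall(detections, truths, iou_threshold, max_dets, area_range) -> float | None:
    lo, hi = area_range
    in_range = [t for t in truths if lo <= box_area(t.bbox) < hi]
    if not in_range:
        return None
    matches, _, unmatched = match_detections(
        detections, in_range, iou_threshold, max_dets)
    return len(matches) / len(in_range)


def average_recall(detections: Sequence[DetectionRecord],
                   truths: Sequence[GroundTruth],
                   max_dets: int = 100,
                   area_range: tuple[float, float] = AREA_RANGES["all"]) -> float:
    """AR: recall averaged over classes and the ten IoU thresholds."""
    classes = sorted({t.label for t in truths})
    vals = []
    for cls in classes:
        cls_d = [d for d in detections if d.label == cls]
        cls_t = [t for t in truths if t.label == cls]
        rs = [_class_recall(cls_d, cls_t, thr, max_dets, area_range)
              for thr in IOU_THRESHOLDS]
        rs = [r for r in rs if r is not None]
        if rs:
            vals.append(float(np.mean(rs)))
    return float(np.mean(vals)) if vals else math.nan


def evaluate(detections: Sequence[DetectionRecord],
             truths: Sequence[GroundTruth]) -> EvalSummary:
    """Full COCO-style metric family, values as percentages."""
    per_class_50, _ = average_precision(detections, truths, iou_thresholds=[0.5])
    ap50_vals = [v[0.5] for v in per_class_50.values() if not math.isnan(v[0.5])]
    ap50 = float(np.mean(ap50_vals)) if ap50_vals else math.nan
    _, ap50_95 = average_precision(detections, truths)
    strata = {}
    for name in ("small", "medium", "large"):
        _, strata[name] = average_precision(detections, truths,
                                            area_range=AREA_RANGES[name])
    pct = lambda v: v * 100.0 if not math.isnan(v) else math.nan
    return EvalSummary(
        AP50=pct(ap50), AP50_95=pct(ap50_95),
        AP_small=pct(strata["small"]), AP_medium=pct(strata["medium"]),
        AP_large=pct(strata["large"]),
        AR_1=pct(average_recall(detections, truths, max_dets=1)),
        AR_10=pct(average_recall(detections, truths, max_dets=10)),
        AR_100=pct(average_recall(detections, truths, max_dets=100)),
        AR_small=pct(average_recall(detections, truths, area_range=AREA_RANGES["small"])),
        AR_medium=pct(average_recall(detections, truths, area_range=AREA_RANGES["medium"])),
        AR_large=pct(average_recall(detections, truths, area_range=AREA_RANGES["large"])),
        per_class_ap50={c: pct(v[0.5]) for c, v in per_class_50.items()},
    )


def size_stratified(detections: Sequence[DetectionRecord],
                    truths: Sequence[GroundTruth],
                    area_ranges: Mapping[str, tuple[float, float]] | None = None,
                    ) -> dict[str, dict[str, float]]:
    """AP and AR per truth-area stratum (fractions; NaN when stratum empty)."""
    area_ranges = dict(area_ranges or
                       {k: v for k, v in AREA_RANGES.items() if k != "all"})
    out: dict[str, dict[str, float]] = {}
    for name, rng in area_ranges.items():
        _, ap = average_precision(detections, truths, area_range=rng)
        out[name] = {"AP": ap,
                     "AR": average_recall(detections, truths, area_range=rng)}
    return out


BACKGROUND = "__background__"


def confusion_matrix(detections: Sequence[DetectionRecord],
                     truths: Sequence[GroundTruth],
                     iou_threshold: float = 0.5,
                     labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Class-agnostic IoU matching followed by label comparison.

    Rows index the true class, columns the predicted class; a trailing
    background row/column absorbs unmatched detections / truths.  Row sums
    over all columns equal the truth counts per class.
    """
    if labels is None:
        labels = sorted({t.label for t in truths} | {d.label for d in detections})
    names = list(labels) + [BACKGROUND]
    idx = {n: i for i, n in enumerate(names)}
    mat = np.zeros((len(names), len(names)), dtype=int)
    matches, unmatched_d, unmatched_t = match_detections(
        detections, truths, iou_threshold, max_dets=10 ** 9, class_agnostic=True)
    for d, t in matches:
        mat[idx[t.label], idx[d.label]] += 1
    for t in unmatched_t:
        mat[idx[t.label], idx[BACKGROUND]] += 1
    for d in unmatched_d:
        mat[idx[BACKGROUND], idx[d.label]] += 1
    return mat, names


def oracle_detector(truths: Sequence[GroundTruth],
                    miss_rate: float = 0.0,
                    fp_rate: float = 0.0,
                    jitter_px: float = 0.0,
                    label_confusion: Mapping[str, Mapping[str, float]] | None = None,
                    image_size: tuple[int, int] = (256, 256),
                    labels: Sequence[str] | None = None,
                    seed: int = 0) -> list[DetectionRecord]:
    """Noisy stand-in for a trained detector, driven by the ground truth.

    Each truth is dropped with probability ``miss_rate``; surviving boxes get
    uniform corner jitter in [-jitter_px, +jitter_px], a label optionally
    resampled from ``label_confusion`` (rows: true label -> predicted-label
    probabilities), and a high confidence.  Poisson(``fp_rate``) false boxes
    per scene are added with lower confidence.  Zero noise reproduces the
    ground truth with confidence 1.0.
    """
    for name, r in (("miss_rate", miss_rate), ("fp_rate", fp_rate)):
        if not (0.0 <= r) or (name == "miss_rate" and r > 1.0):
            raise ArgumentError(f"{name} out of range: {r}")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = sorted({t.label for t in truths}) or ["object"]
    w, h = image_size
    dets: list[DetectionRecord] = []
    zero_noise = miss_rate == 0 and fp_rate == 0 and jitter_px == 0 and not label_confusion
    for t in truths:
        if miss_rate > 0 and rng.uniform() < miss_rate:
            continue
        x0, y0, x1, y1 = t.bbox
        if jitter_px > 0:
            j = rng.uniform(-jitter_px, jitter_px, size=4)
            x0, y0, x1, y1 = x0 + j[0], y0 + j[1], x1 + j[2], y1 + j[3]
            if x1 <= x0:
                x0, x1 = x1, x0 + 1
            if y1 <= y0:
                y0, y1 = y1, y0 + 1
        label = t.label
        if label_confusion and t.label in label_confusion:
            row = label_confusion[t.label]
            names = list(row.keys())
            probs = np.array([row[n] for n in names], dtype=float)
            label = names[rng.choice(len(names), p=probs / probs.sum())]
        conf = 1.0 if zero_noise else float(rng.uniform(0.7, 1.0))
        dets.append(DetectionRecord(t.scene_id, (x0, y0, x1, y1), label, conf))
    if fp_rate > 0:
        for scene in sorted({t.scene_id for t in truths}):
            for _ in range(rng.poisson(fp_rate)):
                bw, bh = rng.uniform(8, 40, size=2)
                x0 = rng.uniform(0, max(1, w - bw))
                y0 = rng.uniform(0, max(1, h - bh))
                dets.append(DetectionRecord(
                    scene, (x0, y0, x0 + bw, y0 + bh),
                    labels[rng.integers(len(labels))],
                    float(rng.uniform(0.05, 0.6))))
    return dets
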