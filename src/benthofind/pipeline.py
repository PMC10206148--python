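"""Stage-by-stage orchestration of the detection workflow.

Stages (in order): simulate -> segment -> train-vae -> features ->
train-iforest -> score -> filter -> annotate -> evaluate -> ecology.
Each stage reads the previous stage's artifacts from the working directory,
writes its own outputs plus a run manifest (config hash, seed, input
checksums), and never mutates upstream artifacts.  ``run_stage("all", ...)``
chains every stage.

The expert-in-the-loop steps of the original workflow (picking classifier
training examples from the score-sorted review queue, assigning morphotype
labels) are emulated programmatically from the synthetic ground truth: a
flagged superpixel counts as a true positive example when its box overlaps a
planted fauna box, and labels are copied from the overlapping ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import pickle
from pathlib import Path
from typing import Callable

import numpy as np

from . import detection_eval as de
from . import ecology as eco
from . import iforest as ifo
from . import superpixels as sp
from . import synthetic as syn
from . import vae as vae_mod
from . import weak_annotations as wa
from .config import PipelineConfig
from .errors import ArgumentError

logger = logging.getLogger("benthofind")

STAGES = ["simulate", "segment", "train-vae", "features", "train-iforest",
          "score", "filter", "annotate", "evaluate", "ecology"]


def _scene_config(cfg: PipelineConfig) -> syn.SceneConfig:
    s = cfg.survey
    return syn.SceneConfig(
        image_size=(s.image_width, s.image_height),
        nodule_density=s.nodule_density, fauna_rate=s.fauna_rate,
        laser_rate=s.laser_rate, dark_patch_rate=s.dark_patch_rate,
        noise_sigma=s.noise_sigma, seed=cfg.stage_seed("simulate"))


def _seg_params(cfg: PipelineConfig) -> sp.SegmentationParams:
    g = cfg.segmentation
    return sp.SegmentationParams(scale=g.scale, sigma=g.sigma, min_size=g.min_size,
                                 max_area_fraction=g.max_area_fraction)


def _regenerate_survey(cfg: PipelineConfig):
    s = cfg.survey
    return syn.generate_survey(
        _scene_config(cfg), s.n_images, start_lonlat=(s.start_lon, s.start_lat),
        heading_deg=s.heading_deg, speed_ms=s.speed_ms, interval_s=s.interval_s)


def _write_run_manifest(workdir: Path, stage: str, cfg: PipelineConfig,
                        outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seed": cfg.stage_seed(stage),
        "outputs": [{"path": str(p.relative_to(workdir)),
                     "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
                    for p in outputs if p.is_file()],
    }
    (workdir / f"run_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))


def _require(workdir: Path, artifact: str, produced_by: str) -> Path:
    p = workdir / artifact
    if not p.exists():
        raise ArgumentError(
            f"missing artifact {artifact!r}; run stage {produced_by!r} first")
    return p


# -- stages -------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    scenes, track = _regenerate_survey(cfg)
    manifest = syn.write_survey(scenes, track, workdir / "survey")
    logger.info("simulate: wrote %d scenes", len(scenes))
    return [manifest]


def _stage_segment(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "survey/manifest.json", "simulate")
    scenes, _ = _regenerate_survey(cfg)
    params = _seg_params(cfg)
    patch_size = cfg.segmentation.patch_size
    patches, bboxes, areas, parents, seg_ids = [], [], [], [], []
    for s in scenes:
        labels = sp.segment_image(s.image, params)
        for p in sp.extract_patches(s.image, labels, params, patch_size, s.scene_id):
            patches.append(p.patch)
            bboxes.append(p.bbox)
            areas.append(p.area)
            parents.append(p.parent_id)
            seg_ids.append(p.segment_id)
    n_sample = min(cfg.segmentation.n_sample_images, len(scenes))
    sampled = sp.sample_images([s.scene_id for s in scenes], n_sample,
                               cfg.stage_seed("segment"))
    out = workdir / "patches.npz"
    np.savez_compressed(out, patches=np.stack(patches).astype(np.float32),
                        bboxes=np.array(bboxes, dtype=np.int64),
                        areas=np.array(areas, dtype=np.int64),
                        parents=np.array(parents), seg_ids=np.array(seg_ids),
                        sampled_scenes=np.array(sorted(sampled)))
    logger.info("segment: %d patches from %d scenes (%d sampled for training)",
                len(patches), len(scenes), n_sample)
    return [out]


def _load_patches(workdir: Path) -> tuple[list[sp.SuperpixelPatch], set[str]]:
    data = np.load(_require(workdir, "patches.npz", "segment"), allow_pickle=False)
    patches = [
        sp.SuperpixelPatch(parent_id=str(par), segment_id=int(sid),
                           bbox=tuple(int(v) for v in bb), patch=pt, area=int(a))
        for pt, bb, a, par, sid in zip(data["patches"], data["bboxes"],
                                       data["areas"], data["parents"],
                                       data["seg_ids"])]
    return patches, set(str(s) for s in data["sampled_scenes"])


def _stage_train_vae(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    patches, sampled = _load_patches(workdir)
    train = [p for p in patches if p.parent_id in sampled]
    v = cfg.vae
    vcfg = vae_mod.VaeConfig(latent_dim=v.latent_dim, patch_size=cfg.segmentation.patch_size,
                             hidden_dim=v.hidden_dim, epochs=v.epochs,
                             batch_size=min(v.batch_size, len(train)),
                             learning_rate=v.learning_rate,
                             seed=cfg.stage_seed("train-vae"))
    model, history = vae_mod.train_vae(train, vcfg)
    out = workdir / "vae.npz"
    model.save(out)
    (workdir / "vae_history.json").write_text(json.dumps(history))
    logger.info("train-vae: %d patches, final loss %.5f", len(train),
                history["loss"][-1])
    return [out, workdir / "vae_history.json"]


def _stage_features(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    patches, _ = _load_patches(workdir)
    model = vae_mod.Vae.load(_require(workdir, "vae.npz", "train-vae"))
    fm = vae_mod.encode_patches(model, patches)
    out = workdir / "features.npz"
    np.savez_compressed(out, ids=np.array(fm.ids), values=fm.values)
    logger.info("features: %s matrix", fm.values.shape)
    return [out]


def _load_features(workdir: Path) -> vae_mod.FeatureMatrix:
    data = np.load(_require(workdir, "features.npz", "features"))
    return vae_mod.FeatureMatrix(ids=[str(i) for i in data["ids"]],
                                 values=data["values"])


def _stage_train_iforest(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    fm = _load_features(workdir)
    patches, sampled = _load_patches(workdir)
    train_rows = [i for i, p in enumerate(patches) if p.parent_id in sampled]
    sub = vae_mod.FeatureMatrix(ids=[fm.ids[i] for i in train_rows],
                                values=fm.values[train_rows])
    fcfg = ifo.ForestConfig(n_trees=cfg.iforest.n_trees,
                            subsample_size=cfg.iforest.subsample_size,
                            contamination=cfg.iforest.contamination,
                            seed=cfg.stage_seed("train-iforest"))
    forest = ifo.fit_forest(sub, fcfg)
    out = workdir / "iforest.pkl"
    with open(out, "wb") as fh:
        pickle.dump(forest, fh)
    logger.info("train-iforest: fitted on %d rows (psi=%d)", len(train_rows),
                forest.psi)
    return [out]


def _stage_score(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    fm = _load_features(workdir)
    with open(_require(workdir, "iforest.pkl", "train-iforest"), "rb") as fh:
        forest = pickle.load(fh)
    results = ifo.score(forest, fm)
    results = ifo.flag_by_contamination(results, cfg.iforest.contamination)
    out = workdir / "scores.csv"
    with open(out, "w") as fh:
        fh.write("patch_id,score,flagged\n")
        for r in results:
            fh.write(f"{r.patch_id},{r.score:.8f},{int(r.flagged)}\n")
    logger.info("score: %d scored, %d flagged", len(results),
                sum(r.flagged for r in results))
    return [out]


def _load_scores(workdir: Path) -> list[ifo.AnomalyResult]:
    out = []
    for line in _require(workdir, "scores.csv", "score").read_text().splitlines()[1:]:
        pid, s, f = line.rsplit(",", 2)
        out.append(ifo.AnomalyResult(pid, float(s), bool(int(f))))
    return out


def _truth_lookup(cfg: PipelineConfig, workdir: Path):
    gt = syn.read_ground_truth(_require(workdir, "survey/ground_truth.csv", "simulate"))
    by_scene: dict[str, list] = {}
    for scene_id, box, label in gt:
        by_scene.setdefault(scene_id, []).append((box, label))
    return by_scene


def _overlap_label(bbox, scene_truths) -> str | None:
    """Label of the max-IoU overlapping ground-truth box, if any overlap."""
    best, best_iou = None, 0.0
    for box, label in scene_truths:
        i = de.iou(bbox, box)
        if i > best_iou:
            best, best_iou = label, i
    return best


def _stage_filter(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    patches, _ = _load_patches(workdir)
    results = _load_scores(workdir)
    flagged_ids = {r.patch_id for r in results if r.flagged}
    scores = {r.patch_id: r.score for r in results}
    flagged = [p for p in patches if p.patch_id in flagged_ids]

    if cfg.filtering.method == "threshold":
        flagged_results = [r for r in results if r.flagged]
        keep = set(wa.threshold_filter(flagged_results, cfg.filtering.percentile))
        records = [wa.AnnotationRecord(p.parent_id, p.bbox,
                                       anomaly_score=scores[p.patch_id])
                   for p in flagged if p.patch_id in keep]
    else:
        # Emulated expert: walk the review queue, mark flagged patches that
        # overlap a planted fauna box as positives, the rest as negatives.
        truths = _truth_lookup(cfg, workdir)
        by_id = {p.patch_id: p for p in flagged}
        queue = [pid for pid in wa.review_queue([r for r in results if r.flagged])
                 if pid in by_id]
        positives, negatives = [], []
        for pid in queue:
            p = by_id[pid]
            if _overlap_label(p.bbox, truths.get(p.parent_id, [])) is not None:
                positives.append(p)
            else:
                negatives.append(p)
        rng = np.random.default_rng(cfg.stage_seed("filter"))
        if len(negatives) > 4 * len(positives) and len(positives) >= 8:
            idx = rng.choice(len(negatives), size=4 * len(positives), replace=False)
            negatives = [negatives[i] for i in sorted(idx)]
        clf = wa.train_patch_classifier(positives, negatives,
                                        epochs=cfg.filtering.classifier_epochs,
                                        learning_rate=cfg.filtering.classifier_lr,
                                        seed=cfg.stage_seed("filter"))
        records = wa.classifier_filter(clf, flagged, scores,
                                       cfg.filtering.prob_cutoff)
    records.sort(key=lambda r: r.record_id)
    out = wa.write_annotations_csv(records, workdir / "weak_annotations.csv")
    logger.info("filter(%s): %d weak annotations from %d flagged patches",
                cfg.filtering.method, len(records), len(flagged))
    return [out]


def _stage_annotate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    records = wa.read_annotations_csv(_require(workdir, "weak_annotations.csv", "filter"))
    truths = _truth_lookup(cfg, workdir)
    table = {}
    for r in records:
        label = _overlap_label(r.bbox, truths.get(r.scene_id, []))
        if label is not None:
            table[r.record_id] = label
    labeled = wa.assign_labels(records, table, drop_unlabeled=True)
    labeled.sort(key=lambda r: r.record_id)
    out_all = wa.write_annotations_csv(labeled, workdir / "annotations.csv")
    out_coco = wa.write_annotations_coco(labeled, workdir / "annotations.json")
    outputs = [out_all, out_coco]
    if len(labeled) >= 2 and len({r.scene_id for r in labeled}) >= 2:
        train, val = wa.split_annotations(labeled, 0.9, cfg.stage_seed("annotate"))
        outputs.append(wa.write_annotations_csv(train, workdir / "annotations_train.csv"))
        outputs.append(wa.write_annotations_csv(val, workdir / "annotations_val.csv"))
    logger.info("annotate: %d labeled annotations", len(labeled))
    return outputs


def _ground_truths(cfg: PipelineConfig, workdir: Path) -> list[de.GroundTruth]:
    gt = syn.read_ground_truth(_require(workdir, "survey/ground_truth.csv", "simulate"))
    return [de.GroundTruth(scene_id, box, label) for scene_id, box, label in gt]


def _stage_evaluate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    truths = _ground_truths(cfg, workdir)
    e = cfg.evaluation
    dets = de.oracle_detector(
        truths, miss_rate=e.miss_rate, fp_rate=e.fp_rate, jitter_px=e.jitter_px,
        image_size=(cfg.survey.image_width, cfg.survey.image_height),
        seed=cfg.stage_seed("evaluate"))
    by_scene: dict[str, list[de.DetectionRecord]] = {}
    for d in dets:
        by_scene.setdefault(d.scene_id, []).append(d)
    dets = [d for scene in sorted(by_scene)
            for d in de.greedy_nms(by_scene[scene], e.nms_iou)]
    summary = de.evaluate(dets, truths)
    mat, names = de.confusion_matrix(dets, truths)

    out_det = workdir / "detections.csv"
    with open(out_det, "w") as fh:
        fh.write("scene_id,x_min,y_min,x_max,y_max,label,confidence\n")
        for d in dets:
            fh.write(f"{d.scene_id},{d.bbox[0]:.2f},{d.bbox[1]:.2f},"
                     f"{d.bbox[2]:.2f},{d.bbox[3]:.2f},{d.label},{d.confidence:.4f}\n")
    out_sum = workdir / "eval_summary.json"
    payload = summary.as_dict()
    payload["per_class_AP50"] = summary.per_class_ap50
    out_sum.write_text(json.dumps(
        {k: (None if isinstance(v, float) and math.isnan(v) else v)
         for k, v in payload.items()}, indent=1, sort_keys=True, default=float))
    out_cm = workdir / "confusion_matrix.csv"
    with open(out_cm, "w") as fh:
        fh.write("," + ",".join(names) + "\n")
        for name, row in zip(names, mat):
            fh.write(name + "," + ",".join(str(v) for v in row) + "\n")
    logger.info("evaluate: AP50=%.1f%% over %d detections", summary.AP50, len(dets))
    return [out_det, out_sum, out_cm]


def _stage_ecology(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "detections.csv", "evaluate")
    scenes, track = _regenerate_survey(cfg)
    times = [s.timestamp for s in scenes]
    resolved, unresolved = eco.georeference(times, track, cfg.ecology.max_gap_s)
    scene_pos = {scenes[i].scene_id: resolved[i] for i in resolved}
    footprints = {sid: eco.image_footprint(alt, cfg.ecology.fov_x_deg,
                                           cfg.ecology.fov_y_deg)
                  for sid, (_, _, alt) in scene_pos.items()}

    dets: list[de.DetectionRecord] = []
    for line in (workdir / "detections.csv").read_text().splitlines()[1:]:
        sid, x0, y0, x1, y1, label, conf = line.split(",")
        dets.append(de.DetectionRecord(sid, (float(x0), float(y0), float(x1),
                                             float(y1)), label, float(conf)))
    geodets = [eco.GeoDetection(d, *scene_pos[d.scene_id][:2],
                                altitude=scene_pos[d.scene_id][2],
                                footprint=footprints[d.scene_id])
               for d in dets if d.scene_id in scene_pos]

    overall, per_class = eco.abundance(geodets, list(footprints.values()))
    counts: dict[str, int] = {}
    for g in geodets:
        counts[g.detection.label] = counts.get(g.detection.label, 0) + 1
    diversity = eco.shannon_effective(counts) if counts else math.nan

    all_ids = sorted(scene_pos)
    xs, ys = eco.lonlat_to_local([scene_pos[s][0] for s in all_ids],
                                 [scene_pos[s][1] for s in all_ids])
    pos_xy = {sid: (float(x), float(y)) for sid, x, y in zip(all_ids, xs, ys)}
    cells = eco.grid_density(
        [pos_xy[g.detection.scene_id] for g in geodets],
        [pos_xy[s] for s in all_ids], [footprints[s] for s in all_ids],
        cfg.ecology.cell_size_m)

    out_json = workdir / "ecology.json"
    out_json.write_text(json.dumps({
        "n_detections": len(geodets),
        "n_unresolved_images": len(unresolved),
        "abundance_ind_per_m2": overall,
        "abundance_per_class": per_class,
        "shannon_effective": None if math.isnan(diversity) else diversity,
        "morphotype_counts": dict(sorted(counts.items())),
    }, indent=1, sort_keys=True))
    out_grid = workdir / "grid_density.csv"
    with open(out_grid, "w") as fh:
        fh.write("cell_i,cell_j,count,footprint_m2,density_ind_per_m2\n")
        for c in cells:
            fh.write(f"{c.index[0]},{c.index[1]},{c.count},"
                     f"{c.footprint_total:.4f},{c.density:.6f}\n")
    logger.info("ecology: %.4f ind/m2, effective diversity %.2f", overall, diversity)
    return [out_json, out_grid]


_STAGE_FUNCS: dict[str, Callable[[PipelineConfig, Path], list[Path]]] = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "train-vae": _stage_train_vae,
    "features": _stage_features,
    "train-iforest": _stage_train_iforest,
    "score": _stage_score,
    "filter": _stage_filter,
    "annotate": _stage_annotate,
    "evaluate": _stage_evaluate,
    "ecology": _stage_ecology,
}


def run_stage(name: str, config: PipelineConfig) -> Path:
    """Run one named stage (or ``all``); returns the working directory.

    Each stage writes its outputs plus a ``run_<stage>.json`` manifest
    recording the config hash, seeds and output checksums.
    """
    if name != "all" and name not in _STAGE_FUNCS:
        raise ArgumentError(f"unknown stage {name!r}; choose from {STAGES + ['all']}")
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if name == "all" else [name]
    for stage in stages:
        outputs = _STAGE_FUNCS[stage](config, workdir)
        _write_run_manifest(workdir, stage, config, outputs)
    return workdir
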