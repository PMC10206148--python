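"""Synthetic benthic survey generator.

Emulates the statistical structure of towed-camera (OFOS-style) photo
transects over an abyssal nodule field: a quasi-homogeneous soft-sediment
background speckled with dark manganese nodules, rare megafauna of distinct
morphotypes planted at a low Poisson rate, red laser-point and dark-patch
distractors, and a timestamped navigation track at 1-4 m altitude.

All randomness flows from a single seed through a counter-based stream per
scene index, so any scene of a survey is independently reproducible.

Boxes follow the global convention: 0-based pixel indices, half-open
``[x_min, x_max) x [y_min, y_max)``, area ``(x_max-x_min)*(y_max-y_min)``.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ArgumentError, ConfigurationError

EARTH_RADIUS_M = 6_371_000.0

#: Default survey start time (UTC epoch seconds), an arbitrary cruise morning.
DEFAULT_START_TIME = datetime(2019, 4, 1, 6, 0, 0, tzinfo=timezone.utc).timestamp()


@dataclass(frozen=True)
class Morphotype:
    """Parametric description of one fauna morphotype.

    ``kind`` selects the rendered shape family: ``disk`` (anemone-like),
    ``disk_arms`` (ophiuroid-like central disk with radiating arms), ``fan``
    (sponge-like), ``star`` (urchin-like spiked disk), ``blob``
    (holothurian-like irregular body).  ``color`` is RGB in [0,1]; a color
    close to the sediment tone yields a camouflaged, hard-to-see morphotype.
    """

    name: str
    kind: str
    color: tuple[float, float, float]
    size_range: tuple[int, int] = (12, 24)
    weight: float = 1.0


def default_palette() -> list[Morphotype]:
    """Morphotype palette used by default surveys.

    Six of the ten morphotype classes of the default label set are rendered;
    the xenophyophore entry is deliberately low-contrast against the sediment
    tone to emulate camouflaged tests that are hard to separate from the
    background.
    """
    return [
        Morphotype("ophiuroid", "disk_arms", (0.86, 0.76, 0.70), (16, 28), 3.0),
        Morphotype("sponge", "fan", (0.92, 0.90, 0.84), (14, 24), 2.0),
        Morphotype("xenophyophore", "blob", (0.60, 0.55, 0.48), (12, 20), 2.0),
        Morphotype("anemone", "disk", (0.85, 0.38, 0.28), (10, 18), 1.0),
        Morphotype("sea urchin", "star", (0.36, 0.16, 0.46), (12, 20), 1.0),
        Morphotype("holothurian", "blob", (0.56, 0.36, 0.66), (18, 30), 1.0),
    ]


@dataclass
class SceneConfig:
    """Configuration of one synthetic scene / survey.

    Parameters
    ----------
    image_size:
        (width, height) in pixels, each >= 64.
    nodule_density:
        Expected number of dark Mn-nodule ellipses per image.
    fauna_rate:
        Poisson mean of planted fauna instances per image.
    morphotype_palette:
        Non-empty list of :class:`Morphotype`; instances are drawn from the
        categorical distribution given by the palette weights.
    laser_rate:
        Expected number of red laser-point *pairs* per image.
    dark_patch_rate:
        Expected number of dark water-column patches per image (distractors).
    noise_sigma:
        Std of per-pixel Gaussian background noise, [0,1] intensity units.
    altitude_range:
        (low, high) camera altitude band in metres.
    seed:
        Master seed; combined with the scene index into a per-scene stream.
    """

    image_size: tuple[int, int] = (256, 256)
    nodule_density: float = 120.0
    fauna_rate: float = 2.0
    morphotype_palette: list[Morphotype] = field(default_factory=default_palette)
    laser_rate: float = 0.5
    dark_patch_rate: float = 0.3
    noise_sigma: float = 0.02
    altitude_range: tuple[float, float] = (1.5, 3.5)
    seed: int = 0

    def validate(self) -> None:
        w, h = self.image_size
        if w < 64 or h < 64:
            raise ConfigurationError(f"image_size must be >= 64x64, got {self.image_size}")
        for name in ("nodule_density", "fauna_rate", "laser_rate", "dark_patch_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 <= self.noise_sigma <= 1.0):
            raise ConfigurationError(f"noise_sigma must be in [0,1], got {self.noise_sigma}")
        if not self.morphotype_palette:
            raise ConfigurationError("morphotype_palette must be non-empty")
        lo, hi = self.altitude_range
        if not (1.0 <= lo <= hi <= 10.0):
            raise ConfigurationError(
                f"altitude_range must satisfy 1 <= low <= high <= 10, got {self.altitude_range}"
            )


@dataclass
class SceneRecord:
    """One synthetic seafloor photograph with ground truth."""

    image: np.ndarray  # (H, W, 3) float in [0,1]
    timestamp: float  # seconds UTC
    ground_truth: list[tuple[tuple[int, int, int, int], str]]
    distractors: list[tuple[tuple[int, int, int, int], str]]
    scene_id: str

    @property
    def background_fraction(self) -> float:
        """Fraction of image area not covered by any ground-truth box."""
        h, w = self.image.shape[:2]
        mask = np.zeros((h, w), dtype=bool)
        for (x0, y0, x1, y1), _ in self.ground_truth:
            mask[y0:y1, x0:x1] = True
        return 1.0 - mask.mean()


@dataclass
class NavigationTrack:
    """Time-ordered USBL-style navigation fixes: (t, lon, lat, altitude)."""

    fixes: list[tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        times = [f[0] for f in self.fixes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ArgumentError("navigation timestamps must be strictly increasing")
        for f in self.fixes:
            if not (1.0 <= f[3] <= 10.0):
                raise ArgumentError(f"altitude {f[3]} outside [1, 10] m")


def _scene_rng(seed: int, scene_index: int) -> np.random.Generator:
    # Counter-based stream: one SeedSequence spawn key per scene so that
    # scene k is identical whether generated alone or inside a survey.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(scene_index,)))


def _shape_mask(kind: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of one rendered organism in a local window."""
    r = size / 2.0
    pad = size + 6
    yy, xx = np.mgrid[0:pad, 0:pad].astype(float)
    cy = cx = pad / 2.0
    d = np.hypot(xx - cx, yy - cy)
    if kind == "disk":
        return d <= r
    if kind == "blob":
        mask = np.zeros((pad, pad), dtype=bool)
        for _ in range(rng.integers(3, 6)):
            ox, oy = rng.uniform(-r / 2, r / 2, size=2)
            rr = rng.uniform(r * 0.35, r * 0.6)
            mask |= np.hypot(xx - cx - ox, yy - cy - oy) <= rr
        return mask
    if kind == "star":
        theta = np.arctan2(yy - cy, xx - cx)
        n_spikes = int(rng.integers(8, 13))
        spikes = r * (0.55 + 0.45 * np.cos(n_spikes * theta) ** 2)
        return d <= spikes
    if kind == "fan":
        theta = np.arctan2(yy - cy, xx - cx)
        phi = rng.uniform(0, 2 * math.pi)
        ang = np.abs((theta - phi + math.pi) % (2 * math.pi) - math.pi)
        fan = (d <= r) & (ang <= math.pi / 3)
        stalk = (d <= r * 0.9) & (ang >= math.pi - 0.25)
        return fan | stalk
    if kind == "disk_arms":
        mask = d <= r * 0.3
        n_arms = int(rng.integers(5, 7))
        for k in range(n_arms):
            phi = 2 * math.pi * k / n_arms + rng.uniform(-0.2, 0.2)
            curvature = rng.uniform(-0.3, 0.3)
            for t in np.linspace(0, 1, int(3 * r)):
                ang = phi + curvature * t
                px = cx + r * t * math.cos(ang)
                py = cy + r * t * math.sin(ang)
                mask |= np.hypot(xx - px, yy - py) <= max(1.2, r * 0.1 * (1 - 0.5 * t))
        return mask
    raise ConfigurationError(f"unknown morphotype kind {kind!r}")


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _render_background(w: int, h: int, rng: np.random.Generator, noise_sigma: float) -> np.ndarray:
    base = np.array([0.55, 0.50, 0.44])
    field2d = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=min(w, h) / 8.0)
    if field2d.std() > 0:
        field2d = 0.04 * field2d / field2d.std()
    img = base[None, None, :] + field2d[..., None]
    img += rng.normal(0.0, noise_sigma, size=(h, w, 3))
    return np.clip(img, 0.0, 1.0)


def _stamp(img: np.ndarray, mask: np.ndarray, x0: int, y0: int,
           color: np.ndarray, rng: np.random.Generator, shade: float = 0.06) -> None:
    ph, pw = mask.shape
    tile = img[y0:y0 + ph, x0:x0 + pw]
    texture = rng.normal(0.0, shade, size=(ph, pw, 1))
    tile[mask] = np.clip(color[None, :] + texture[mask], 0.0, 1.0)


def generate_scene(config: SceneConfig, scene_index: int) -> SceneRecord:
    """Render one seafloor scene with ground truth and distractor boxes.

    Reproducible: a fixed ``(config.seed, scene_index)`` pair always yields a
    byte-identical image and identical ground truth.  The fauna count is
    Poisson(``fauna_rate``); each instance's box tightly encloses its rendered
    pixels.  Laser points and dark patches are recorded as distractors and
    never enter ``ground_truth``.
    """
    config.validate()
    rng = _scene_rng(config.seed, scene_index)
    w, h = config.image_size
    img = _render_background(w, h, rng, config.noise_sigma)

    # Mn-nodules: small dark ellipses, part of the "normal" background.
    n_nodules = rng.poisson(config.nodule_density)
    yy0, xx0 = np.mgrid[0:16, 0:16].astype(float)
    for _ in range(n_nodules):
        a = rng.uniform(3.5, 6.5)
        b = a * rng.uniform(0.6, 1.0)
        phi = rng.uniform(0, math.pi)
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        u = (xx0 - 8) * math.cos(phi) + (yy0 - 8) * math.sin(phi)
        v = -(xx0 - 8) * math.sin(phi) + (yy0 - 8) * math.cos(phi)
        em = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        x0, y0 = int(cx) - 8, int(cy) - 8
        xs0, ys0 = max(0, -x0), max(0, -y0)
        xs1 = 16 - max(0, x0 + 16 - w)
        ys1 = 16 - max(0, y0 + 16 - h)
        if xs1 <= xs0 or ys1 <= ys0:
            continue
        sub = em[ys0:ys1, xs0:xs1]
        tile = img[y0 + ys0:y0 + ys1, x0 + xs0:x0 + xs1]
        tile[sub] = tile[sub] * rng.uniform(0.45, 0.6)

    # Fauna: rare planted organisms with tight ground-truth boxes.
    ground_truth: list[tuple[tuple[int, int, int, int], str]] = []
    weights = np.array([m.weight for m in config.morphotype_palette], dtype=float)
    weights = weights / weights.sum()
    n_fauna = rng.poisson(config.fauna_rate)
    for _ in range(n_fauna):
        m = config.morphotype_palette[rng.choice(len(weights), p=weights)]
        size = int(rng.integers(m.size_range[0], m.size_range[1] + 1))
        mask = _shape_mask(m.kind, size, rng)
        bx0, by0, bx1, by1 = _tight_bbox(mask)
        mask = mask[by0:by1, bx0:bx1]
        mh, mw = mask.shape
        if mw >= w or mh >= h:
            continue
        x0 = int(rng.integers(0, w - mw))
        y0 = int(rng.integers(0, h - mh))
        _stamp(img, mask, x0, y0, np.asarray(m.color), rng)
        ground_truth.append(((x0, y0, x0 + mw, y0 + mh), m.name))

    # Distractors: paired saturated red laser dots; dark water-column patches.
    distractors: list[tuple[tuple[int, int, int, int], str]] = []
    yy, xx = np.mgrid[0:9, 0:9].astype(float)
    dot = np.hypot(xx - 4, yy - 4) <= 3.0
    for _ in range(rng.poisson(config.laser_rate)):
        lx = int(rng.integers(4, max(5, w - 30)))
        ly = int(rng.integers(4, h - 5))
        for k in range(2):
            x0, y0 = lx + 20 * k - 4, ly - 4
            if x0 < 0 or y0 < 0 or x0 + 9 > w or y0 + 9 > h:
                continue
            _stamp(img, dot, x0, y0, np.asarray([0.95, 0.05, 0.05]), rng, shade=0.02)
            distractors.append(((x0, y0, x0 + 9, y0 + 9), "laser"))
    for _ in range(rng.poisson(config.dark_patch_rate)):
        size = int(rng.integers(10, 20))
        mask = _shape_mask("blob", size, rng)
        b = _tight_bbox(mask)
        mask = mask[b[1]:b[3], b[0]:b[2]]
        mh, mw = mask.shape
        if mw >= w or mh >= h:
            continue
        x0 = int(rng.integers(0, w - mw))
        y0 = int(rng.integers(0, h - mh))
        _stamp(img, mask, x0, y0, np.asarray([0.06, 0.06, 0.08]), rng, shade=0.01)
        distractors.append(((x0, y0, x0 + mw, y0 + mh), "dark_patch"))

    return SceneRecord(
        image=np.clip(img, 0.0, 1.0),
        timestamp=DEFAULT_START_TIME,
        ground_truth=ground_truth,
        distractors=distractors,
        scene_id=f"scene_{scene_index:05d}",
    )


def generate_survey(
    config: SceneConfig,
    n_images: int,
    start_lonlat: tuple[float, float] = (-125.0, 11.8),
    heading_deg: float = 90.0,
    speed_ms: float = 0.26,
    interval_s: float = 10.0,
    start_time: float = DEFAULT_START_TIME,
) -> tuple[list[SceneRecord], NavigationTrack]:
    """Generate a photo transect: scenes at a fixed cadence plus navigation.

    The camera platform moves along a locally straight track at ``speed_ms``
    (default ~0.5 knots) and photographs every ``interval_s`` seconds
    (default 10 s, i.e. 0.1 Hz).  Navigation fixes are produced at twice the
    image cadence; altitude drifts smoothly within the configured band.
    """
    if n_images < 1:
        raise ArgumentError(f"n_images must be >= 1, got {n_images}")
    if interval_s <= 0:
        raise ArgumentError(f"interval_s must be > 0, got {interval_s}")
    config.validate()

    scenes = []
    for i in range(n_images):
        rec = generate_scene(config, i)
        rec.timestamp = start_time + i * interval_s
        scenes.append(rec)

    lon0, lat0 = start_lonlat
    lo, hi = config.altitude_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0 * 0.8
    heading = math.radians(heading_deg)
    fix_dt = interval_s / 2.0
    n_fixes = 2 * n_images + 1
    fixes = []
    for j in range(n_fixes):
        t = start_time - fix_dt + j * fix_dt
        dist = speed_ms * (t - start_time)
        de, dn = dist * math.sin(heading), dist * math.cos(heading)
        lon = lon0 + math.degrees(de / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
        lat = lat0 + math.degrees(dn / EARTH_RADIUS_M)
        alt = mid + amp * math.sin(2 * math.pi * (t - start_time) / (40 * interval_s))
        fixes.append((t, lon, lat, alt))
    return scenes, NavigationTrack(fixes=fixes)


def _iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def write_survey(scenes: Sequence[SceneRecord], track: NavigationTrack, out_dir: str | Path) -> Path:
    """Write a survey to disk and return the manifest path.

    Layout: ``images/<scene_id>.png`` (8-bit RGB), ``ground_truth.csv``
    (scene_id,x_min,y_min,x_max,y_max,label), COCO-style
    ``ground_truth.json``, ``navigation.csv``
    (timestamp_iso,lon,lat,altitude_m) and ``manifest.json`` listing every
    file with its SHA-256 checksum.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    files: list[Path] = []
    categories = sorted({lbl for s in scenes for _, lbl in s.ground_truth})
    cat_ids = {c: i + 1 for i, c in enumerate(categories)}
    coco: dict = {"images": [], "annotations": [], "categories":
                  [{"id": i, "name": c} for c, i in cat_ids.items()]}
    ann_id = 1
    gt_path = out / "ground_truth.csv"
    with open(gt_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["scene_id", "x_min", "y_min", "x_max", "y_max", "label"])
        for img_id, s in enumerate(scenes, start=1):
            arr = (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)
            p = out / "images" / f"{s.scene_id}.png"
            Image.fromarray(arr).save(p)
            files.append(p)
            h, w = arr.shape[:2]
            coco["images"].append({"id": img_id, "file_name": f"images/{s.scene_id}.png",
                                   "width": w, "height": h,
                                   "date_captured": _iso(s.timestamp)})
            for (x0, y0, x1, y1), lbl in s.ground_truth:
                wr.writerow([s.scene_id, x0, y0, x1, y1, lbl])
                coco["annotations"].append({
                    "id": ann_id, "image_id": img_id, "category_id": cat_ids[lbl],
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0), "iscrowd": 0})
                ann_id += 1
    files.append(gt_path)

    coco_path = out / "ground_truth.json"
    coco_path.write_text(json.dumps(coco, indent=1, sort_keys=True))
    files.append(coco_path)

    nav_path = out / "navigation.csv"
    with open(nav_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["timestamp_iso", "lon", "lat", "altitude_m"])
        for t, lon, lat, alt in track.fixes:
            wr.writerow([_iso(t), f"{lon:.8f}", f"{lat:.8f}", f"{alt:.3f}"])
    files.append(nav_path)

    manifest = {"files": [
        {"path": str(p.relative_to(out)),
         "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
        for p in files]}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_ground_truth(csv_path: str | Path) -> list[tuple[str, tuple[int, int, int, int], str]]:
    """Read a ground-truth CSV back into (scene_id, box, label) triples."""
    rows = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((row["scene_id"],
                         (int(row["x_min"]), int(row["y_min"]),
                          int(row["x_max"]), int(row["y_max"])), row["label"]))
    return rows
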