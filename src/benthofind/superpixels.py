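"""Superpixel generation and square patch extraction.

Each image is over-segmented with the graph-based (Felzenszwalb-Huttenlocher)
algorithm after Gaussian pre-smoothing; on a quasi-homogeneous seafloor the
dominant sediment forms one huge segment while organisms, nodules and
distractors form small isolated segments.  Segments below a configurable area
fraction are cropped into square patches for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import felzenszwalb
from skimage.transform import resize

from .errors import ArgumentError, ConfigurationError


@dataclass
class SegmentationParams:
    """Graph-based segmentation parameters.

    scale: merging-threshold constant (larger => larger segments);
    sigma: Gaussian pre-smoothing std in pixels;
    min_size: minimum segment area in pixels (smaller segments are merged);
    max_area_fraction: segments covering more than this fraction of the image
    are treated as background and excluded from patch extraction.
    """

    scale: float = 100.0
    sigma: float = 1.0
    min_size: int = 50
    max_area_fraction: float = 0.25

    def validate(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")
        if self.min_size < 1:
            raise ConfigurationError(f"min_size must be >= 1, got {self.min_size}")
        if not (0 < self.max_area_fraction <= 1):
            raise ConfigurationError(
                f"max_area_fraction must be in (0,1], got {self.max_area_fraction}")


@dataclass
class SuperpixelPatch:
    """One retained segment: its tight bbox and a square resampled crop."""

    parent_id: str
    segment_id: int
    bbox: tuple[int, int, int, int]  # half-open [x0,x1) x [y0,y1)
    patch: np.ndarray  # (patch_size, patch_size, 3) float in [0,1]
    area: int

    @property
    def patch_id(self) -> str:
        return f"{self.parent_id}:{self.segment_id}"


def segment_image(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Partition an RGB image into superpixels; returns an integer label map.

    Every pixel gets exactly one label; no segment is smaller than
    ``min_size``; the result is deterministic for fixed inputs.
    """
    params = params or SegmentationParams()
    params.validate()
    image = np.asarray(image)
    if image.size == 0:
        raise ArgumentError("image is empty")
    return felzenszwalb(image, scale=params.scale, sigma=params.sigma,
                        min_size=params.min_size, channel_axis=-1)


def _square_crop(image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Square crop of side max(w,h) centered on the box center.

    The window is clipped to image bounds and edge-padded (replicate) back to
    square, so border segments keep their aspect without new colors.
    """
    h, w = image.shape[:2]
    x0, y0, x1, y1 = bbox
    side = max(x1 - x0, y1 - y0)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    wx0 = int(np.floor(cx - side / 2.0))
    wy0 = int(np.floor(cy - side / 2.0))
    wx1, wy1 = wx0 + side, wy0 + side
    ix0, iy0 = max(wx0, 0), max(wy0, 0)
    ix1, iy1 = min(wx1, w), min(wy1, h)
    crop = image[iy0:iy1, ix0:ix1]
    pad = ((iy0 - wy0, wy1 - iy1), (ix0 - wx0, wx1 - ix1), (0, 0))
    if any(p != (0, 0) for p in pad[:2]):
        crop = np.pad(crop, pad, mode="edge")
    return crop


def extract_patches(
    image: np.ndarray,
    label_map: np.ndarray,
    params: SegmentationParams | None = None,
    patch_size: int = 64,
    parent_id: str = "",
) -> list[SuperpixelPatch]:
    """Crop every non-background segment into a square, resampled patch.

    Segments whose area exceeds ``max_area_fraction`` of the image (the
    dominant sediment segment) are skipped.  Crops are bilinear-resampled to
    ``patch_size`` x ``patch_size``.
    """
    params = params or SegmentationParams()
    params.validate()
    image = np.asarray(image, dtype=np.float64)
    if label_map.shape != image.shape[:2]:
        raise ArgumentError(
            f"label_map shape {label_map.shape} does not match image {image.shape[:2]}")
    total = label_map.size
    patches = []
    labels, counts = np.unique(label_map, return_counts=True)
    # One pass over pixel coordinates per label via sorted flat indices.
    order = np.argsort(label_map, axis=None, kind="stable")
    ys, xs = np.unravel_index(order, label_map.shape)
    start = 0
    for lab, cnt in zip(labels, counts):
        sel_y, sel_x = ys[start:start + cnt], xs[start:start + cnt]
        start += cnt
        if cnt > params.max_area_fraction * total:
            continue
        bbox = (int(sel_x.min()), int(sel_y.min()),
                int(sel_x.max()) + 1, int(sel_y.max()) + 1)
        crop = _square_crop(image, bbox)
        patch = resize(crop, (patch_size, patch_size), order=1,
                       preserve_range=True, anti_aliasing=False)
        patches.append(SuperpixelPatch(parent_id=parent_id, segment_id=int(lab),
                                       bbox=bbox, patch=patch.astype(np.float32),
                                       area=int(cnt)))
    return patches


def sample_images(scene_ids: list[str], n: int, seed: int) -> list[str]:
    """Uniform sample of ``n`` scene ids without replacement, seeded."""
    if n > len(scene_ids):
        raise ArgumentError(f"cannot sample {n} from {len(scene_ids)} scenes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(scene_ids), size=n, replace=False)
    return [scene_ids[i] for i in idx]
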