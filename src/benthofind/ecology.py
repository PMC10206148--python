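"""Ecological summaries from georeferenced detections.

Detections inherit the position of their parent image (matched by
acquisition time to the navigation track); per-image seafloor footprints
follow from altitude and the camera field of view; abundance is individuals
per square metre of surveyed seafloor; diversity is the exponential of the
Shannon entropy of morphotype proportions (the effective number of equally
common morphotypes); spatial structure comes from gridding detections into
square blocks and normalizing counts by the summed footprint per block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .detection_eval import DetectionRecord
from .errors import ArgumentError
from .synthetic import EARTH_RADIUS_M, NavigationTrack


@dataclass
class GeoDetection:
    """A detection with the georeference of its parent image."""

    detection: DetectionRecord
    lon: float
    lat: float
    altitude: float
    footprint: float  # m^2

    def __post_init__(self) -> None:
        if self.footprint <= 0:
            raise ArgumentError(f"footprint must be > 0, got {self.footprint}")
        if self.altitude <= 0:
            raise ArgumentError(f"altitude must be > 0, got {self.altitude}")


@dataclass
class GridCell:
    index: tuple[int, int]
    count: int
    footprint_total: float

    @property
    def density(self) -> float:
        return self.count / self.footprint_total if self.footprint_total > 0 else math.nan


def georeference(image_times: Sequence[float], track: NavigationTrack,
                 max_gap_s: float = 60.0
                 ) -> tuple[dict[int, tuple[float, float, float]], list[int]]:
    """Assign each image the nearest navigation fix in time.

    Ties go to the earlier fix.  Returns (resolved, unresolved): ``resolved``
    maps the image index to (lon, lat, altitude); images farther than
    ``max_gap_s`` from every fix land in ``unresolved`` instead of being
    silently dropped.
    """
    if not track.fixes:
        raise ArgumentError("navigation track is empty")
    fix_t = np.array([f[0] for f in track.fixes])
    resolved: dict[int, tuple[float, float, float]] = {}
    unresolved: list[int] = []
    for i, t in enumerate(image_times):
        gaps = np.abs(fix_t - t)
        j = int(np.argmin(gaps))  # argmin takes the first (earlier) on ties
        if gaps[j] > max_gap_s:
            unresolved.append(i)
        else:
            _, lon, lat, alt = track.fixes[j]
            resolved[i] = (lon, lat, alt)
    return resolved, unresolved


def image_footprint(altitude_m: float, fov_x_deg: float = 64.0,
                    fov_y_deg: float = 64.0) -> float:
    """Seafloor area (m^2) imaged from ``altitude_m`` with the given FOV.

    footprint = (2 a tan(fov_x/2)) * (2 a tan(fov_y/2)); the default 64 x 64
    degree view angle is the towed platform's video-camera FOV.
    """
    if altitude_m <= 0:
        raise ArgumentError(f"altitude must be > 0, got {altitude_m}")
    for fov in (fov_x_deg, fov_y_deg):
        if not (0 < fov < 180):
            raise ArgumentError(f"fov must be in (0, 180) degrees, got {fov}")
    wx = 2.0 * altitude_m * math.tan(math.radians(fov_x_deg) / 2.0)
    wy = 2.0 * altitude_m * math.tan(math.radians(fov_y_deg) / 2.0)
    return wx * wy


def abundance(detections: Sequence[GeoDetection],
              survey_footprints: Sequence[float]
              ) -> tuple[float, dict[str, float]]:
    """Individuals per m^2, overall and per morphotype.

    The denominator is the summed footprint of ALL surveyed images, not just
    those containing detections.
    """
    total_area = float(np.sum(survey_footprints))
    if total_area <= 0:
        raise ArgumentError("total surveyed footprint must be > 0")
    per_class: dict[str, float] = {}
    for g in detections:
        per_class[g.detection.label] = per_class.get(g.detection.label, 0) + 1
    overall = len(detections) / total_area
    return overall, {k: v / total_area for k, v in sorted(per_class.items())}


def shannon_effective(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Effective number of morphotypes: exp of the Shannon entropy.

    Equals the number of classes exactly at uniform counts; invariant under
    rescaling all counts by a positive constant.
    """
    vals = np.asarray(list(counts.values()) if isinstance(counts, Mapping)
                      else counts, dtype=float)
    if np.any(vals < 0):
        raise ArgumentError("counts must be >= 0")
    total = vals.sum()
    if total <= 0:
        raise ArgumentError("total count must be > 0")
    p = vals[vals > 0] / total
    return float(np.exp(-np.sum(p * np.log(p))))


def lonlat_to_local(lons: Sequence[float], lats: Sequence[float]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection to planar metres.

    x = R * dlon * cos(mean lat), y = R * dlat, about the mean position;
    adequate at survey scale (km).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lat0 = lats.mean()
    x = EARTH_RADIUS_M * np.radians(lons - lons.mean()) * math.cos(math.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lats - lats.mean())
    return x, y


def grid_density(points_xy: Sequence[tuple[float, float]],
                 image_xy: Sequence[tuple[float, float]],
                 image_footprints: Sequence[float],
                 cell_size: float = 200.0) -> list[GridCell]:
    """Grid detections into square blocks and normalize by block footprint.

    ``points_xy`` are detection positions and ``image_xy`` the image-center
    positions (both planar metres); cell index = (floor(x/cell),
    floor(y/cell)); a block's footprint sums the footprints of the images
    whose centers fall in it.
    """
    if cell_size <= 0:
        raise ArgumentError(f"cell_size must be > 0, got {cell_size}")
    cells: dict[tuple[int, int], GridCell] = {}

    def key(x: float, y: float) -> tuple[int, int]:
        return int(math.floor(x / cell_size)), int(math.floor(y / cell_size))

    for (x, y), fp in zip(image_xy, image_footprints):
        k = key(x, y)
        cell = cells.setdefault(k, GridCell(index=k, count=0, footprint_total=0.0))
        cell.footprint_total += fp
    for x, y in points_xy:
        k = key(x, y)
        cell = cells.setdefault(k, GridCell(index=k, count=0, footprint_total=0.0))
        cell.count += 1
    return [cells[k] for k in sorted(cells)]
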