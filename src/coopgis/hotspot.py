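"""Thiessen-polygon behavior hotspot maps.

Ethogram annotations are made spatially explicit by time-syncing each one
to the nearest state of the imputed (gap-free, regular-grid) track.  The
room is then tessellated into Thiessen (Voronoi) polygons seeded by the
animal's unique imputed locations, and each polygon is scored with the
fraction f of its synced behavior points that carry the label of interest.
For display the fraction is quantized into four classes: high (f > 0.75),
medium (0.25 <= f <= 0.75), low (0 < f < 0.25) and none (f = 0, or no
points in the polygon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .ctcrw import StateEstimate
from .io import ETHOGRAM, BehaviorAnnotation
from .room import RoomGeometry

SNAP = 0.01  # m; coincident Thiessen seeds are snapped to a 1 cm grid


@dataclass(frozen=True)
class SpatialBehaviorPoint:
    """One behavior annotation matched to an imputed location."""

    animal_id: str
    t: float
    x: float
    y: float
    label: str


@dataclass
class SyncReport:
    n_matched: int
    n_dropped: int


@dataclass
class HotspotMap:
    """Per-behavior Thiessen map: polygons, intensity fractions, classes."""

    label: str
    polygons: list[Polygon]
    fractions: list[float | None]  # None where the polygon holds no points
    classes: list[str]
    counts: list[int]  # label-specific point counts per polygon
    totals: list[int]  # all synced points per polygon


def time_sync(
    annotations: Sequence[BehaviorAnnotation],
    grid_track: Sequence[StateEstimate],
    tolerance: float = 4.0,
) -> tuple[list[SpatialBehaviorPoint], SyncReport]:
    """Match each annotation to the nearest grid state within tolerance.

    Ties between two equidistant grid states resolve to the earlier one;
    annotations with no grid state within the tolerance are dropped and
    counted in the report.
    """
    if not grid_track:
        raise ValueError("empty track")
    ts = np.array([s.t for s in grid_track])
    matched: list[SpatialBehaviorPoint] = []
    dropped = 0
    for a in annotations:
        i = int(np.searchsorted(ts, a.t))
        best, best_d = None, None
        for j in (i - 1, i):
            if 0 <= j < len(ts):
                d = abs(ts[j] - a.t)
                if best_d is None or d < best_d:  # strict: earlier time wins ties
                    best, best_d = j, d
        if best is None or best_d > tolerance:
            dropped += 1
            continue
        s = grid_track[best]
        matched.append(
            SpatialBehaviorPoint(a.animal_id, a.t, float(s.mean[0]), float(s.mean[2]), a.label)
        )
    return matched, SyncReport(n_matched=len(matched), n_dropped=dropped)


def thiessen_tessellation(
    seed_points: np.ndarray, room: RoomGeometry
) -> tuple[list[Polygon], np.ndarray]:
    """Voronoi polygons of the seed points, clipped to the room rectangle.

    Seeds are snapped to a 1 cm grid and de-duplicated first.  Bounded
    cells are obtained by mirroring the seeds across each of the four
    walls, so every original seed's region is finite and the clipped cells
    tile the room exactly (the room is convex).  Returns (polygons, snapped
    unique seeds), index-aligned.
    """
    pts = np.asarray(seed_points, float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no seed points")
    snapped = np.round(pts / SNAP) * SNAP
    uniq = np.unique(snapped, axis=0)
    w, d = room.width, room.depth
    if len(uniq) == 1:
        return [room.boundary_polygon()], uniq
    mirrors = [
        uniq,
        np.column_stack([-uniq[:, 0], uniq[:, 1]]),          # x = 0 wall
        np.column_stack([2 * w - uniq[:, 0], uniq[:, 1]]),   # x = w wall
        np.column_stack([uniq[:, 0], -uniq[:, 1]]),          # y = 0 wall
        np.column_stack([uniq[:, 0], 2 * d - uniq[:, 1]]),   # y = d wall
    ]
    vor = Voronoi(np.vstack(mirrors))
    rect = room.boundary_polygon()
    polys: list[Polygon] = []
    for i in range(len(uniq)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # cannot happen with mirrored seeds
            raise RuntimeError("unbounded Voronoi region for an interior seed")
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)
    return polys, uniq


def behavior_intensity(
    polygons: Sequence[Polygon],
    points: Sequence[SpatialBehaviorPoint],
    behavior: str,
) -> tuple[list[float | None], list[int], list[int]]:
    """Per-polygon fraction of synced points carrying the target label.

    Each point is assigned to the polygon containing it; a point on a
    shared boundary goes to the lowest polygon index.  Polygons with no
    points get fraction None.  Returns (fractions, label counts, totals).
    """
    if behavior not in ETHOGRAM["behavior"]:
        raise ValueError(f"unknown behavior label {behavior!r}")
    tree = STRtree(list(polygons))
    counts = [0] * len(polygons)
    totals = [0] * len(polygons)
    eps = 1e-9
    for pt in points:
        g = Point(pt.x, pt.y)
        cand = sorted(tree.query(g.buffer(eps)))
        idx = None
        for j in cand:
            if polygons[j].distance(g) <= eps:
                idx = int(j)
                break
        if idx is None:
            continue  # outside the room
        totals[idx] += 1
        if pt.label == behavior:
            counts[idx] += 1
    fractions: list[float | None] = [
        (counts[i] / totals[i] if totals[i] > 0 else None) for i in range(len(polygons))
    ]
    return fractions, counts, totals


def quantize(f: float | None) -> str:
    """Four-class intensity quantization: high / medium / low / none.

    f > 0.75 is high, 0.25 <= f <= 0.75 medium, 0 < f < 0.25 low, and
    f = 0 or undefined (no points) none.
    """
    if f is None:
        return "none"
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if f > 0.75:
        return "high"
    if f >= 0.25:
        return "medium"
    if f > 0.0:
        return "low"
    return "none"


def hotspot_map(
    points: Sequence[SpatialBehaviorPoint],
    room: RoomGeometry,
    behavior: str,
) -> HotspotMap:
    """Build the Thiessen hotspot map of one behavior for one animal.

    Seeds are the animal's unique synced locations (snapped to 1 cm); each
    polygon is scored with the fraction of its points carrying the label.
    """
    if not points:
        raise ValueError("no spatial behavior points")
    seeds = np.array([[p.x, p.y] for p in points])
    polys, _ = thiessen_tessellation(seeds, room)
    fractions, counts, totals = behavior_intensity(polys, points, behavior)
    classes = [quantize(f) for f in fractions]
    return HotspotMap(behavior, list(polys), fractions, classes, counts, totals)
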