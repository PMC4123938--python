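"""Room geometry for the indoor enclosure.

The study system is a rectangular non-cage laying-hen room, 6 m by 4.5 m,
furnished with tube feeders, a bank of nest boxes on one wall, a three-rail
perch structure over a slatted strip, and a nipple water line across the
middle of the room.  All geometry is planar, in meters, with the origin at
one room corner: x runs along the 6 m wall, y along the 4.5 m wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.base import BaseGeometry

FEATURE_KINDS = ("feeder", "nest_box", "perch", "water_line")


@dataclass(frozen=True)
class Feature:
    """One furnishing of the room: a polygon (footprint) or polyline."""

    kind: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}"
            )


@dataclass(frozen=True)
class RoomGeometry:
    """A rectangular room with furnishing features in room coordinates.

    Parameters
    ----------
    width:
        Extent along x, meters (default 6.0).
    depth:
        Extent along y, meters (default 4.5).
    features:
        Furnishings (feeders, nest boxes, perch strip, water line).  Every
        feature geometry must lie within the room rectangle.
    """

    width: float = 6.0
    depth: float = 4.5
    features: tuple[Feature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.depth > 0):
            raise ValueError("room width and depth must be positive")
        rect = self.boundary_polygon().buffer(1e-9)
        for f in self.features:
            if not rect.contains(f.geometry):
                raise ValueError(f"feature {f.kind!r} lies outside the room")

    @property
    def area(self) -> float:
        """Floor area in m^2 (27.0 for the default room)."""
        return self.width * self.depth

    def boundary_polygon(self) -> Polygon:
        return box(0.0, 0.0, self.width, self.depth)

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width and 0.0 <= y <= self.depth

    def clip_point(self, x: float, y: float) -> tuple[float, float]:
        """Clamp a point to the room rectangle."""
        return (min(max(x, 0.0), self.width), min(max(y, 0.0), self.depth))

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def distance_to_feature(self, kind: str, x: float, y: float) -> float:
        """Distance from (x, y) to the nearest feature of the given kind.

        Returns +inf if the room has no such feature.
        """
        feats = self.features_of_kind(kind)
        if not feats:
            return float("inf")
        p = Point(x, y)
        return min(f.geometry.distance(p) for f in feats)


def default_room() -> RoomGeometry:
    """The furnished 6 m x 4.5 m study room.

    Layout: two tube feeders on the open floor, a 16-box (8 x 2) nest-box
    bank along the far (y = depth) wall, a 1 m x 6 m perch/slat strip along
    the near (y = 0) wall, and the water line running across the middle of
    the room parallel to the long wall.
    """
    feeders = [Point(1.8, 2.9).buffer(0.2, 16), Point(4.2, 2.9).buffer(0.2, 16)]
    nest_box = box(1.4, 4.2, 4.6, 4.5)  # 3.2 m bank of 0.4 m boxes, 0.3 m deep
    perch = box(0.0, 0.0, 6.0, 1.0)
    water = LineString([(0.5, 2.25), (5.5, 2.25)])
    features = (
        Feature("feeder", feeders[0]),
        Feature("feeder", feeders[1]),
        Feature("nest_box", nest_box),
        Feature("perch", perch),
        Feature("water_line", water),
    )
    return RoomGeometry(6.0, 4.5, features)
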