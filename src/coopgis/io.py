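"""Log records and file formats.

Two plain-CSV interchange formats are defined:

* sensor log      — header ``animal_id,t,x,y``; one time-stamped planar fix
                    per row, meters, seconds since the study epoch;
* behavior log    — header ``animal_id,t,category,label``; one instantaneous
                    ethogram annotation per row.

Both are comma-separated UTF-8 with a '.' decimal point.  Polygon outputs
(home ranges, Thiessen maps) are exported as GeoJSON FeatureCollections in
room coordinates.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from shapely.geometry import mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

#: Ethogram vocabulary: mutually exclusive labels within each category.
ETHOGRAM: dict[str, tuple[str, ...]] = {
    "posture": ("walk", "stand", "sit"),
    "behavior": ("feed", "drink", "preen", "dust_bathe", "forage", "rest"),
    "resource": ("feeder", "drinker", "perch", "nest_box"),
}
#: Behavior labels reported in time budgets (the rest goes to "other").
BUDGET_LABELS = ETHOGRAM["behavior"]


class LogParseError(ValueError):
    """Malformed row in a log file; message names the offending line."""


class LogValidationError(ValueError):
    """Structurally valid file violating a log invariant."""


@dataclass(frozen=True)
class SensorFix:
    """One time-stamped planar position measurement of one animal."""

    animal_id: str
    t: float  # seconds since the study epoch
    x: float  # meters; may fall slightly outside the room (sensor noise)
    y: float


@dataclass(frozen=True)
class BehaviorAnnotation:
    """One instantaneous ethogram annotation of one animal."""

    animal_id: str
    t: float
    category: str
    label: str

    def __post_init__(self) -> None:
        if self.category not in ETHOGRAM:
            raise ValueError(f"unknown category {self.category!r}")
        if self.label not in ETHOGRAM[self.category]:
            raise ValueError(
                f"label {self.label!r} is not in the {self.category!r} ethogram"
            )


def _fmt(v: float) -> str:
    """Canonical number formatting: integers bare, floats via shortest repr."""
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def _parse_float(s: str, line_no: int, col: str) -> float:
    try:
        v = float(s)
    except ValueError:
        raise LogParseError(f"line {line_no}: column {col!r} is not a number: {s!r}")
    if v != v or v in (float("inf"), float("-inf")):
        raise LogParseError(f"line {line_no}: column {col!r} is not finite: {s!r}")
    return v


SENSOR_HEADER = ["animal_id", "t", "x", "y"]
BEHAVIOR_HEADER = ["animal_id", "t", "category", "label"]


def read_sensor_log(path: str | Path) -> dict[str, list[SensorFix]]:
    """Read a sensor log CSV, returning fixes grouped by animal.

    Fixes are returned sorted by time within each animal (the file order
    must already be non-decreasing per animal; a time that repeats or runs
    backwards raises :class:`LogValidationError`).
    """
    path = Path(path)
    out: dict[str, list[SensorFix]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != SENSOR_HEADER:
            raise LogParseError(
                f"line 1: expected header {','.join(SENSOR_HEADER)!r}, got {header!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LogParseError(f"line {line_no}: expected 4 columns, got {len(row)}")
            animal_id = row[0]
            t = _parse_float(row[1], line_no, "t")
            x = _parse_float(row[2], line_no, "x")
            y = _parse_float(row[3], line_no, "y")
            fixes = out.setdefault(animal_id, [])
            if fixes and t <= fixes[-1].t:
                raise LogValidationError(
                    f"line {line_no}: time {t} not strictly increasing for "
                    f"animal {animal_id!r} (previous {fixes[-1].t})"
                )
            fixes.append(SensorFix(animal_id, t, x, y))
    if not out:
        log.warning("sensor log %s contains no fixes", path)
    return out


def write_sensor_log(fixes: Mapping[str, Sequence[SensorFix]], path: str | Path) -> None:
    """Write fixes grouped by animal to the canonical sensor-log CSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SENSOR_HEADER)
        for animal_id in fixes:
            for f in fixes[animal_id]:
                writer.writerow([f.animal_id, _fmt(f.t), _fmt(f.x), _fmt(f.y)])


def read_behavior_log(path: str | Path) -> list[BehaviorAnnotation]:
    """Read a behavior annotation log, validating the ethogram vocabulary."""
    path = Path(path)
    out: list[BehaviorAnnotation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != BEHAVIOR_HEADER:
            raise LogParseError(
                f"line 1: expected header {','.join(BEHAVIOR_HEADER)!r}, got {header!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LogParseError(f"line {line_no}: expected 4 columns, got {len(row)}")
            animal_id, t_s, category, label = row
            t = _parse_float(t_s, line_no, "t")
            if category not in ETHOGRAM:
                raise LogValidationError(f"line {line_no}: unknown category {category!r}")
            if label not in ETHOGRAM[category]:
                raise LogValidationError(
                    f"line {line_no}: label {label!r} is not a "
                    f"{category!r} ethogram label"
                )
            out.append(BehaviorAnnotation(animal_id, t, category, label))
    if not out:
        log.warning("behavior log %s is empty", path)
    return out


def write_behavior_log(
    annotations: Iterable[BehaviorAnnotation], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(BEHAVIOR_HEADER)
        for a in annotations:
            writer.writerow([a.animal_id, _fmt(a.t), a.category, a.label])


class GeometryError(ValueError):
    """Invalid (e.g. self-intersecting) geometry passed to the exporter."""


def export_geojson(
    geometries: Sequence[tuple[BaseGeometry, Mapping[str, object]]],
    path: str | Path | None = None,
) -> dict:
    """Build a GeoJSON FeatureCollection from (geometry, properties) pairs.

    Geometries are in room coordinates (meters).  Properties are carried
    verbatim.  If ``path`` is given the document is also written there.
    """
    features = []
    for geom, props in geometries:
        if not geom.is_valid:
            raise GeometryError(f"invalid geometry: {geom.wkt[:80]}")
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(geom),
                "properties": dict(props),
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return doc
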