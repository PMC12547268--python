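"""Zone geometry, polygon annotations and tabular count I/O shared by all stages.

Coordinate convention: pixel coordinates with origin at the top-left corner,
x increasing rightward and y increasing downward.  Vertical zones are indexed
1..K from the top of the frame to the bottom, so for the aviary side view
zone 1 is the upmost tier and zone 4 is the litter floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "DAY_TYPES",
    "MEASURES",
    "EXCLUDE_PREFIX",
    "Zone",
    "ZoneMap",
    "Detection",
    "CountRecord",
    "read_zone_annotation",
    "write_zone_annotation",
    "assign_zone",
    "read_counts",
    "write_counts",
    "records_to_frame",
    "frame_to_records",
    "clock_to_seconds",
    "seconds_to_clock",
]

DAY_TYPES = ("visual", "frustrative", "auditory", "control")
MEASURES = ("vertical_movement", "litter_zone_count")

#: Label prefix marking an annotation polygon as an exclusion region
#: (e.g. the stairs between the third tier and the litter).
EXCLUDE_PREFIX = "exclude:"

PointXY = tuple[float, float]


@dataclass(frozen=True)
class Zone:
    """One vertical zone: an indexed, labelled simple polygon."""

    index: int
    label: str
    polygon: tuple[PointXY, ...]

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class ZoneMap:
    """Ordered vertical zone polygons plus exclusion regions for one camera view.

    Invariants checked at construction: every polygon is simple, all vertices
    lie within the frame, zone interiors are pairwise disjoint, and zone
    indices are consecutive from 1.
    """

    frame_width: int
    frame_height: int
    zones: list[Zone]
    exclusion_polygons: list[tuple[PointXY, ...]] = field(default_factory=list)
    zone_order: str = "top-to-bottom"

    def __post_init__(self) -> None:
        self._validate()
        self._zone_polys = [z.shapely() for z in self.zones]
        self._excl_polys = [Polygon(p) for p in self.exclusion_polygons]

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if not self.zones:
            raise ValueError("zone map must contain at least one zone")
        indices = [z.index for z in self.zones]
        if indices != list(range(1, len(self.zones) + 1)):
            raise ValueError(
                f"zone indices must be consecutive from 1, got {indices}"
            )
        for zone in self.zones:
            self._check_polygon(zone.polygon, f"zone {zone.index} ({zone.label!r})")
        for i, poly in enumerate(self.exclusion_polygons):
            self._check_polygon(poly, f"exclusion polygon {i}")
        shp = [z.shapely() for z in self.zones]
        for i in range(len(shp)):
            for j in range(i + 1, len(shp)):
                inter = shp[i].intersection(shp[j])
                if inter.area > 1e-9:
                    raise ValueError(
                        "zone interiors overlap: "
                        f"zone {self.zones[i].index} and zone {self.zones[j].index}"
                    )

    def _check_polygon(self, poly: Sequence[PointXY], name: str) -> None:
        if len(poly) < 3:
            raise ValueError(f"{name}: polygon needs at least 3 vertices")
        p = Polygon(poly)
        if not p.is_valid or p.area <= 0:
            raise ValueError(f"{name}: polygon is not simple")
        for x, y in poly:
            if not (0 <= x <= self.frame_width and 0 <= y <= self.frame_height):
                raise ValueError(
                    f"{name}: vertex ({x}, {y}) outside frame "
                    f"{self.frame_width}x{self.frame_height}"
                )

    # -- conveniences -------------------------------------------------------

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    def zone_polygon(self, index: int) -> Polygon:
        return self._zone_polys[index - 1]

    def exclusion_shapely(self) -> list[Polygon]:
        return list(self._excl_polys)

    def label_of(self, index: int) -> str:
        return self.zones[index - 1].label

    def in_frame(self, point: PointXY) -> bool:
        x, y = point
        return 0 <= x <= self.frame_width and 0 <= y <= self.frame_height


def assign_zone(point: PointXY, zonemap: ZoneMap) -> Optional[int]:
    """Return the index of the zone containing ``point``, or ``None``.

    Points inside any exclusion polygon map to ``None``; points exactly on a
    boundary shared by two zones are deterministically assigned to the zone
    with the lower index.  Raises ``ValueError`` for points outside the frame.
    """
    if not zonemap.in_frame(point):
        raise ValueError(f"point {point} outside frame bounds")
    p = Point(point)
    for excl in zonemap._excl_polys:
        if excl.covers(p):
            return None
    for zone, poly in zip(zonemap.zones, zonemap._zone_polys):
        if poly.covers(p):
            return zone.index
    return None


# ---------------------------------------------------------------------------
# Labelme-dialect annotation files
# ---------------------------------------------------------------------------


def read_zone_annotation(path: str | Path) -> ZoneMap:
    """Read a Labelme-style polygon annotation JSON into a validated ZoneMap.

    Zone order is inferred from the top-to-bottom ordering of polygon
    centroids; polygon labels with the ``exclude:`` prefix become exclusion
    regions instead of zones.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed zone annotation {path}: {exc}") from exc
    try:
        width = int(payload["imageWidth"])
        height = int(payload["imageHeight"])
        shapes = payload["shapes"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"zone annotation {path} missing required keys") from exc

    zone_shapes: list[tuple[str, tuple[PointXY, ...]]] = []
    exclusions: list[tuple[PointXY, ...]] = []
    for shape in shapes:
        if shape.get("shape_type") != "polygon":
            raise ValueError(
                f"unsupported shape_type {shape.get('shape_type')!r} in {path}"
            )
        pts = tuple((float(x), float(y)) for x, y in shape["points"])
        label = str(shape.get("label", ""))
        if label.startswith(EXCLUDE_PREFIX):
            exclusions.append(pts)
        else:
            zone_shapes.append((label, pts))

    # top-to-bottom by centroid y; ties broken by centroid x for determinism
    def centroid_key(item: tuple[str, tuple[PointXY, ...]]):
        c = Polygon(item[1]).centroid
        return (c.y, c.x)

    zone_shapes.sort(key=centroid_key)
    zones = [
        Zone(index=i + 1, label=label, polygon=pts)
        for i, (label, pts) in enumerate(zone_shapes)
    ]
    return ZoneMap(
        frame_width=width,
        frame_height=height,
        zones=zones,
        exclusion_polygons=exclusions,
    )


def write_zone_annotation(zonemap: ZoneMap, path: str | Path) -> None:
    shapes = [
        {
            "label": z.label,
            "points": [[float(x), float(y)] for x, y in z.polygon],
            "shape_type": "polygon",
        }
        for z in zonemap.zones
    ]
    shapes += [
        {
            "label": f"{EXCLUDE_PREFIX}{i}",
            "points": [[float(x), float(y)] for x, y in poly],
            "shape_type": "polygon",
        }
        for i, poly in enumerate(zonemap.exclusion_polygons)
    ]
    payload = {
        "imageWidth": zonemap.frame_width,
        "imageHeight": zonemap.frame_height,
        "shapes": shapes,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Detection:
    """One bounding-box detection in a single frame."""

    frame_index: int
    box: tuple[float, float, float, float]  # x1, y1, x2, y2
    score: float = 1.0

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}: need x1<x2 and y1<y2")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def center(self) -> PointXY:
        x1, y1, x2, y2 = self.box
        return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


# ---------------------------------------------------------------------------
# Count records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountRecord:
    """A per-interval count keyed by group, week, day type and clock time.

    ``value`` is a nonnegative count; fractional values are permitted for
    interval-averaged occupancy series (the stress model later enforces
    integer counts where its likelihood requires them).
    """

    group_id: str
    week: int
    day_type: str
    clock_time: int  # seconds since midnight
    interval_s: int
    measure: str
    value: float
    zone_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative count {self.value}")
        if self.interval_s <= 0:
            raise ValueError("interval must be positive")
        if self.week < 1:
            raise ValueError("week must be >= 1")
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"unknown day_type {self.day_type!r}")


COUNT_COLUMNS = [
    "group_id",
    "week",
    "day_type",
    "clock_time",
    "interval_s",
    "measure",
    "zone_label",
    "value",
]


def clock_to_seconds(clock: str) -> int:
    """Parse an ISO-8601 ``HH:MM:SS`` (or ``HH:MM``) clock time to seconds."""
    parts = clock.split(":")
    if len(parts) == 2:
        parts.append("0")
    if len(parts) != 3:
        raise ValueError(f"bad clock time {clock!r}")
    h, m, s = (int(p) for p in parts)
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"bad clock time {clock!r}")
    return h * 3600 + m * 60 + s


def seconds_to_clock(seconds: int) -> str:
    seconds = int(seconds)
    h, rem = divmod(seconds, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _sort_key(r: CountRecord):
    return (r.group_id, r.week, r.day_type, r.clock_time,
            r.measure, r.zone_label or "")


def records_to_frame(records: Iterable[CountRecord]) -> pd.DataFrame:
    rows = [
        {
            "group_id": r.group_id,
            "week": r.week,
            "day_type": r.day_type,
            "clock_time": seconds_to_clock(r.clock_time),
            "interval_s": r.interval_s,
            "measure": r.measure,
            "zone_label": r.zone_label if r.zone_label is not None else "",
            "value": r.value,
        }
        for r in sorted(records, key=_sort_key)
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CountRecord]:
    records = []
    for i, row in df.iterrows():
        try:
            zone_label = row["zone_label"]
            if pd.isna(zone_label) or zone_label == "":
                zone_label = None
            value = float(row["value"])
            if value == int(value):
                value = int(value)
            records.append(
                CountRecord(
                    group_id=str(row["group_id"]),
                    week=int(row["week"]),
                    day_type=str(row["day_type"]),
                    clock_time=clock_to_seconds(str(row["clock_time"])),
                    interval_s=int(row["interval_s"]),
                    measure=str(row["measure"]),
                    zone_label=zone_label,
                    value=value,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"invalid count record at row {i}: {exc}") from exc
    keys = [
        (r.group_id, r.week, r.day_type, r.clock_time, r.measure, r.zone_label)
        for r in records
    ]
    if len(set(keys)) != len(keys):
        seen: set = set()
        for k in keys:
            if k in seen:
                raise ValueError(f"duplicate count record key {k}")
            seen.add(k)
    return sorted(records, key=_sort_key)


def read_counts(path: str | Path) -> list[CountRecord]:
    """Read a counts CSV and return validated, sorted CountRecords."""
    df = pd.read_csv(path, dtype={"group_id": str, "clock_time": str,
                                  "zone_label": str}, keep_default_na=False)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts CSV {path} missing columns {missing}")
    return frame_to_records(df)


def write_counts(records: Iterable[CountRecord], path: str | Path) -> None:
    """Write CountRecords as a sorted UTF-8 CSV with a mandatory header."""
    df = records_to_frame(records)
    # integral values serialize without a trailing .0 so reruns are
    # byte-identical regardless of intermediate dtypes
    df["value"] = df["value"].map(
        lambda v: int(v) if float(v) == int(v) else float(v)
    )
    df.to_csv(path, index=False)
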