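"""Hen counts per litter zone, densities and spatial heatmaps.

A trained neural detector is out of scope here; instead this module offers
(a) ingestion of externally produced bounding-box detections and (b) a
background-subtraction reference detector that is adequate for synthetic
scenes.  Zone membership is decided by the bounding-box centre.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry_io import CountRecord, Detection, ZoneMap, assign_zone

__all__ = [
    "LitterGrid",
    "reference_detect",
    "ingest_detections",
    "write_detections",
    "zone_counts",
    "density",
    "occupancy_heatmap",
    "aggregate_series",
    "count_litter_video",
]

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["frame_index", "x1", "y1", "x2", "y2", "score"]


@dataclass
class LitterGrid:
    """Two litter zones (system-side / wall-side) with a physical scale.

    ``litter_area`` defaults to the 4 m^2 top-view field of the litter
    camera; override for other rigs.
    """

    zonemap: ZoneMap
    litter_area: float = 4.0  # m^2
    px_per_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.zonemap.n_zones != 2:
            raise ValueError("litter grid requires exactly 2 zones")
        if self.litter_area <= 0:
            raise ValueError("litter_area must be positive")

    @property
    def zone_labels(self) -> list[str]:
        return [z.label for z in self.zonemap.zones]


_EIGHT = np.ones((3, 3), dtype=bool)


def reference_detect(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float = 25.0,
    min_area: float = 60.0,
    max_area: float = 4000.0,
    merge_px: int = 2,
    frame_index: int = 0,
) -> list[Detection]:
    """Background-subtraction detector: |frame - background| thresholded,
    8-connected components with area in [min_area, max_area] reported as
    bounding boxes with score 1.0."""
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame/background size mismatch: {frame.shape} vs {background.shape}"
        )
    mask = np.abs(frame - background) > threshold
    if not mask.any():
        return []
    if merge_px > 0:
        yy, xx = np.ogrid[-merge_px : merge_px + 1, -merge_px : merge_px + 1]
        disk = xx * xx + yy * yy <= merge_px * merge_px
        merged = ndimage.binary_dilation(mask, structure=disk)
    else:
        merged = mask
    labels, n = ndimage.label(merged, structure=_EIGHT)
    motion_labels = np.where(mask, labels, 0)
    detections: list[Detection] = []
    for obj_slice, lab in zip(ndimage.find_objects(motion_labels), range(1, n + 1)):
        if obj_slice is None:
            continue
        component = motion_labels[obj_slice] == lab
        area = int(component.sum())
        if not (min_area <= area <= max_area):
            continue
        ys, xs = np.nonzero(component)
        y_off, x_off = obj_slice[0].start, obj_slice[1].start
        detections.append(
            Detection(
                frame_index=frame_index,
                box=(
                    float(x_off + xs.min()),
                    float(y_off + ys.min()),
                    float(x_off + xs.max() + 1),
                    float(y_off + ys.max() + 1),
                ),
                score=1.0,
            )
        )
    detections.sort(key=lambda d: (d.box[1], d.box[0]))
    return detections


def ingest_detections(path: str | Path) -> list[Detection]:
    """Read a detections CSV (frame_index, x1, y1, x2, y2, score)."""
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detections CSV {path} missing columns {missing}")
    detections = []
    for i, row in df.iterrows():
        try:
            detections.append(
                Detection(
                    frame_index=int(row["frame_index"]),
                    box=(
                        float(row["x1"]),
                        float(row["y1"]),
                        float(row["x2"]),
                        float(row["y2"]),
                    ),
                    score=float(row["score"]),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: header line plus 1-based numbering
            raise ValueError(f"invalid detection at line {i + 2}: {exc}") from exc
    return detections


def write_detections(detections: Sequence[Detection], path: str | Path) -> None:
    rows = [
        {
            "frame_index": d.frame_index,
            "x1": d.box[0],
            "y1": d.box[1],
            "x2": d.box[2],
            "y2": d.box[3],
            "score": d.score,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def zone_counts(
    detections: Sequence[Detection], grid: LitterGrid
) -> dict[str, int]:
    """Per-zone hen counts for one frame, assigning each detection by its
    box centre; detections whose centre lies in no zone are dropped and
    logged."""
    counts = {label: 0 for label in grid.zone_labels}
    for det in detections:
        cx, cy = det.center
        zm = grid.zonemap
        cx = min(max(cx, 0.0), float(zm.frame_width))
        cy = min(max(cy, 0.0), float(zm.frame_height))
        zone = assign_zone((cx, cy), zm)
        if zone is None:
            log.info("detection at (%.1f, %.1f) outside litter zones, dropped",
                     cx, cy)
            continue
        counts[zm.label_of(zone)] += 1
    return counts


def density(total_count: float, grid: LitterGrid) -> float:
    """Hens per square metre of litter."""
    if grid.litter_area <= 0:
        raise ValueError("litter area must be positive")
    return total_count / grid.litter_area


def occupancy_heatmap(
    detections: Sequence[Detection],
    bins: tuple[int, int],
    frame_size: tuple[int, int],
) -> np.ndarray:
    """(ny, nx) histogram of detection centres, normalized to sum 1 when
    non-empty.  ``bins`` is (nx, ny); ``frame_size`` is (width, height)."""
    nx, ny = bins
    if nx < 1 or ny < 1:
        raise ValueError("bins must be >= 1")
    width, height = frame_size
    if not detections:
        return np.zeros((ny, nx))
    xs = np.array([d.center[0] for d in detections])
    ys = np.array([d.center[1] for d in detections])
    hist, _, _ = np.histogram2d(
        ys, xs, bins=(ny, nx), range=[[0, height], [0, width]]
    )
    total = hist.sum()
    return hist / total if total > 0 else hist


def aggregate_series(
    per_frame: pd.DataFrame,
    frame_rate: float,
    interval_s: int = 60,
    group_id: str = "G1",
    week: int = 1,
    day_type: str = "control",
    clock_anchor: int = 0,
    round_digits: Optional[int] = None,
) -> list[CountRecord]:
    """Interval-averaged occupancy series per zone.

    ``per_frame`` needs columns frame_index, zone_label, count.  Each output
    record holds the mean per-frame count of its interval (unrounded by
    default).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    df = per_frame.copy()
    df["interval"] = (df["frame_index"] / frame_rate // interval_s).astype(int)
    records: list[CountRecord] = []
    grouped = df.groupby(["zone_label", "interval"])["count"].mean()
    for (zone_label, interval), mean_count in grouped.items():
        value = float(mean_count)
        if round_digits is not None:
            value = round(value, round_digits)
        records.append(
            CountRecord(
                group_id=group_id,
                week=week,
                day_type=day_type,
                clock_time=clock_anchor + interval * interval_s,
                interval_s=interval_s,
                measure="litter_zone_count",
                zone_label=str(zone_label),
                value=value,
            )
        )
    records.sort(key=lambda r: (r.clock_time, r.zone_label or ""))
    return records


def count_litter_video(
    frames: np.ndarray,
    background: np.ndarray,
    grid: LitterGrid,
    threshold: float = 25.0,
    min_area: float = 60.0,
    max_area: float = 4000.0,
) -> tuple[pd.DataFrame, list[Detection]]:
    """Run the reference detector over a frame stack and tabulate per-frame
    zone counts.  Returns (per_frame counts frame, all detections)."""
    rows = []
    all_detections: list[Detection] = []
    for i in range(frames.shape[0]):
        dets = reference_detect(
            frames[i], background, threshold=threshold,
            min_area=min_area, max_area=max_area, frame_index=i,
        )
        all_detections.extend(dets)
        counts = zone_counts(dets, grid)
        for label, n in counts.items():
            rows.append({"frame_index": i, "zone_label": label, "count": n})
    return pd.DataFrame(rows, columns=["frame_index", "zone_label", "count"]), all_detections
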