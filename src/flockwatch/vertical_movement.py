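"""Directed vertical-movement counting between stacked zones from video frames.

The counter works on consecutive-frame pixel differences: frames are
greyscale, Gaussian-blurred, differenced and thresholded; connected motion
regions become blobs; blobs are linked into short tracks by greedy
nearest-neighbour association; a track whose zone label changes between two
consecutive observations yields one directed crossing event.  Motion blobs
whose centroid falls inside an exclusion region (the stairs between the
third tier and the litter) are dropped, so traffic through that region is
never counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry_io import CountRecord, ZoneMap, assign_zone

__all__ = [
    "MovementConfig",
    "MotionBlob",
    "Track",
    "CrossingEvent",
    "preprocess",
    "frame_difference",
    "extract_blobs",
    "associate",
    "Tracker",
    "detect_crossings",
    "aggregate_per_minute",
    "count_movements",
    "subsample_frames",
]


@dataclass
class MovementConfig:
    """Tunable parameters of the movement counter.

    The source method fixes the processing rate (4 frames/s) but leaves the
    blur kernel, difference threshold, minimum blob area and association
    rules open; all are configurable here.
    """

    blur_kernel: int = 5
    blur_sigma: Optional[float] = None  # None -> derived from kernel size
    diff_threshold: float = 25.0
    min_area: float = 30.0
    merge_px: int = 5  # dilation radius used to merge fragments of one motion
    max_link_distance: float = 60.0
    max_gap: int = 3
    frame_rate: float = 4.0


@dataclass(frozen=True)
class MotionBlob:
    frame_index: int
    centroid: tuple[float, float]
    area: float
    zone: Optional[int] = None


@dataclass
class Track:
    track_id: int
    # ordered (frame_index, centroid, zone) observations
    observations: list[tuple[int, tuple[float, float], Optional[int]]] = field(
        default_factory=list
    )

    @property
    def last_frame(self) -> int:
        return self.observations[-1][0]

    @property
    def last_position(self) -> tuple[float, float]:
        return self.observations[-1][1]


@dataclass(frozen=True)
class CrossingEvent:
    """A directed movement of one tracked object between two zones."""

    time: float  # seconds
    from_zone: int
    to_zone: int
    direction: str  # "up" | "down"
    track_id: int = -1
    agent_id: int = -1

    def __post_init__(self) -> None:
        if self.from_zone == self.to_zone:
            raise ValueError("crossing requires distinct zones")
        expected = "up" if self.to_zone < self.from_zone else "down"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with "
                f"{self.from_zone}->{self.to_zone}"
            )


def direction_of(from_zone: int, to_zone: int) -> str:
    """Zone 1 is the upmost tier, so moving to a lower index is 'up'."""
    return "up" if to_zone < from_zone else "down"


# ---------------------------------------------------------------------------
# Image operations
# ---------------------------------------------------------------------------


def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2.0
    x = np.arange(size) - half
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def auto_sigma(kernel_size: int) -> float:
    # standard heuristic relating kernel extent to Gaussian width
    return 0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8


def preprocess(
    frame: np.ndarray, kernel_size: int = 5, sigma: Optional[float] = None
) -> np.ndarray:
    """Gaussian-blur a greyscale frame (separable convolution, edge replicate).

    Returns a float64 image; the normalized kernel preserves constant frames
    exactly and total mass of impulses.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim != 2:
        raise ValueError(f"expected a single-channel frame, got shape {frame.shape}")
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    if sigma is None:
        sigma = auto_sigma(kernel_size)
    k = _gaussian_kernel_1d(kernel_size, sigma)
    out = frame.astype(np.float64)
    out = ndimage.convolve1d(out, k, axis=0, mode="nearest")
    out = ndimage.convolve1d(out, k, axis=1, mode="nearest")
    return out


def frame_difference(
    prev: np.ndarray, cur: np.ndarray, threshold: float = 25.0
) -> np.ndarray:
    """Binary motion mask: set where |cur - prev| exceeds ``threshold``."""
    prev = np.asarray(prev, dtype=np.float64)
    cur = np.asarray(cur, dtype=np.float64)
    if prev.shape != cur.shape:
        raise ValueError(f"frame size mismatch: {prev.shape} vs {cur.shape}")
    return np.abs(cur - prev) > threshold


_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def extract_blobs(
    mask: np.ndarray,
    min_area: float = 30.0,
    merge_px: int = 5,
    zonemap: Optional[ZoneMap] = None,
    frame_index: int = 0,
) -> list[MotionBlob]:
    """8-connected motion components of ``mask`` with area >= ``min_area``.

    ``merge_px`` dilates the mask before labelling so that nearby fragments
    of a single moving object (e.g. leading and trailing difference crescents)
    form one blob; areas and centroids are computed from the original mask
    pixels.  When a ``zonemap`` is given, blobs whose centroid falls in an
    exclusion polygon are dropped and the remaining blobs carry zone labels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    if merge_px > 0:
        # separable Chebyshev dilation: fast and sufficient for merging
        merged = ndimage.maximum_filter(
            mask.view(np.uint8), size=2 * merge_px + 1
        ).astype(bool)
    else:
        merged = mask
    labels, n = ndimage.label(merged, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    # restrict statistics to true motion pixels inside each merged component
    ys, xs = np.nonzero(mask)
    labs = labels[ys, xs]
    areas = np.bincount(labs, minlength=n + 1)[1:]
    sum_y = np.bincount(labs, weights=ys, minlength=n + 1)[1:]
    sum_x = np.bincount(labs, weights=xs, minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        cys = sum_y / areas
        cxs = sum_x / areas
    blobs: list[MotionBlob] = []
    for area, cy, cx in zip(areas, cys, cxs):
        if area < min_area or not np.isfinite(cy):
            continue
        zone: Optional[int] = None
        if zonemap is not None:
            cx_c = min(max(cx, 0.0), float(zonemap.frame_width))
            cy_c = min(max(cy, 0.0), float(zonemap.frame_height))
            from shapely.geometry import Point

            pt = Point((cx_c, cy_c))
            if any(e.covers(pt) for e in zonemap._excl_polys):
                continue  # motion on the stairs is never counted
            zone = assign_zone((cx_c, cy_c), zonemap)
        blobs.append(
            MotionBlob(
                frame_index=frame_index,
                centroid=(float(cx), float(cy)),
                area=float(area),
                zone=zone,
            )
        )
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------


def associate(
    open_tracks: list[Track],
    blobs: Sequence[MotionBlob],
    max_link_distance: float,
    max_gap: int,
    frame_index: int,
    next_track_id: int,
) -> tuple[list[Track], list[Track], int]:
    """Greedy nearest-neighbour update of open tracks with one frame of blobs.

    Candidate (track, blob) pairs are processed in ascending distance order
    (ties by lower track_id, then blob input order); each track and blob is
    used at most once.  Unmatched blobs open new tracks; tracks unmatched for
    more than ``max_gap`` frames are closed.  Returns
    ``(open_tracks, closed_tracks, next_track_id)``.
    """
    pairs = []
    for ti, track in enumerate(open_tracks):
        tx, ty = track.last_position
        for bi, blob in enumerate(blobs):
            bx, by = blob.centroid
            d = math.hypot(bx - tx, by - ty)
            if d <= max_link_distance:
                pairs.append((d, track.track_id, bi, ti))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))

    used_tracks: set[int] = set()
    used_blobs: set[int] = set()
    for d, _tid, bi, ti in pairs:
        if ti in used_tracks or bi in used_blobs:
            continue
        used_tracks.add(ti)
        used_blobs.add(bi)
        blob = blobs[bi]
        open_tracks[ti].observations.append(
            (frame_index, blob.centroid, blob.zone)
        )

    for bi, blob in enumerate(blobs):
        if bi in used_blobs:
            continue
        open_tracks.append(
            Track(
                track_id=next_track_id,
                observations=[(frame_index, blob.centroid, blob.zone)],
            )
        )
        next_track_id += 1

    still_open: list[Track] = []
    closed: list[Track] = []
    for track in open_tracks:
        if frame_index - track.last_frame > max_gap:
            closed.append(track)
        else:
            still_open.append(track)
    return still_open, closed, next_track_id


class Tracker:
    """Stateful wrapper around :func:`associate` over a frame sequence."""

    def __init__(self, max_link_distance: float, max_gap: int) -> None:
        self.max_link_distance = max_link_distance
        self.max_gap = max_gap
        self.open_tracks: list[Track] = []
        self.closed_tracks: list[Track] = []
        self._next_id = 0

    def step(self, frame_index: int, blobs: Sequence[MotionBlob]) -> None:
        self.open_tracks, closed, self._next_id = associate(
            self.open_tracks,
            blobs,
            self.max_link_distance,
            self.max_gap,
            frame_index,
            self._next_id,
        )
        self.closed_tracks.extend(closed)

    def all_tracks(self) -> list[Track]:
        tracks = self.closed_tracks + self.open_tracks
        tracks.sort(key=lambda t: t.track_id)
        return tracks


# ---------------------------------------------------------------------------
# Crossing extraction and aggregation
# ---------------------------------------------------------------------------


def detect_crossings(
    tracks: Iterable[Track], frame_rate: float = 4.0
) -> list[CrossingEvent]:
    """One event per consecutive observation pair with differing zones.

    Observations with zone ``None`` (exclusion region or uncovered frame
    area) break the pair, so no event is ever produced across the stairs.
    The event time is the later frame's timestamp.
    """
    events: list[CrossingEvent] = []
    for track in tracks:
        obs = track.observations
        for (f0, _c0, z0), (f1, _c1, z1) in zip(obs, obs[1:]):
            if z0 is None or z1 is None or z0 == z1:
                continue
            events.append(
                CrossingEvent(
                    time=f1 / frame_rate,
                    from_zone=z0,
                    to_zone=z1,
                    direction=direction_of(z0, z1),
                    track_id=track.track_id,
                )
            )
    events.sort(key=lambda e: (e.time, e.track_id))
    return events


def aggregate_per_minute(
    events: Sequence[CrossingEvent],
    group_id: str = "G1",
    week: int = 1,
    day_type: str = "control",
    clock_anchor: int = 0,
    duration_s: Optional[float] = None,
    split_direction: bool = False,
) -> list[CountRecord]:
    """Per-minute counts of crossing events, zero-filled over the duration.

    ``clock_anchor`` is the wall-clock time (seconds since midnight) of video
    time zero; minutes with no events emit a zero record.
    """
    times = [e.time for e in events]
    if duration_s is None:
        duration_s = (max(times) + 1.0) if times else 60.0
    n_minutes = max(1, math.ceil(duration_s / 60.0))
    directions = ("up", "down") if split_direction else (None,)
    records: list[CountRecord] = []
    for d in directions:
        counts = [0] * n_minutes
        for e in events:
            if d is not None and e.direction != d:
                continue
            m = int(e.time // 60)
            if 0 <= m < n_minutes:
                counts[m] += 1
        for m, c in enumerate(counts):
            records.append(
                CountRecord(
                    group_id=group_id,
                    week=week,
                    day_type=day_type,
                    clock_time=clock_anchor + 60 * m,
                    interval_s=60,
                    measure="vertical_movement",
                    zone_label=d,
                    value=c,
                )
            )
    return records


def subsample_frames(
    frames: np.ndarray, source_rate: float, target_rate: float = 4.0
) -> np.ndarray:
    """Honor the 4 frames/s processing rate by striding higher-rate input."""
    if target_rate > source_rate:
        raise ValueError("cannot upsample frames")
    stride = int(round(source_rate / target_rate))
    return frames[::stride]


def count_movements(
    frames: np.ndarray | Sequence[np.ndarray],
    zonemap: ZoneMap,
    config: Optional[MovementConfig] = None,
) -> tuple[list[CrossingEvent], list[Track]]:
    """Full counter: blur, difference, blobs, tracks, crossing events.

    ``frames`` is a (T, H, W) greyscale stack already at the configured
    frame rate.  Returns time-sorted events and all tracks.
    """
    if config is None:
        config = MovementConfig()
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (T, H, W) frame stack")
    tracker = Tracker(config.max_link_distance, config.max_gap)
    prev = preprocess(frames[0], config.blur_kernel, config.blur_sigma)
    for i in range(1, frames.shape[0]):
        cur = preprocess(frames[i], config.blur_kernel, config.blur_sigma)
        mask = frame_difference(prev, cur, config.diff_threshold)
        blobs = extract_blobs(
            mask,
            min_area=config.min_area,
            merge_px=config.merge_px,
            zonemap=zonemap,
            frame_index=i,
        )
        tracker.step(i, blobs)
        prev = cur
    tracks = tracker.all_tracks()
    events = detect_crossings(tracks, config.frame_rate)
    return events, tracks
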