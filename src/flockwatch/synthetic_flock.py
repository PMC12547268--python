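"""Synthetic aviary videos, litter scenes and count series with ground truth.

The simulators emulate the statistical structure the analysis pipeline
assumes: hen-like agents jittering inside stacked zones with
Poisson-scheduled zone crossings, static litter scenes with known per-zone
counts, and per-minute count series with negative-binomial noise,
phase-specific means and a multiplicative (log-normal) week effect.

Rendering assumes convex zone polygons (the aviary use case is stacked
rectangles): straight-line walks between points of a zone then stay inside
it.  A crossing is realized as a translation across the shared zone boundary
over exactly 2 consecutive frames, so one scheduled crossing produces one
motion signature at 4 frames/s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import nearest_points

from .geometry_io import (
    CountRecord,
    Zone,
    ZoneMap,
    assign_zone,
    seconds_to_clock,
)
from .vertical_movement import CrossingEvent, direction_of

__all__ = [
    "FrameSeries",
    "VideoScenario",
    "GroundTruth",
    "RenderResult",
    "LitterScene",
    "CountSimParams",
    "stacked_zonemap",
    "litter_zonemap",
    "simulate_crossing_schedule",
    "render_video",
    "simulate_litter_scene",
    "simulate_count_series",
    "simulate_count_frame",
    "write_frames",
    "read_frames",
    "events_to_frame",
    "write_ground_truth",
]


@dataclass
class FrameSeries:
    """A greyscale frame stack with its frame rate."""

    frames: np.ndarray  # (T, H, W) uint8
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


def stacked_zonemap(
    width: int = 640,
    height: int = 480,
    n_zones: int = 4,
    labels: Optional[Sequence[str]] = None,
    stairs_exclusion: bool = False,
) -> ZoneMap:
    """Vertically stacked rectangular zones spanning the frame, indexed
    1 (top) .. K (bottom); optionally with a stairs-like exclusion rectangle
    straddling the boundary between the two lowest zones."""
    if labels is None:
        labels = (
            ["tier_top", "tier_middle", "tier_bottom", "litter"]
            if n_zones == 4
            else [f"zone_{i+1}" for i in range(n_zones)]
        )
    band = height / n_zones
    zones = []
    exclusions: list[tuple[tuple[float, float], ...]] = []
    for i in range(n_zones):
        y0, y1 = i * band, (i + 1) * band
        zones.append(
            Zone(
                index=i + 1,
                label=labels[i],
                polygon=((0, y0), (width, y0), (width, y1), (0, y1)),
            )
        )
    if stairs_exclusion and n_zones >= 2:
        yb = (n_zones - 1) * band
        x0, x1 = 0.05 * width, 0.22 * width
        exclusions.append(
            ((x0, yb - 0.35 * band), (x1, yb - 0.35 * band),
             (x1, yb + 0.35 * band), (x0, yb + 0.35 * band))
        )
    return ZoneMap(
        frame_width=width,
        frame_height=height,
        zones=zones,
        exclusion_polygons=exclusions,
    )


def litter_zonemap(width: int = 640, height: int = 480) -> ZoneMap:
    """Two side-by-side litter zones: system-side (left) and wall-side."""
    half = width / 2
    return ZoneMap(
        frame_width=width,
        frame_height=height,
        zones=[
            Zone(1, "system", ((0, 0), (half, 0), (half, height), (0, height))),
            Zone(2, "wall", ((half, 0), (width, 0), (width, height), (half, height))),
        ],
    )


# ---------------------------------------------------------------------------
# Crossing schedule
# ---------------------------------------------------------------------------


@dataclass
class VideoScenario:
    zonemap: ZoneMap
    n_agents: int = 8
    agent_radius: float = 9.0
    frame_rate: float = 4.0
    duration: float = 60.0
    # directed (from_zone, to_zone) -> events per minute
    crossing_rates: dict[tuple[int, int], float] = field(default_factory=dict)
    background_noise_sd: float = 0.0
    seed: int = 0
    background_level: int = 110
    agent_level: int = 210
    jitter_px: float = 2.5
    walk_step: float = 10.0
    min_event_gap_frames: int = 3
    # optional explicit starting zone per agent (default: round-robin 1..K)
    initial_zones: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.n_agents < 0:
            raise ValueError("n_agents must be >= 0")
        if self.initial_zones is not None:
            if len(self.initial_zones) != self.n_agents:
                raise ValueError("initial_zones must have n_agents entries")
            if any(not (1 <= z <= self.zonemap.n_zones)
                   for z in self.initial_zones):
                raise ValueError("initial_zones out of range")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for pair, rate in self.crossing_rates.items():
            if rate < 0:
                raise ValueError(f"negative rate for pair {pair}")
            i, j = pair
            k = self.zonemap.n_zones
            if not (1 <= i <= k and 1 <= j <= k) or i == j:
                raise ValueError(f"bad zone pair {pair}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def boundary_margin(self) -> float:
        # keep resting agents far enough from zone boundaries that their
        # motion blobs can never merge with an agent on the other side
        return max(2.0 * self.agent_radius, 12.0)


@dataclass(frozen=True)
class ScheduledEvent:
    time: float
    from_zone: int
    to_zone: int
    agent_id: int

    @property
    def direction(self) -> str:
        return direction_of(self.from_zone, self.to_zone)


@dataclass
class GroundTruth:
    events: list[ScheduledEvent]
    occupancy: np.ndarray  # (n_frames, n_zones) agent counts
    initial_zones: list[int]
    frame_rate: float

    def __post_init__(self) -> None:
        n = len(self.initial_zones)
        if self.occupancy.size and not np.all(self.occupancy.sum(axis=1) == n):
            raise ValueError("occupancy must sum to n_agents in every frame")

    def crossing_events(self) -> list[CrossingEvent]:
        return [
            CrossingEvent(
                time=e.time,
                from_zone=e.from_zone,
                to_zone=e.to_zone,
                direction=e.direction,
                agent_id=e.agent_id,
            )
            for e in self.events
        ]


def simulate_crossing_schedule(scenario: VideoScenario) -> GroundTruth:
    """Draw a Poisson crossing schedule and assign agents to events.

    Per directed zone pair, event counts are Poisson with mean
    rate * duration and times uniform on the clip, snapped to the frame grid
    (a video realization cannot resolve sub-frame timing).  Agents are
    assigned in time order among those currently in the source zone whose
    previous event is at least ``min_event_gap_frames`` frames away; if no
    agent qualifies the schedule is infeasible and an error advises raising
    ``n_agents``.
    """
    rng = np.random.default_rng(scenario.seed)
    n_frames = scenario.n_frames
    k = scenario.zonemap.n_zones
    raw: list[tuple[int, int, int]] = []  # (event_frame, from, to)
    for (i, j), rate in sorted(scenario.crossing_rates.items()):
        if rate <= 0:
            continue
        n = rng.poisson(rate * scenario.duration / 60.0)
        times = rng.uniform(0.0, scenario.duration, size=n)
        for t in times:
            ef = int(round(t * scenario.frame_rate))
            ef = min(max(ef, 2), max(n_frames - 3, 2))
            raw.append((ef, i, j))
    raw.sort()

    if scenario.initial_zones is not None:
        initial_zones = list(scenario.initial_zones)
    else:
        initial_zones = [(a % k) + 1 for a in range(scenario.n_agents)]
    zone_now = list(initial_zones)
    last_event_frame = [-(10**9)] * scenario.n_agents

    events: list[ScheduledEvent] = []
    for ef, i, j in raw:
        candidates = [
            a
            for a in range((scenario.n_agents))
            if zone_now[a] == i
            and ef - last_event_frame[a] >= scenario.min_event_gap_frames
        ]
        if not candidates:
            raise ValueError(
                f"no free agent in zone {i} at frame {ef}: crossing rates are "
                "too high for this population, increase n_agents"
            )
        agent = int(rng.choice(candidates))
        zone_now[agent] = j
        last_event_frame[agent] = ef
        events.append(
            ScheduledEvent(
                time=ef / scenario.frame_rate, from_zone=i, to_zone=j, agent_id=agent
            )
        )

    occupancy = np.zeros((n_frames, k), dtype=int)
    zone_traj = np.empty((n_frames, scenario.n_agents), dtype=int)
    for a, z in enumerate(initial_zones):
        zone_traj[:, a] = z
    for e in events:
        ef = int(round(e.time * scenario.frame_rate))
        # the agent's centre is still in the source zone at the event frame
        # (staged at the boundary) and in the destination zone one frame later
        zone_traj[ef + 1 :, e.agent_id] = e.to_zone
    for z in range(1, k + 1):
        occupancy[:, z - 1] = (zone_traj == z).sum(axis=1)

    return GroundTruth(
        events=events,
        occupancy=occupancy,
        initial_zones=initial_zones,
        frame_rate=scenario.frame_rate,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderResult:
    frames: FrameSeries
    positions: np.ndarray  # (n_frames, n_agents, 2) agent centres (x, y)


def _interior(poly: Polygon, margin: float) -> Polygon:
    eroded = poly.buffer(-margin)
    if eroded.is_empty or eroded.area <= 0:
        raise ValueError(
            f"zone too small for agent radius/margin {margin:.1f}px"
        )
    if eroded.geom_type != "Polygon":  # keep the largest piece
        eroded = max(eroded.geoms, key=lambda g: g.area)
    return eroded


def _sample_point(
    rng: np.random.Generator,
    region: Polygon,
    exclusions: Sequence[Polygon],
    clearance: float,
    max_tries: int = 2000,
) -> tuple[float, float]:
    minx, miny, maxx, maxy = region.bounds
    for _ in range(max_tries):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        p = Point(x, y)
        if not region.covers(p):
            continue
        if any(e.distance(p) < clearance for e in exclusions):
            continue
        return (x, y)
    raise ValueError("could not place an agent: zone capacity exceeded")


def _sample_home(
    rng: np.random.Generator,
    region: Polygon,
    exclusions: Sequence[Polygon],
    clearance: float,
    used: Sequence[np.ndarray],
    separation: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Sample a home point keeping a separation from previously used homes;
    falls back to an unconstrained sample if the zone is too crowded."""
    for _ in range(max_tries):
        cand = np.array(_sample_point(rng, region, exclusions, clearance))
        if all(np.linalg.norm(cand - u) >= separation for u in used):
            return cand
    return np.array(_sample_point(rng, region, exclusions, clearance))


def _crossing_points(
    zonemap: ZoneMap,
    from_zone: int,
    to_zone: int,
    exclusions: Sequence[Polygon],
    clearance: float,
    delta: float = 3.0,
    near: Optional[tuple[float, float]] = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Staging point just inside the source zone and landing point just
    inside the destination zone, straddling their shared boundary away from
    any exclusion region.  With a ``near`` hint the crossing point is placed
    close to it (keeping concurrent crossings of different agents apart)."""
    pa = zonemap.zone_polygon(from_zone)
    pb = zonemap.zone_polygon(to_zone)
    shared = pa.boundary.intersection(pb.boundary)
    if shared.is_empty:
        # non-adjacent zones: jump between the mutually nearest points
        qa, qb = nearest_points(pa, pb)
        ca = np.array([qa.x, qa.y])
        cb = np.array([qb.x, qb.y])
        u = cb - ca
        u = u / max(np.linalg.norm(u), 1e-9)
        return tuple(ca - delta * u), tuple(cb + delta * u)
    if shared.geom_type != "LineString":
        shared = max(
            (g for g in getattr(shared, "geoms", [shared])
             if isinstance(g, LineString)),
            key=lambda g: g.length,
            default=None,
        )
        if shared is None:
            raise ValueError(
                f"zones {from_zone} and {to_zone} share no boundary edge"
            )
    ca = np.array(pa.centroid.coords[0])
    cb = np.array(pb.centroid.coords[0])
    normal = ca - cb
    normal = normal / max(np.linalg.norm(normal), 1e-9)
    fracs = [0.5, 0.35, 0.65, 0.25, 0.75, 0.45, 0.55]
    if near is not None and shared.length > 0:
        f = shared.project(Point(near), normalized=True)
        fracs = [min(max(f, 0.05), 0.95)] + fracs
    for frac in fracs:
        c = np.array(shared.interpolate(frac, normalized=True).coords[0])
        staging = tuple(c + delta * normal)
        landing = tuple(c - delta * normal)
        ps, pl = Point(staging), Point(landing)
        if not (pa.covers(ps) and pb.covers(pl)):
            continue
        if any(e.distance(ps) < clearance or e.distance(pl) < clearance
               for e in exclusions):
            continue
        return staging, landing
    raise ValueError(
        f"no admissible crossing point between zones {from_zone} and {to_zone}"
    )


def _advance(
    pos: np.ndarray,
    target: np.ndarray,
    step_len: float,
    zone_poly: Polygon,
    obstacles: Sequence[Polygon],
) -> np.ndarray:
    """One walking step toward ``target`` staying inside the zone and out of
    obstacle regions; deflects sideways in fixed angular increments when the
    direct step is blocked (deterministic)."""
    d = target - pos
    dist = float(np.linalg.norm(d))
    if dist < 1e-9:
        return pos
    if dist <= step_len:
        cand = target
        if not any(o.covers(Point(tuple(cand))) for o in obstacles):
            return cand
    u = d / dist
    for deg in (0, 25, -25, 50, -50, 75, -75, 100, -100, 130, -130, 160, -160):
        ang = math.radians(deg)
        c, s = math.cos(ang), math.sin(ang)
        v = np.array([u[0] * c - u[1] * s, u[0] * s + u[1] * c])
        cand = pos + step_len * v
        p = Point(tuple(cand))
        if any(o.covers(p) for o in obstacles):
            continue
        if not zone_poly.covers(p):
            continue
        return cand
    return pos


def _draw_ellipse(
    frame: np.ndarray, cx: float, cy: float, rx: float, ry: float, level: int
) -> None:
    h, w = frame.shape
    x0 = max(int(math.floor(cx - rx)), 0)
    x1 = min(int(math.ceil(cx + rx)) + 1, w)
    y0 = max(int(math.floor(cy - ry)), 0)
    y1 = min(int(math.ceil(cy + ry)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys = np.arange(y0, y1)[:, None]
    xs = np.arange(x0, x1)[None, :]
    inside = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
    frame[y0:y1, x0:x1][inside] = level


def render_video(scenario: VideoScenario, truth: GroundTruth) -> RenderResult:
    """Rasterize agents as filled ellipses over a noisy uniform background.

    Between events an agent jitters around a home point well inside its zone;
    around an event it walks to a staging point at the shared boundary and
    translates across it over exactly 2 consecutive frames, then walks to a
    new home in the destination zone.  Agents never enter exclusion polygons.
    """
    zm = scenario.zonemap
    rng = np.random.default_rng(scenario.seed + 1)
    n_frames = scenario.n_frames
    n_agents = scenario.n_agents
    margin = scenario.boundary_margin
    exclusions = [e.buffer(scenario.agent_radius * 0.5) for e in zm._excl_polys]
    path_obstacles = [e.buffer(1.5) for e in zm._excl_polys]
    interiors = {
        z.index: _interior(zm.zone_polygon(z.index), margin) for z in zm.zones
    }
    clearance = scenario.agent_radius + 2.0

    events_by_agent: dict[int, list[ScheduledEvent]] = {
        a: [] for a in range(n_agents)
    }
    for e in truth.events:
        events_by_agent[e.agent_id].append(e)
    for evs in events_by_agent.values():
        evs.sort(key=lambda e: e.time)

    positions = np.zeros((n_frames, n_agents, 2), dtype=float)
    rx = scenario.agent_radius
    ry = 0.8 * scenario.agent_radius
    home_separation = 4.0 * scenario.agent_radius
    used_homes: list[np.ndarray] = []

    for a in range(n_agents):
        zone = truth.initial_zones[a] if n_agents else 1
        home = _sample_home(
            rng, interiors[zone], exclusions, clearance,
            used_homes, home_separation,
        )
        used_homes.append(home)
        pos = home.copy()
        queue = list(events_by_agent[a])
        pending: Optional[tuple[int, np.ndarray, np.ndarray, int]] = None
        walking_home = False
        for f in range(n_frames):
            if pending is None and queue:
                e = queue[0]
                ef = int(round(e.time * scenario.frame_rate))
                staging, landing = _crossing_points(
                    zm, e.from_zone, e.to_zone, exclusions, clearance,
                    near=tuple(pos),
                )
                pending = (ef, np.array(staging), np.array(landing), e.to_zone)
                queue.pop(0)
            if f == 0:
                positions[f, a] = pos
                continue
            if pending is not None:
                ef, staging, landing, to_zone = pending
                if f == ef:
                    pos = staging.copy()
                    positions[f, a] = pos
                    continue
                if f == ef + 1:
                    pos = landing.copy()
                    positions[f, a] = pos
                    zone = to_zone
                    home = _sample_home(
                        rng, interiors[zone], exclusions, clearance,
                        used_homes, home_separation,
                    )
                    used_homes.append(home)
                    walking_home = True
                    pending = None
                    continue
                if f < ef:
                    # approach the staging point so as to arrive exactly at ef
                    d = float(np.linalg.norm(staging - pos))
                    frames_left = ef - f
                    if d / frames_left >= 0.8 * scenario.walk_step or (
                        frames_left <= 2 and d > scenario.jitter_px
                    ):
                        step = min(scenario.walk_step, d / frames_left)
                        pos = _advance(
                            pos, staging, step, zm.zone_polygon(zone),
                            path_obstacles,
                        )
                        positions[f, a] = pos
                        continue
            if walking_home:
                pos = _advance(
                    pos, home, scenario.walk_step, zm.zone_polygon(zone),
                    path_obstacles,
                )
                if float(np.linalg.norm(home - pos)) < 1e-9:
                    walking_home = False
                positions[f, a] = pos
                continue
            # idle jitter uniformly within a disk around home
            r = scenario.jitter_px * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            pos = home + np.array([r * math.cos(theta), r * math.sin(theta)])
            positions[f, a] = pos

    frames = np.empty(
        (n_frames, zm.frame_height, zm.frame_width), dtype=np.uint8
    )
    for f in range(n_frames):
        img = np.full(
            (zm.frame_height, zm.frame_width),
            float(scenario.background_level),
        )
        if scenario.background_noise_sd > 0:
            img += rng.normal(0.0, scenario.background_noise_sd, img.shape)
        base = np.clip(img, 0, 255)
        for a in range(n_agents):
            cx, cy = positions[f, a]
            _draw_ellipse(base, cx, cy, rx, ry, scenario.agent_level)
        frames[f] = base.astype(np.uint8)

    return RenderResult(
        frames=FrameSeries(frames=frames, frame_rate=scenario.frame_rate),
        positions=positions,
    )


# ---------------------------------------------------------------------------
# Litter scenes
# ---------------------------------------------------------------------------


@dataclass
class LitterScene:
    frames: FrameSeries
    background: np.ndarray
    positions: np.ndarray  # (n_agents, 2)
    truth: pd.DataFrame  # frame_index, zone_label, count


def _zone_index_for_label(zonemap: ZoneMap, needle: str) -> int:
    for z in zonemap.zones:
        if needle in z.label.lower():
            return z.index
    raise ValueError(f"no zone labelled like {needle!r} in zone map")


def simulate_litter_scene(
    n_wall: int,
    n_system: int,
    zonemap: ZoneMap,
    seed: int = 0,
    n_frames: int = 4,
    frame_rate: float = 4.0,
    agent_radius: float = 9.0,
    background_level: int = 95,
    agent_level: int = 205,
    noise_sd: float = 0.0,
    min_separation: Optional[float] = None,
) -> LitterScene:
    """Static top-view litter scene with known per-zone hen counts.

    Agents are placed uniformly inside the requested zone with pairwise
    centre separation of at least ``min_separation`` (default: just over one
    agent diameter, i.e. no overlap); placement failure raises a capacity
    error.  Truth counts equal the requested counts in every frame.
    """
    if n_wall < 0 or n_system < 0:
        raise ValueError("counts must be >= 0")
    if zonemap.n_zones != 2:
        raise ValueError("litter zone map must have exactly 2 zones")
    rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = 2.0 * agent_radius + 2.0
    wall_idx = _zone_index_for_label(zonemap, "wall")
    system_idx = _zone_index_for_label(zonemap, "system")
    exclusions = [e.buffer(agent_radius * 0.5) for e in zm_excl(zonemap)]
    placed: list[tuple[float, float]] = []
    zones_of: list[int] = []
    for zone_idx, n in ((system_idx, n_system), (wall_idx, n_wall)):
        interior = _interior(zonemap.zone_polygon(zone_idx), agent_radius + 1.0)
        for _ in range(n):
            ok = False
            for _try in range(4000):
                cand = _sample_point(rng, interior, exclusions, agent_radius + 1.0)
                if all(
                    math.hypot(cand[0] - px, cand[1] - py) >= min_separation
                    for px, py in placed
                ):
                    placed.append(cand)
                    zones_of.append(zone_idx)
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"zone {zone_idx} capacity exceeded for {n} agents"
                )

    background = np.full(
        (zonemap.frame_height, zonemap.frame_width),
        float(background_level),
    )
    frames = np.empty(
        (n_frames, zonemap.frame_height, zonemap.frame_width), dtype=np.uint8
    )
    rx, ry = agent_radius, 0.8 * agent_radius
    for f in range(n_frames):
        img = background.copy()
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
        img = np.clip(img, 0, 255)
        for (cx, cy) in placed:
            _draw_ellipse(img, cx, cy, rx, ry, agent_level)
        frames[f] = img.astype(np.uint8)

    rows = []
    for f in range(n_frames):
        rows.append({"frame_index": f, "zone_label": zonemap.label_of(wall_idx),
                     "count": n_wall})
        rows.append({"frame_index": f, "zone_label": zonemap.label_of(system_idx),
                     "count": n_system})
    truth = pd.DataFrame(rows)
    return LitterScene(
        frames=FrameSeries(frames=frames, frame_rate=frame_rate),
        background=background.astype(np.uint8),
        positions=np.array(placed) if placed else np.zeros((0, 2)),
        truth=truth,
    )


def zm_excl(zonemap: ZoneMap) -> list[Polygon]:
    return zonemap.exclusion_shapely()


# ---------------------------------------------------------------------------
# Count series
# ---------------------------------------------------------------------------


@dataclass
class CountSimParams:
    """Generating model for per-minute count series.

    For each week w a log-scale intercept b_w ~ Normal(0, week_sd^2) is
    drawn (shared by all groups); each minute of each phase then yields
    y ~ NB2(mean = phase_mean * exp(b_w), dispersion k) with variance
    mean + mean^2 / k.
    """

    phase_means: dict[str, float]
    phase_durations: dict[str, int]  # minutes
    week_sd: float = 0.1
    nb_dispersion: float = 5.0
    n_weeks: int = 10
    n_groups: int = 4
    seed: int = 0
    day_type: str = "control"
    measure: str = "vertical_movement"
    anchor_clock: int = 9 * 3600

    def __post_init__(self) -> None:
        if set(self.phase_means) != set(self.phase_durations):
            raise ValueError("phase_means and phase_durations must share keys")
        if any(m <= 0 for m in self.phase_means.values()):
            raise ValueError("phase means must be positive")
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValueError("phase durations must be positive")
        if self.week_sd < 0:
            raise ValueError("week_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if k > 1e6:  # quasi-Poisson limit
        return rng.poisson(mean)
    return rng.negative_binomial(k, k / (k + mean))


def simulate_count_frame(params: CountSimParams) -> pd.DataFrame:
    """Simulate the count series as a tidy frame with explicit phase labels.

    Columns: group, week, phase, minute (within phase), clock_time (s),
    value.
    """
    rng = np.random.default_rng(params.seed)
    b = rng.normal(0.0, params.week_sd, size=params.n_weeks)
    rows = []
    for w in range(1, params.n_weeks + 1):
        week_factor = math.exp(b[w - 1])
        for g in range(1, params.n_groups + 1):
            offset = 0
            for phase, mean in params.phase_means.items():
                dur = params.phase_durations[phase]
                mu = mean * week_factor
                ys = _nb_draw(rng, np.full(dur, mu), params.nb_dispersion)
                for m in range(dur):
                    rows.append(
                        {
                            "group": f"G{g}",
                            "week": w,
                            "phase": phase,
                            "minute": m,
                            "clock_time": params.anchor_clock + 60 * (offset + m),
                            "value": int(ys[m]),
                        }
                    )
                offset += dur
    return pd.DataFrame(rows)


def simulate_count_series(params: CountSimParams) -> list[CountRecord]:
    df = simulate_count_frame(params)
    return [
        CountRecord(
            group_id=row["group"],
            week=int(row["week"]),
            day_type=params.day_type,
            clock_time=int(row["clock_time"]),
            interval_s=60,
            measure=params.measure,
            value=int(row["value"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Disk I/O for frames and ground truth
# ---------------------------------------------------------------------------


def write_frames(series: FrameSeries, outdir: str | Path) -> Path:
    """Write frames as a PNG sequence plus a manifest JSON; returns outdir."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i in range(series.n_frames):
        iio.imwrite(outdir / f"frame_{i:06d}.png", series.frames[i])
    manifest = {
        "n_frames": series.n_frames,
        "frame_rate": series.frame_rate,
        "height": int(series.frames.shape[1]),
        "width": int(series.frames.shape[2]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_frames(indir: str | Path) -> FrameSeries:
    import imageio.v3 as iio

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    frames = np.stack(
        [
            iio.imread(indir / f"frame_{i:06d}.png")
            for i in range(manifest["n_frames"])
        ]
    )
    return FrameSeries(frames=frames, frame_rate=float(manifest["frame_rate"]))


def events_to_frame(events: Sequence[ScheduledEvent] | Sequence[CrossingEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "time_s": e.time,
                "from_zone": e.from_zone,
                "to_zone": e.to_zone,
                "agent_id": getattr(e, "agent_id", -1),
            }
        )
    return pd.DataFrame(rows, columns=["time_s", "from_zone", "to_zone", "agent_id"])


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_to_frame(truth.events).to_csv(outdir / "events.csv", index=False)
    occ = pd.DataFrame(
        truth.occupancy,
        columns=[f"zone_{i+1}" for i in range(truth.occupancy.shape[1])],
    )
    occ.insert(0, "frame_index", np.arange(truth.occupancy.shape[0]))
    occ.to_csv(outdir / "occupancy.csv", index=False)
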