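import numpy as np
import pytest

from flockwatch.geometry_io import Zone, ZoneMap
from flockwatch.vertical_movement import (
    CrossingEvent,
    MotionBlob,
    MovementConfig,
    Track,
    Tracker,
    aggregate_per_minute,
    associate,
    count_movements,
    detect_crossings,
    extract_blobs,
    frame_difference,
    preprocess,
    subsample_frames,
    _gaussian_kernel_1d,
    auto_sigma,
)


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------


def test_blur_preserves_constant_frame():
    frame = np.full((20, 30), 77, dtype=np.uint8)
    out = preprocess(frame)
    assert np.allclose(out, 77.0)


def test_blur_impulse_is_normalized_kernel():
    frame = np.zeros((21, 21))
    frame[10, 10] = 1000.0
    out = preprocess(frame, kernel_size=5)
    k = _gaussian_kernel_1d(5, auto_sigma(5))
    expected = 1000.0 * np.outer(k, k)
    assert np.allclose(out[8:13, 8:13], expected)
    assert np.isclose(out.sum(), 1000.0)


def test_blur_matches_direct_convolution_oracle(rng):
    frame = rng.integers(0, 256, size=(16, 19)).astype(np.float64)
    sigma = auto_sigma(5)
    k = _gaussian_kernel_1d(5, sigma)
    kernel2d = np.outer(k, k)
    padded = np.pad(frame, 2, mode="edge")
    expected = np.empty_like(frame)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            expected[i, j] = np.sum(padded[i : i + 5, j : j + 5] * kernel2d)
    assert np.allclose(preprocess(frame, 5, sigma), expected, atol=1e-9)


def test_blur_rejects_bad_input():
    with pytest.raises(ValueError):
        preprocess(np.zeros((0, 0)))
    with pytest.raises(ValueError):
        preprocess(np.zeros((4, 4, 3)))


# ---------------------------------------------------------------------------
# frame_difference
# ---------------------------------------------------------------------------


def test_identical_frames_give_empty_mask():
    frame = np.random.default_rng(0).integers(0, 255, (10, 10))
    assert not frame_difference(frame, frame, 25).any()


def _disk_mask(shape, cx, cy, r):
    ys, xs = np.mgrid[: shape[0], : shape[1]]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def test_moved_disk_covers_old_and_new_footprints_only():
    shape = (60, 60)
    prev = np.zeros(shape)
    cur = np.zeros(shape)
    old = _disk_mask(shape, 20, 30, 5)
    new = _disk_mask(shape, 31, 30, 5)  # moved past its diameter: disjoint
    prev[old] = 200.0
    cur[new] = 200.0
    mask = frame_difference(prev, cur, 25)
    assert np.array_equal(mask, old | new)


def test_frame_difference_matches_pixel_loop_oracle(rng):
    prev = rng.integers(0, 256, (12, 14)).astype(float)
    cur = rng.integers(0, 256, (12, 14)).astype(float)
    mask = frame_difference(prev, cur, 25)
    for i in range(12):
        for j in range(14):
            assert mask[i, j] == (abs(cur[i, j] - prev[i, j]) > 25)


def test_threshold_monotonicity(rng):
    prev = rng.integers(0, 256, (30, 30)).astype(float)
    cur = rng.integers(0, 256, (30, 30)).astype(float)
    counts = [
        frame_difference(prev, cur, t).sum() for t in (0, 10, 25, 50, 100, 200)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_size_mismatch_raises():
    with pytest.raises(ValueError):
        frame_difference(np.zeros((4, 4)), np.zeros((5, 4)))


# ---------------------------------------------------------------------------
# extract_blobs
# ---------------------------------------------------------------------------


def test_empty_mask_no_blobs():
    assert extract_blobs(np.zeros((20, 20), dtype=bool)) == []


def test_two_disjoint_squares():
    mask = np.zeros((100, 100), dtype=bool)
    mask[10:20, 10:20] = True
    mask[60:70, 60:70] = True
    blobs = extract_blobs(mask, min_area=50, merge_px=0)
    assert len(blobs) == 2
    centers = sorted(b.centroid for b in blobs)
    assert np.allclose(centers[0], (14.5, 14.5))
    assert np.allclose(centers[1], (64.5, 64.5))
    assert all(b.area == 100 for b in blobs)


def test_min_area_filters_small_components():
    mask = np.zeros((50, 50), dtype=bool)
    mask[5:8, 5:8] = True  # area 9
    assert extract_blobs(mask, min_area=50, merge_px=0) == []


def _flood_fill_labels(mask):
    """Independent 8-connected labelling oracle by explicit flood fill."""
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if labels[sy, sx]:
            continue
        next_label += 1
        stack = [(sy, sx)]
        labels[sy, sx] = next_label
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < mask.shape[0]
                        and 0 <= nx < mask.shape[1]
                        and mask[ny, nx]
                        and not labels[ny, nx]
                    ):
                        labels[ny, nx] = next_label
                        stack.append((ny, nx))
    return labels, next_label


def test_component_labels_match_flood_fill_oracle(rng):
    for _ in range(5):
        mask = rng.random((40, 40)) < 0.3
        blobs = extract_blobs(mask, min_area=1, merge_px=0)
        labels, n = _flood_fill_labels(mask)
        oracle = []
        for lab in range(1, n + 1):
            ys, xs = np.nonzero(labels == lab)
            oracle.append((round(float(xs.mean()), 6), round(float(ys.mean()), 6), len(ys)))
        got = [
            (round(b.centroid[0], 6), round(b.centroid[1], 6), int(b.area))
            for b in blobs
        ]
        assert sorted(got) == sorted(oracle)


def test_exclusion_blobs_dropped():
    zm = ZoneMap(
        100,
        100,
        [Zone(1, "top", ((0, 0), (100, 0), (100, 50), (0, 50))),
         Zone(2, "bottom", ((0, 50), (100, 50), (100, 100), (0, 100)))],
        [((40, 40), (60, 40), (60, 60), (40, 60))],
    )
    mask = np.zeros((100, 100), dtype=bool)
    mask[45:55, 45:55] = True  # centroid in the exclusion
    mask[10:18, 10:18] = True
    blobs = extract_blobs(mask, min_area=10, merge_px=0, zonemap=zm)
    assert len(blobs) == 1
    assert blobs[0].zone == 1


# ---------------------------------------------------------------------------
# associate
# ---------------------------------------------------------------------------


def blob(x, y, frame=1):
    return MotionBlob(frame_index=frame, centroid=(x, y), area=100.0)


def test_nearby_blob_extends_track():
    tracks = [Track(track_id=0, observations=[(0, (10, 10), 1)])]
    tracks, closed, nid = associate(tracks, [blob(12, 10)], 20, 3, 1, 1)
    assert closed == []
    assert len(tracks) == 1
    assert tracks[0].observations[-1] == (1, (12, 10), None)


def test_far_blob_opens_new_track():
    tracks = [Track(track_id=0, observations=[(0, (10, 10), 1)])]
    tracks, _closed, nid = associate(tracks, [blob(90, 90)], 20, 3, 1, 1)
    assert len(tracks) == 2
    assert nid == 2


def test_greedy_matches_exhaustive_oracle_on_crossing_2x2():
    import itertools

    # two objects whose paths crossed: each track's nearest blob is the
    # other object's previous neighbourhood
    t_pos = np.array([[10.0, 10.0], [30.0, 10.0]])
    b_pos = np.array([[28.0, 10.0], [12.0, 10.0]])
    tracks = [
        Track(track_id=i, observations=[(0, tuple(t_pos[i]), None)])
        for i in range(2)
    ]
    blobs = [blob(*b_pos[i]) for i in range(2)]
    tracks_out, _c, _n = associate(tracks, blobs, 1e9, 3, 1, 2)
    got = {
        t.track_id: t.observations[-1][1]
        for t in tracks_out
        if len(t.observations) == 2
    }
    d = np.linalg.norm(t_pos[:, None, :] - b_pos[None, :, :], axis=2)
    best = min(
        itertools.permutations(range(2)), key=lambda p: d[0, p[0]] + d[1, p[1]]
    )
    assert got == {i: tuple(b_pos[best[i]]) for i in range(2)}


def test_gap_closes_track():
    tracker = Tracker(max_link_distance=20, max_gap=2)
    tracker.step(0, [blob(10, 10, 0)])
    tracker.step(1, [blob(12, 10, 1)])
    for f in range(2, 6):
        tracker.step(f, [])
    assert tracker.open_tracks == []
    assert len(tracker.closed_tracks) == 1


# ---------------------------------------------------------------------------
# detect_crossings
# ---------------------------------------------------------------------------


def track_with_zones(zones, track_id=0):
    return Track(
        track_id=track_id,
        observations=[(i, (0.0, 0.0), z) for i, z in enumerate(zones)],
    )


def test_zone_change_yields_one_upward_event():
    events = detect_crossings([track_with_zones([4, 4, 3, 3])], frame_rate=4.0)
    assert len(events) == 1
    e = events[0]
    assert (e.from_zone, e.to_zone, e.direction) == (4, 3, "up")
    assert e.time == 2 / 4.0  # later frame of the changing pair


def test_none_zone_breaks_pair_no_stairs_events():
    events = detect_crossings([track_with_zones([2, None, 3])], frame_rate=4.0)
    assert events == []


def test_non_adjacent_change_counts_once():
    events = detect_crossings([track_with_zones([4, 2])], frame_rate=4.0)
    assert len(events) == 1
    assert (events[0].from_zone, events[0].to_zone, events[0].direction) == (4, 2, "up")


def test_direction_invariant_enforced():
    with pytest.raises(ValueError):
        CrossingEvent(time=0, from_zone=1, to_zone=2, direction="up")
    with pytest.raises(ValueError):
        CrossingEvent(time=0, from_zone=1, to_zone=1, direction="up")


def test_synthetic_events_recovered_exactly(rendered_scenario):
    scenario, truth, render = rendered_scenario
    events, _tracks = count_movements(
        render.frames.frames, scenario.zonemap, MovementConfig()
    )
    ref = truth.crossing_events()
    assert len(events) == len(ref)
    got = sorted((round(e.time * 4), e.from_zone, e.to_zone) for e in events)
    want = sorted((round(e.time * 4), e.from_zone, e.to_zone) for e in ref)
    for (tf_g, f_g, t_g), (tf_w, f_w, t_w) in zip(got, want):
        assert (f_g, t_g) == (f_w, t_w)
        assert abs(tf_g - tf_w) <= 2  # within 0.5 s at 4 frames/s


# ---------------------------------------------------------------------------
# aggregate_per_minute
# ---------------------------------------------------------------------------


def ev(t, fz=2, tz=1):
    return CrossingEvent(time=t, from_zone=fz, to_zone=tz,
                         direction="up" if tz < fz else "down")


def test_minute_counts_simple():
    records = aggregate_per_minute([ev(10), ev(70), ev(130)], duration_s=180)
    assert [r.value for r in records] == [1, 1, 1]
    assert [r.clock_time for r in records] == [0, 60, 120]


def test_zero_fill_over_five_minutes():
    records = aggregate_per_minute([], duration_s=300)
    assert [r.value for r in records] == [0, 0, 0, 0, 0]


def test_minute_totals_conserve_schedule(rendered_scenario):
    scenario, truth, _render = rendered_scenario
    events = truth.crossing_events()
    records = aggregate_per_minute(events, duration_s=scenario.duration)
    assert sum(r.value for r in records) == len(truth.events)


def test_direction_split_conserves_totals(rendered_scenario):
    scenario, truth, _render = rendered_scenario
    events = truth.crossing_events()
    total = aggregate_per_minute(events, duration_s=scenario.duration)
    split = aggregate_per_minute(
        events, duration_s=scenario.duration, split_direction=True
    )
    by_minute = {}
    for r in split:
        by_minute[r.clock_time] = by_minute.get(r.clock_time, 0) + r.value
    for r in total:
        assert by_minute[r.clock_time] == r.value


def test_subsample_honors_target_rate():
    frames = np.zeros((24, 4, 4))
    assert subsample_frames(frames, 8.0, 4.0).shape[0] == 12
    with pytest.raises(ValueError):
        subsample_frames(frames, 2.0, 4.0)


def test_pipeline_output_idempotent(rendered_scenario, tmp_path):
    from flockwatch.geometry_io import write_counts

    scenario, _truth, render = rendered_scenario
    paths = []
    for run in (1, 2):
        events, _ = count_movements(
            render.frames.frames, scenario.zonemap, MovementConfig()
        )
        p = tmp_path / f"counts_{run}.csv"
        write_counts(
            aggregate_per_minute(events, duration_s=scenario.duration), p
        )
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
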