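import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flockwatch.activity_stats import (
    DEFAULT_SCHEDULES,
    bh_adjust,
    build_schedule,
    friedman_test,
    label_minutes,
    posthoc_pairs,
    qcd,
    weekly_descriptives,
    weekly_summary_matrix,
)
from flockwatch.geometry_io import clock_to_seconds


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def test_visual_day_predator_cue_1_span():
    schedule = build_schedule("visual")
    cue1 = next(c for c in schedule if c.name == "Predator cue 1")
    assert cue1.start_clock == clock_to_seconds("15:30")
    assert cue1.end_clock == clock_to_seconds("15:33")


def test_frustrative_day_frustration_1_span():
    schedule = build_schedule("frustrative")
    f1 = next(c for c in schedule if c.name == "Frustration 1")
    assert f1.start_clock == clock_to_seconds("10:00")
    assert f1.end_clock == clock_to_seconds("10:15")


def test_visual_day_durations_sum_to_120():
    assert sum(d for _n, d in DEFAULT_SCHEDULES["visual"][1]) == 120


def test_schedules_contiguous():
    for day_type in DEFAULT_SCHEDULES:
        schedule = build_schedule(day_type)
        for a, b in zip(schedule, schedule[1:]):
            assert b.start_clock == a.end_clock


def test_custom_schedule_validation():
    with pytest.raises(ValueError):
        build_schedule("visual", {"anchor": "14:30",
                                  "categories": [{"name": "A", "duration_min": 0}]})
    with pytest.raises(ValueError):
        build_schedule("visual", {"anchor": "14:30",
                                  "categories": [{"name": "A", "duration_min": 5},
                                                 {"name": "A", "duration_min": 5}]})


# ---------------------------------------------------------------------------
# label_minutes
# ---------------------------------------------------------------------------


def minutes_frame(day_type="visual", start="14:30", n_minutes=120, value=1.0):
    t0 = clock_to_seconds(start)
    return pd.DataFrame(
        {
            "group_id": "G1",
            "week": 1,
            "day_type": day_type,
            "clock_time": [t0 + 60 * m for m in range(n_minutes)],
            "interval_s": 60,
            "measure": "vertical_movement",
            "value": value,
        }
    )


def test_minute_15_31_is_predator_cue_1():
    schedule = build_schedule("visual")
    df = pd.DataFrame({"group_id": "G1", "week": 1,
                       "clock_time": [clock_to_seconds("15:31")], "value": 1.0})
    labeled = label_minutes(df, schedule)
    assert labeled.loc[0, "category"] == "Predator cue 1"


def test_boundary_minute_belongs_to_starting_category():
    schedule = build_schedule("visual")
    df = pd.DataFrame({"group_id": "G1", "week": 1,
                       "clock_time": [clock_to_seconds("15:33")], "value": 1.0})
    labeled = label_minutes(df, schedule)
    assert labeled.loc[0, "category"] == "Predator cue 2"


def test_labeled_counts_partition_durations():
    schedule = build_schedule("visual")
    labeled = label_minutes(minutes_frame(), schedule)
    counts = labeled["category"].value_counts()
    for cat in schedule:
        assert counts[cat.name] == cat.duration_min
    assert "unscheduled" not in counts


def test_out_of_window_minute_warns():
    schedule = build_schedule("visual")
    df = pd.DataFrame({"group_id": "G1", "week": 1,
                       "clock_time": [clock_to_seconds("08:00")], "value": 1.0})
    with pytest.warns(UserWarning, match="outside"):
        labeled = label_minutes(df, schedule)
    assert labeled.loc[0, "category"] == "unscheduled"


# ---------------------------------------------------------------------------
# descriptives / QCD
# ---------------------------------------------------------------------------


def test_qcd_reproduces_reported_cells():
    assert round(qcd(18.4, 24.7), 1) == 14.6
    assert round(qcd(6.5, 12.6), 1) == 31.9
    assert round(qcd(28.7, 36.1), 1) == 11.4
    assert round(qcd(29.9, 39.7), 1) == 14.1


def test_qcd_no_dispersion():
    assert qcd(5.0, 5.0) == 0.0


def test_qcd_undefined_flagged():
    with pytest.warns(UserWarning):
        assert np.isnan(qcd(0.0, 0.0))


def test_qcd_scale_invariance(rng):
    vals = rng.uniform(1, 10, 2)
    q1, q3 = sorted(vals)
    for scale in (0.5, 3.0, 100.0):
        assert np.isclose(qcd(q1, q3), qcd(scale * q1, scale * q3))


def labeled_weeks_frame(week_values, category="A"):
    """One category, one minute per week per group (two groups averaged)."""
    rows = []
    for week, value in enumerate(week_values, start=1):
        for group in ("G1", "G2"):
            rows.append({"group_id": group, "week": week,
                         "clock_time": 0, "value": value, "category": category})
    return pd.DataFrame(rows)


def test_weekly_descriptives_quantile_identities():
    values = [18.0, 20.0, 22.0, 25.0, 30.0]
    df = labeled_weeks_frame(values)
    desc = weekly_descriptives(df)
    row = desc.iloc[0]
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    assert np.isclose(row["median"], med)
    assert np.isclose(row["q1"], q1)
    assert np.isclose(row["q3"], q3)
    assert np.isclose(row["iqr"], row["q3"] - row["q1"])
    assert np.isclose(row["qcd_pct"], 100 * (q3 - q1) / (q3 + q1))
    assert row["weekly_min"] == 18.0
    assert row["weekly_max"] == 30.0


def test_weekly_descriptives_group_average_first():
    # groups disagree wildly but average to the same value per week: no spread
    rows = []
    for week in (1, 2, 3):
        rows += [
            {"group_id": "G1", "week": week, "clock_time": 0,
             "value": 10.0 + week * 0, "category": "A"},
            {"group_id": "G2", "week": week, "clock_time": 0,
             "value": 30.0, "category": "A"},
        ]
    desc = weekly_descriptives(pd.DataFrame(rows))
    assert np.isclose(desc.iloc[0]["iqr"], 0.0)
    assert desc.iloc[0]["qcd_pct"] == 0.0


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------


def test_perfect_concordance_closed_form():
    matrix = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [1.5, 2.5, 9.0]])
    result = friedman_test(matrix)
    assert np.isclose(result.chi2, 6.0)
    assert result.df == 2
    assert np.isclose(result.w, 1.0)


def test_all_equal_cells():
    matrix = np.full((4, 3), 7.0)
    result = friedman_test(matrix)
    assert result.chi2 == 0.0
    assert result.w == 0.0
    assert result.p == 1.0


def test_chi2_matches_scipy_without_ties(rng):
    for _ in range(10):
        matrix = rng.normal(size=(6, 4))
        ours = friedman_test(matrix)
        ref_chi2, ref_p = stats.friedmanchisquare(*matrix.T)
        assert np.isclose(ours.chi2, ref_chi2)
        assert np.isclose(ours.p, ref_p)


def _permutation_oracle(matrix):
    """Independent full-enumeration permutation null for the Friedman
    statistic (shares only scipy.rankdata with the implementation)."""
    n, k = matrix.shape

    def chi2_of(m):
        ranks = np.apply_along_axis(stats.rankdata, 1, m)
        rsum = ranks.sum(axis=0)
        return 12.0 / (n * k * (k + 1)) * np.sum(rsum**2) - 3 * n * (k + 1)

    observed = chi2_of(matrix)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        m = np.stack([matrix[b, list(combo[b])] for b in range(n)])
        total += 1
        if chi2_of(m) >= observed - 1e-12:
            count += 1
    return count / total


def test_exact_p_matches_enumeration_oracle(rng):
    matrix = rng.normal(size=(4, 3))
    result = friedman_test(matrix, p_method="exact")
    assert np.isclose(result.p, _permutation_oracle(matrix))


def test_monotone_transform_invariance(rng):
    matrix = rng.normal(size=(5, 4))
    a = friedman_test(matrix)
    b = friedman_test(np.exp(matrix))  # strictly increasing transform
    assert np.isclose(a.chi2, b.chi2)
    assert np.isclose(a.w, b.w)


def test_missing_cells_rejected():
    matrix = np.array([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError, match="missing"):
        friedman_test(matrix)


def test_w_in_unit_interval(rng):
    for _ in range(20):
        matrix = rng.normal(size=(rng.integers(2, 8), rng.integers(2, 6)))
        result = friedman_test(matrix)
        assert -1e-12 <= result.w <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# post hoc
# ---------------------------------------------------------------------------


def test_identical_columns_raw_p_one():
    matrix = np.tile(np.arange(5.0)[:, None], (1, 3))
    comparisons = posthoc_pairs(matrix)
    assert all(c.raw_p == 1.0 for c in comparisons)


def test_bh_step_up_formula():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.01, 0.04, 0.03]),
                       [0.03, 0.04, 0.04])


def test_bh_never_decreases_and_bounded(rng):
    p = rng.uniform(size=12)
    adj = bh_adjust(p)
    assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))
    assert all(a <= 1.0 for a in adj)


def test_mc_agrees_with_exact_on_5_blocks(rng):
    matrix = rng.normal(size=(5, 3))
    exact = posthoc_pairs(matrix, method="exact")
    n_mc = 20000
    mc = posthoc_pairs(matrix, method="mc", n_mc=n_mc, seed=4)
    for e, m in zip(exact, mc):
        se = np.sqrt(max(e.raw_p * (1 - e.raw_p), 1e-6) / n_mc)
        assert abs(e.raw_p - m.raw_p) <= 3 * se + 2.0 / n_mc


def test_posthoc_detects_separated_column():
    matrix = np.column_stack([
        np.arange(8.0), np.arange(8.0) + 0.1, np.arange(8.0) + 50.0,
    ])
    comparisons = posthoc_pairs(matrix)
    by_pair = {c.pair: c for c in comparisons}
    assert by_pair[("T1", "T3")].raw_p < 0.01
    assert by_pair[("T1", "T2")].adjusted_p >= by_pair[("T1", "T2")].raw_p


# ---------------------------------------------------------------------------
# matrix plumbing
# ---------------------------------------------------------------------------


def test_weekly_summary_matrix_shape():
    schedule = build_schedule("visual")
    frames = []
    rng = np.random.default_rng(0)
    for week in range(1, 6):
        df = minutes_frame()
        df["week"] = week
        df["value"] = rng.poisson(10, len(df)).astype(float)
        frames.append(df)
    labeled = label_minutes(pd.concat(frames, ignore_index=True), schedule)
    matrix = weekly_summary_matrix(labeled)
    assert matrix.shape == (5, 9)
    assert not matrix.isna().any().any()
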