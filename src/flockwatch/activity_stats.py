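"""Activity-category schedules, weekly-consistency descriptives and blocked
Friedman tests with exact all-pairs post hoc comparisons.

The observation day is partitioned into named activity categories (feeding
windows, resting periods, stress-cue windows).  Per activity, per-minute
counts are averaged across experimental groups, summarized per week, and the
between-week spread is described by quartiles and the quartile coefficient
of dispersion QCD = 100 * (Q3 - Q1) / (Q3 + Q1).  Differences between
activities are tested with a Friedman test blocked on week, with Kendall's W
as effect size, followed by exact pairwise sign-permutation comparisons
under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry_io import CountRecord, clock_to_seconds, records_to_frame

__all__ = [
    "ActivityCategory",
    "DEFAULT_SCHEDULES",
    "build_schedule",
    "label_minutes",
    "weekly_descriptives",
    "qcd",
    "FriedmanResult",
    "friedman_test",
    "PairComparison",
    "posthoc_pairs",
    "bh_adjust",
    "weekly_summary_matrix",
]


@dataclass(frozen=True)
class ActivityCategory:
    name: str
    day_type: str
    start_clock: int  # seconds since midnight
    duration_min: int

    @property
    def end_clock(self) -> int:
        return self.start_clock + 60 * self.duration_min

    def contains(self, clock_time: int) -> bool:
        # a boundary minute belongs to the category that starts at it
        return self.start_clock <= clock_time < self.end_clock


#: Default observation-day schedules: (anchor clock, ordered categories with
#: durations in minutes).  Categories are sequential and contiguous.
DEFAULT_SCHEDULES: dict[str, tuple[str, list[tuple[str, int]]]] = {
    "visual": (
        "14:30",
        [
            ("Feeding 1", 5),
            ("Resting 1", 25),
            ("Feeding sound", 5),
            ("Resting 2", 25),
            ("Predator cue 1", 3),
            ("Predator cue 2", 3),
            ("Resting 3", 25),
            ("Resting 4", 24),
            ("Feeding 2", 5),
        ],
    ),
    "auditory": (
        "14:30",
        [
            ("Feeding 1", 5),
            ("Resting 1", 25),
            ("Feeding sound", 5),
            ("Resting 2", 25),
            ("Thunder sound", 1),
            ("Resting 3", 27),
            ("Resting 4", 26),
            ("Feeding 2", 5),
        ],
    ),
    "frustrative": (
        "09:00",
        [
            ("Resting 1", 30),
            ("Resting 2", 30),
            ("Frustration 1", 15),
            ("Frustration 2", 15),
            ("Frustration 3", 15),
            ("Frustration 4", 15),
            ("Feeding 1", 5),
            ("Resting 3", 30),
            ("Resting 4", 30),
        ],
    ),
}


def build_schedule(
    day_type: str,
    config: Optional[dict] = None,
) -> list[ActivityCategory]:
    """Sequential, contiguous activity categories for one day type.

    ``config`` may override the defaults with
    ``{"anchor": "HH:MM", "categories": [{"name": ..., "duration_min": ...}]}``.
    """
    if config is not None:
        anchor = config["anchor"]
        entries = [(c["name"], int(c["duration_min"])) for c in config["categories"]]
    else:
        if day_type not in DEFAULT_SCHEDULES:
            raise ValueError(f"no default schedule for day_type {day_type!r}")
        anchor, entries = DEFAULT_SCHEDULES[day_type]
    names = [n for n, _ in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate category names in schedule")
    clock = clock_to_seconds(anchor)
    schedule: list[ActivityCategory] = []
    for name, duration in entries:
        if duration <= 0:
            raise ValueError(f"category {name!r} has nonpositive duration")
        schedule.append(
            ActivityCategory(
                name=name,
                day_type=day_type,
                start_clock=clock,
                duration_min=duration,
            )
        )
        clock += 60 * duration
    return schedule


def label_minutes(
    records: Iterable[CountRecord] | pd.DataFrame,
    schedule: Sequence[ActivityCategory],
) -> pd.DataFrame:
    """Tag each per-minute record with its containing activity category.

    Records outside the schedule window are tagged ``"unscheduled"`` and a
    warning is emitted.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if df["clock_time"].dtype == object:
            df["clock_time"] = df["clock_time"].map(clock_to_seconds)
    else:
        df = records_to_frame(records)
        df["clock_time"] = df["clock_time"].map(clock_to_seconds)

    def _label(clock: int) -> str:
        for cat in schedule:
            if cat.contains(clock):
                return cat.name
        return "unscheduled"

    df["category"] = df["clock_time"].map(_label)
    n_out = int((df["category"] == "unscheduled").sum())
    if n_out:
        warnings.warn(f"{n_out} records outside the schedule window")
    return df


def qcd(q1: float, q3: float) -> float:
    """Quartile coefficient of dispersion in percent: 100*(Q3-Q1)/(Q3+Q1)."""
    if q1 + q3 == 0:
        warnings.warn("QCD undefined: Q1 + Q3 = 0")
        return float("nan")
    return 100.0 * (q3 - q1) / (q3 + q1)


def _per_week_summaries(
    labeled: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group_id",
    inner_stat: str = "mean",
) -> pd.DataFrame:
    """Average across groups per minute, then summarize per week and
    category; returns a tidy frame with columns category, week, summary."""
    df = labeled[labeled["category"] != "unscheduled"]
    per_minute = (
        df.groupby(["category", "week", "clock_time"])[value_col]
        .mean()
        .reset_index()
    )
    agg = "mean" if inner_stat == "mean" else "median"
    summaries = (
        per_minute.groupby(["category", "week"])[value_col]
        .agg(agg)
        .reset_index()
        .rename(columns={value_col: "summary"})
    )
    return summaries


def weekly_descriptives(
    labeled: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group_id",
    inner_stat: str = "mean",
    category_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Between-week descriptives per activity category.

    Per activity: per-minute values are averaged across groups, summarized
    per week (mean by default), and the per-week summaries are described by
    median, Q1, Q3 (linear-interpolation quantiles), IQR, QCD and the weekly
    minimum/maximum.
    """
    summaries = _per_week_summaries(labeled, value_col, group_col, inner_stat)
    rows = []
    for category, sub in summaries.groupby("category", sort=False):
        vals = sub["summary"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interp
        rows.append(
            {
                "activity": category,
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
                "qcd_pct": qcd(q1, q3),
                "weekly_min": vals.min(),
                "weekly_max": vals.max(),
                "n_weeks": len(vals),
            }
        )
    df = pd.DataFrame(rows)
    if category_order is not None:
        df["activity"] = pd.Categorical(
            df["activity"], categories=list(category_order), ordered=True
        )
        df = df.sort_values("activity").reset_index(drop=True)
    return df


def weekly_summary_matrix(
    labeled: pd.DataFrame,
    value_col: str = "value",
    inner_stat: str = "mean",
) -> pd.DataFrame:
    """Weeks-by-activities matrix of per-week summaries (Friedman input)."""
    summaries = _per_week_summaries(labeled, value_col, inner_stat=inner_stat)
    matrix = summaries.pivot(index="week", columns="category", values="summary")
    if matrix.isna().any().any():
        raise ValueError("missing week/category cells; cannot build matrix")
    return matrix


# ---------------------------------------------------------------------------
# Friedman test with Kendall's W
# ---------------------------------------------------------------------------


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    w: float
    n_blocks: int
    n_treatments: int
    posthoc: Optional[list["PairComparison"]] = None


def _friedman_chi2(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from an (n blocks, k treatments)
    matrix using within-block mid-ranks."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * float(np.sum(col_sums**2) - n**2 * k * (k + 1) ** 2 / 4.0)
    denom = float(np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0)
    if denom <= 0:  # every block completely tied
        return 0.0
    return numer / denom


def friedman_test(
    matrix: pd.DataFrame | np.ndarray,
    p_method: str = "chisq",
    max_enumeration: int = 2_000_000,
) -> FriedmanResult:
    """Friedman test on a blocks-by-treatments matrix (no missing cells).

    ``p_method="chisq"`` uses the chi-squared reference distribution;
    ``"exact"`` enumerates all within-block orderings (guarded by
    ``max_enumeration``).  Kendall's W is chi2 / (n * (k - 1)).
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x treatments)")
    if np.isnan(values).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    chi2 = _friedman_chi2(values)
    w = chi2 / (n * (k - 1))
    if p_method == "chisq":
        p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    elif p_method == "exact":
        total = math.factorial(k) ** n
        if total > max_enumeration:
            raise ValueError(
                f"exact enumeration of {total} orderings exceeds the guard"
            )
        count = 0
        perms = list(itertools.permutations(range(k)))
        for combo in itertools.product(perms, repeat=n):
            permuted = np.stack(
                [values[b, list(combo[b])] for b in range(n)]
            )
            if _friedman_chi2(permuted) >= chi2 - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return FriedmanResult(
        chi2=chi2, df=k - 1, p=p, w=w, n_blocks=n, n_treatments=k
    )


# ---------------------------------------------------------------------------
# Exact all-pairs post hoc with FDR control
# ---------------------------------------------------------------------------


@dataclass
class PairComparison:
    pair: tuple[str, str]
    statistic: float
    raw_p: float
    adjusted_p: float = float("nan")
    method: str = "exact"


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        candidate = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted.tolist()


def _pair_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact sign-permutation p for one treatment pair.

    ``diffs`` are within-block rank differences (+1 / -1 / 0 for ties).
    The statistic is |sum of differences|; the null enumerates every
    within-block ordering of the two values (sign flips of the non-tied
    blocks)."""
    nonzero = diffs[diffs != 0]
    m = len(nonzero)
    t_obs = abs(float(diffs.sum()))
    if m == 0:
        return 0.0, 1.0
    count = 0
    for signs in itertools.product((-1.0, 1.0), repeat=m):
        t = abs(float(np.dot(signs, np.abs(nonzero))))
        if t >= t_obs - 1e-12:
            count += 1
    return t_obs, count / 2**m


def _pair_mc_p(
    diffs: np.ndarray, n_mc: int, rng: np.random.Generator
) -> tuple[float, float]:
    nonzero = np.abs(diffs[diffs != 0])
    m = len(nonzero)
    t_obs = abs(float(diffs.sum()))
    if m == 0:
        return 0.0, 1.0
    signs = rng.choice((-1.0, 1.0), size=(n_mc, m))
    ts = np.abs(signs @ nonzero)
    # add-one correction keeps the Monte-Carlo p valid
    p = (1 + int(np.sum(ts >= t_obs - 1e-12))) / (n_mc + 1)
    return t_obs, p


def posthoc_pairs(
    matrix: pd.DataFrame | np.ndarray,
    labels: Optional[Sequence[str]] = None,
    method: str = "auto",
    max_exact_blocks: int = 10,
    n_mc: int = 20000,
    seed: int = 0,
) -> list[PairComparison]:
    """All-pairs comparisons of treatments blocked on week.

    For each treatment pair, the two columns are ranked within block; the
    statistic is the absolute sum of rank differences.  The null is exact by
    full enumeration of within-block orderings when the block count is at
    most ``max_exact_blocks``, otherwise a seeded Monte-Carlo permutation.
    Benjamini-Hochberg adjustment is applied across pairs.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        if labels is None:
            labels = [str(c) for c in matrix.columns]
    else:
        values = np.asarray(matrix, dtype=float)
    n, k = values.shape
    if labels is None:
        labels = [f"T{i+1}" for i in range(k)]
    use_exact = method == "exact" or (method == "auto" and n <= max_exact_blocks)
    if method == "mc":
        use_exact = False
    rng = np.random.default_rng(seed)
    comparisons: list[PairComparison] = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = values[:, i], values[:, j]
        diffs = np.sign(a - b)
        if use_exact:
            t_obs, p = _pair_exact_p(diffs)
            how = "exact"
        else:
            t_obs, p = _pair_mc_p(diffs, n_mc, rng)
            how = "mc"
        comparisons.append(
            PairComparison(
                pair=(labels[i], labels[j]),
                statistic=t_obs,
                raw_p=p,
                method=how,
            )
        )
    adjusted = bh_adjust([c.raw_p for c in comparisons])
    for c, ap in zip(comparisons, adjusted):
        c.adjusted_p = ap
        if ap < c.raw_p - 1e-12:
            raise AssertionError("BH adjustment must not decrease p")
    return comparisons
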