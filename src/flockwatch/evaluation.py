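"""Confusion-matrix evaluation of the movement and litter counters.

True positives are correctly detected crossing events (matched one-to-one
against reference events within a time tolerance, with agreeing direction)
or correctly counted hens per zone; false positives are surplus detections,
false negatives missed ones.  Precision, recall and the F1 score (harmonic
mean of the two) summarize the tallies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .vertical_movement import CrossingEvent

__all__ = [
    "ConfusionCounts",
    "match_events",
    "count_confusion",
    "precision_recall_f1",
    "f1_from_precision_recall",
    "evaluation_report",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def match_events(
    predicted: Sequence[CrossingEvent],
    reference: Sequence[CrossingEvent],
    tolerance: float = 0.5,
) -> ConfusionCounts:
    """Greedy one-to-one chronological matching of predicted to reference.

    A predicted event matches the earliest unmatched reference event with
    ``|dt| <= tolerance`` and the same direction.  Matched pairs are TP,
    unmatched predicted FP, unmatched reference FN.  For this interval
    structure the greedy rule attains the maximum bipartite matching.
    """
    predicted = sorted(predicted, key=lambda e: e.time)
    reference = sorted(reference, key=lambda e: e.time)
    matched = [False] * len(reference)
    tp = 0
    for p in predicted:
        for i, r in enumerate(reference):
            if r.time < p.time - tolerance or matched[i]:
                continue
            if r.time > p.time + tolerance:
                break
            if r.direction == p.direction:
                matched[i] = True
                tp += 1
                break
    fp = len(predicted) - tp
    fn = len(reference) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def count_confusion(predicted_count: int, reference_count: int) -> ConfusionCounts:
    """Per-observation count comparison: surplus detections are FP, missing
    ones FN, the overlap TP.  Accumulate over observations by summation."""
    if predicted_count < 0 or reference_count < 0:
        raise ValueError("counts must be >= 0")
    return ConfusionCounts(
        tp=min(predicted_count, reference_count),
        fp=max(predicted_count - reference_count, 0),
        fn=max(reference_count - predicted_count, 0),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return (2.0 * precision * recall) / (precision + recall)


def precision_recall_f1(c: ConfusionCounts) -> dict[str, float]:
    """Precision, recall and F1 from confusion tallies.

    Undefined metrics (zero denominators) are reported as NaN with a
    warning rather than raising.
    """
    precision = recall = float("nan")
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        warnings.warn("precision undefined: no predicted positives")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("recall undefined: no reference positives")
    if math.isnan(precision) or math.isnan(recall):
        f1 = float("nan")
    else:
        f1 = f1_from_precision_recall(precision, recall)
    return {"precision": precision, "recall": recall, "f1": f1}


def evaluation_report(
    entries: Iterable[tuple[str, str, ConfusionCounts]],
    csv_path: Optional[str | Path] = None,
    json_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Tabulate (video_id, measure, confusion) entries with derived metrics.

    Metrics are written at full precision to CSV; the JSON summary rounds
    F1 to 2 decimals as in reporting convention.
    """
    rows = []
    for video_id, measure, c in entries:
        metrics = precision_recall_f1(c)
        rows.append(
            {
                "video_id": video_id,
                "measure": measure,
                "TP": c.tp,
                "FP": c.fp,
                "FN": c.fn,
                **metrics,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["video_id", "measure", "TP", "FP", "FN",
                 "precision", "recall", "f1"],
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = [
            {
                "video_id": r["video_id"],
                "measure": r["measure"],
                "precision": None if math.isnan(r["precision"]) else round(r["precision"], 2),
                "recall": None if math.isnan(r["recall"]) else round(r["recall"], 2),
                "f1": None if math.isnan(r["f1"]) else round(r["f1"], 2),
            }
            for r in rows
        ]
        Path(json_path).write_text(json.dumps(summary, indent=2))
    return df
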