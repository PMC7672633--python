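"""Event-based scoring of detections against annotations.

Soft (onset-only) sound-event detection is scored with an onset collar: a
detection is correct if its onset falls within +/- collar seconds of an
unmatched reference onset. Matching is one-to-one; the default policy is
greedy nearest-first in time order, with optimal bipartite assignment
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MatchResult", "match_events"]


@dataclass(frozen=True)
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 1.0

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
        }


def match_events(
    detections: Sequence[float],
    annotations: Sequence[float],
    collar_s: float = 6.0,
    collar_before_s: float | None = None,
    collar_after_s: float | None = None,
    policy: str = "greedy",
) -> MatchResult:
    """Match detection onsets to annotation onsets under a time collar.

    A detection at t matches an annotation at r when
    r - collar_before <= t <= r + collar_after (both default to
    ``collar_s``, i.e. a symmetric +/- 6 s collar). ``policy="greedy"``
    walks detections in time order and takes the nearest unmatched
    annotation; ``policy="optimal"`` maximizes the number of matches by
    bipartite assignment.
    """
    if collar_s <= 0:
        raise ValueError("collar_s must be positive")
    before = collar_s if collar_before_s is None else collar_before_s
    after = collar_s if collar_after_s is None else collar_after_s
    det = sorted(float(t) for t in detections)
    ann = sorted(float(t) for t in annotations)

    def fits(t: float, r: float) -> bool:
        return r - before <= t <= r + after

    if policy == "greedy":
        matched = [False] * len(ann)
        tp = 0
        for t in det:
            best, best_dist = -1, float("inf")
            for j, r in enumerate(ann):
                if matched[j] or not fits(t, r):
                    continue
                dist = abs(t - r)
                if dist < best_dist:
                    best, best_dist = j, dist
            if best >= 0:
                matched[best] = True
                tp += 1
    elif policy == "optimal":
        from scipy.optimize import linear_sum_assignment

        if det and ann:
            cost = np.ones((len(det), len(ann)))
            for i, t in enumerate(det):
                for j, r in enumerate(ann):
                    if fits(t, r):
                        cost[i, j] = 0.0
            rows, cols = linear_sum_assignment(cost)
            tp = int(np.sum(cost[rows, cols] == 0.0))
        else:
            tp = 0
    else:
        raise ValueError(f"unknown matching policy {policy!r}")
    return MatchResult(
        true_positives=tp,
        false_positives=len(det) - tp,
        false_negatives=len(ann) - tp,
    )
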