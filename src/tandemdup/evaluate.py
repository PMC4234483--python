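"""Benchmark metrics: precision, recall, F1 and mean breakpoint mismatch.

A call is a true positive when it has at least 50% *mutual* overlap with a
spiked-in duplication: the overlap must cover at least half of the truth
interval AND at least half of the call interval.  Matching is one-to-one and
greedy by decreasing overlap fraction, so a single call cannot absorb
several truths.  Breakpoint mismatch is |Δstart| + |Δend| summed per matched
pair and averaged over true positives only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

Interval = Tuple[int, int]  # (start, end), 1-based inclusive


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    mean_breakpoint_mismatch: float  # nan when there are no true positives
    matched_pairs: List[Tuple[Interval, Interval]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_breakpoint_mismatch": self.mean_breakpoint_mismatch,
        }

    def __str__(self) -> str:
        return "\n".join(f"{k}={v}" for k, v in self.as_dict().items())


def _overlap(a: Interval, b: Interval) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def _length(a: Interval) -> int:
    return a[1] - a[0] + 1


def mutual_overlap_fraction(truth: Interval, call: Interval) -> float:
    """min(overlap/len(truth), overlap/len(call)); <= 0 when disjoint."""
    ov = _overlap(truth, call)
    if ov <= 0:
        return 0.0
    return min(ov / _length(truth), ov / _length(call))


def match_and_score(
    truth: Sequence[Interval],
    calls: Sequence[Interval],
    min_mutual_overlap: float = 0.5,
) -> EvaluationReport:
    """Match calls to truth one-to-one and compute the four metrics.

    Candidate matches (mutual overlap >= ``min_mutual_overlap``) are taken
    greedily by decreasing mutual-overlap fraction (overlap length, then
    coordinates, break remaining ties).  Unmatched calls are false
    positives; unmatched truths false negatives.
    """
    truth = [tuple(t) for t in truth]
    calls = [tuple(c) for c in calls]
    candidates = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            frac = mutual_overlap_fraction(t, c)
            if frac >= min_mutual_overlap:
                candidates.append((frac, _overlap(t, c), -t[0], -c[0], ti, ci))
    candidates.sort(reverse=True)
    truth_used = [False] * len(truth)
    call_used = [False] * len(calls)
    matched: List[Tuple[Interval, Interval]] = []
    mismatch_total = 0
    for frac, ov, _, _, ti, ci in candidates:
        if truth_used[ti] or call_used[ci]:
            continue
        truth_used[ti] = True
        call_used[ci] = True
        t, c = truth[ti], calls[ci]
        matched.append((t, c))
        mismatch_total += abs(t[0] - c[0]) + abs(t[1] - c[1])
    tp = len(matched)
    return EvaluationReport(
        tp=tp,
        fp=len(calls) - tp,
        fn=len(truth) - tp,
        mean_breakpoint_mismatch=(mismatch_total / tp) if tp else float("nan"),
        matched_pairs=matched,
    )
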