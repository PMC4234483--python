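"""Greedy conflict resolution among overlapping calls.

True tandem duplications are assumed non-overlapping, so overlaps among
calls mark likely false positives from noisy evidence.  Following the
maximum-parsimony heuristic, the call overlapping the most other calls is
removed, overlap counts are recomputed, and the loop repeats until the kept
set is conflict-free.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from .breakpoints import TandemDuplicationCall


def _overlap_len(a: TandemDuplicationCall, b: TandemDuplicationCall) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def _conflicting(a: TandemDuplicationCall, b: TandemDuplicationCall,
                 min_overlap_fraction: float) -> bool:
    ov = _overlap_len(a, b)
    if ov < 1:
        return False
    if min_overlap_fraction <= 0.0:
        return True
    return ov >= min_overlap_fraction * min(a.length, b.length)


def resolve_conflicts(
    calls: Sequence[TandemDuplicationCall],
    min_overlap_fraction: float = 0.0,
) -> Tuple[List[TandemDuplicationCall], List[TandemDuplicationCall]]:
    """Remove calls until no two kept calls overlap; returns (kept, removed).

    All calls must be on one contig.  Each iteration removes the call with
    the highest current conflict count; ties prefer removing the call with
    fewer supporting pairs, then lower log score, then the leftmost start —
    fully deterministic.  With
    ``min_overlap_fraction`` > 0, only overlaps of at least that fraction of
    the shorter call count as conflicts.
    """
    contigs = {c.contig for c in calls}
    if len(contigs) > 1:
        raise ValueError(f"calls span multiple contigs: {sorted(contigs)}")
    kept = list(calls)
    removed: List[TandemDuplicationCall] = []
    while True:
        n = len(kept)
        counts = [0] * n
        for i in range(n):
            for j in range(i + 1, n):
                if _conflicting(kept[i], kept[j], min_overlap_fraction):
                    counts[i] += 1
                    counts[j] += 1
        worst = max(counts, default=0)
        if worst == 0:
            return kept, removed
        victim = max(
            (i for i in range(n) if counts[i] == worst),
            key=lambda i: (-kept[i].support, -kept[i].log_score, -kept[i].start),
        )
        removed.append(kept.pop(victim))
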