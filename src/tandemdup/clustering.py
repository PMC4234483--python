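"""Grouping everted-pair trapezoids into putative duplications.

Two everted pairs induced by the same tandem duplication have intersecting
feasible-breakpoint trapezoids.  Noise makes the all-pairs common
intersection unreliable, so the grouping criterion is relaxed to connectivity
of the pairwise-intersection graph: a cluster is a connected component in
which every member intersects at least one other member.  Components are
found breadth-first, seeded in deterministic coordinate order; a spatial
index prunes the candidate neighbours before the exact intersection
predicate confirms them.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from intervaltree import IntervalTree

from .geometry import Trapezoid, intersects


@dataclass
class DuplicationCluster:
    """A connected set of trapezoids on one contig."""

    cluster_id: int
    members: List[Trapezoid]
    contig: str
    bounding_box: Tuple[int, int, int, int]  # (x_lo, x_hi, y_lo, y_hi)

    @property
    def support(self) -> int:
        return len(self.members)


class TrapezoidIndex:
    """Spatial index over trapezoid bounding boxes.

    An interval tree on the x-extent of each bounding box; d-extent
    ``[diag_lo, diag_hi]`` is filtered on query.  Returns a superset of the
    truly intersecting trapezoids (bounding-box overlaps); callers confirm
    with the exact predicate.  The index is a performance device only — any
    structure returning a superset of box overlaps yields identical clusters.
    """

    def __init__(self, trapezoids: Sequence[Trapezoid]):
        self.trapezoids = list(trapezoids)
        self._tree = IntervalTree()
        for i, t in enumerate(self.trapezoids):
            # IntervalTree is half-open; widen by 1 for closed bp intervals
            self._tree.addi(t.x_min, t.x_max + 1, i)

    def query(self, t: Trapezoid) -> List[int]:
        """Indices whose bounding boxes overlap t's (includes t itself)."""
        hits = []
        for iv in self._tree.overlap(t.x_min, t.x_max + 1):
            other = self.trapezoids[iv.data]
            if other.diag_lo <= t.diag_hi and other.diag_hi >= t.diag_lo:
                hits.append(iv.data)
        return hits

    def neighbours(self, i: int) -> List[int]:
        """Indices of trapezoids that exactly intersect trapezoid ``i``."""
        t = self.trapezoids[i]
        return [
            j
            for j in self.query(t)
            if j != i and intersects(t, self.trapezoids[j])
        ]


def build_spatial_index(trapezoids: Sequence[Trapezoid]) -> TrapezoidIndex:
    return TrapezoidIndex(trapezoids)


def _cluster_bbox(members: Sequence[Trapezoid]) -> Tuple[int, int, int, int]:
    return (
        min(t.x_min for t in members),
        max(t.x_max for t in members),
        min(t.y_min for t in members),
        max(t.y_max for t in members),
    )


def connected_components(
    trapezoids: Sequence[Trapezoid],
    min_support: int = 2,
) -> Tuple[List[DuplicationCluster], int]:
    """Connected components of the trapezoid-intersection graph.

    All trapezoids must lie on one contig (callers iterate contigs).
    Components with fewer than ``min_support`` members are dropped; the count
    of dropped trapezoids is returned alongside the clusters.  Seeds are
    taken in (x_min, y_min) order and clusters are renumbered by leftmost
    bounding-box coordinate then size, so output is independent of input
    order.
    """
    trapezoids = list(trapezoids)
    contigs = {t.contig for t in trapezoids}
    if len(contigs) > 1:
        raise ValueError(f"trapezoids span multiple contigs: {sorted(contigs)}")
    if not trapezoids:
        return [], 0

    index = build_spatial_index(trapezoids)
    order = sorted(
        range(len(trapezoids)),
        key=lambda i: (trapezoids[i].x_min, trapezoids[i].y_min, trapezoids[i].pair_id),
    )
    assigned = [False] * len(trapezoids)
    raw_components: List[List[Trapezoid]] = []
    for seed in order:
        if assigned[seed]:
            continue
        assigned[seed] = True
        component = [seed]
        frontier = deque([seed])
        while frontier:
            i = frontier.popleft()
            for j in index.neighbours(i):
                if not assigned[j]:
                    assigned[j] = True
                    component.append(j)
                    frontier.append(j)
        raw_components.append([trapezoids[i] for i in component])

    kept = [c for c in raw_components if len(c) >= min_support]
    dropped = sum(len(c) for c in raw_components if len(c) < min_support)
    kept.sort(key=lambda c: (_cluster_bbox(c)[0], len(c)))
    clusters = [
        DuplicationCluster(
            cluster_id=k,
            members=sorted(c, key=lambda t: (t.x_min, t.y_min, t.pair_id)),
            contig=c[0].contig,
            bounding_box=_cluster_bbox(c),
        )
        for k, c in enumerate(kept)
    ]
    return clusters, dropped
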