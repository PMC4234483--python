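"""Breakpoint trapezoid geometry for everted read pairs.

An everted (RF) pair with reverse-strand leftmost coordinate ``s``, forward-
strand leftmost coordinate ``e`` and read length ``r`` is explained by a
tandem duplication with breakpoint-pair ``(x, y)`` (start and end of the
duplicated segment, both inclusive) exactly when four linear inequalities
hold:

    (i)   y >= x + e - s - r - 1 + l_min
    (ii)  y <= x + e - s - r - 1 + l_max
    (iii) x <= s
    (iv)  y >= e + r - 1

(i)-(ii) say the fragment length implied by (x, y),

    l(x, y) = y - e + s - x + r + 1,

must fall inside the fragment-length support ``[l_min, l_max]``; (iii)-(iv)
say the two reads flank the fusion point without containing it.  The feasible
set is a closed trapezoid in the (x, y) plane.  In the sheared coordinates
(x, d = y - x) it is bounded by ``x <= x_max``, ``d_lo <= d <= d_hi`` and the
half-plane ``x + d >= y_min``, which makes membership, emptiness and pairwise
intersection exact integer arithmetic — no floating point, no polygon
clipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

__all__ = [
    "Trapezoid",
    "build_trapezoid",
    "contains",
    "implied_fragment_length",
    "intersects",
    "EmptyTrapezoidError",
]


class EmptyTrapezoidError(ValueError):
    """The RF pair admits no breakpoint-pair (l_max < 2r): both reads cannot
    flank the fusion point when even the longest fragment is shorter than two
    reads."""


@dataclass(frozen=True, slots=True)
class Trapezoid:
    """Feasible breakpoint-pair region of one everted pair (closed region)."""

    pair_id: str
    contig: str
    s: int
    e: int
    r: int
    l_min: int
    l_max: int

    @property
    def x_max(self) -> int:
        return self.s

    @property
    def y_min(self) -> int:
        return self.e + self.r - 1

    @property
    def diag_lo(self) -> int:
        return self.e - self.s - self.r - 1 + self.l_min

    @property
    def diag_hi(self) -> int:
        return self.e - self.s - self.r - 1 + self.l_max

    @property
    def x_min(self) -> int:
        """Smallest feasible x: attained at y = y_min, d = diag_hi."""
        return self.y_min - self.diag_hi

    @property
    def y_max(self) -> int:
        """Largest feasible y: attained at x = x_max, d = diag_hi."""
        return self.x_max + self.diag_hi

    def is_empty(self) -> bool:
        return self.diag_lo > self.diag_hi or self.x_max + self.diag_hi < self.y_min

    def vertices(self) -> List[Tuple[int, int]]:
        """Corner points of the (possibly truncated) trapezoid, for plotting."""
        if self.is_empty():
            return []
        X, Y, lo, hi = self.x_max, self.y_min, self.diag_lo, self.diag_hi
        corners: List[Tuple[int, int]] = [(Y - hi, Y)]
        if Y - lo <= X:  # lower diagonal reaches the y = Y edge
            if Y - lo != Y - hi:
                corners.append((Y - lo, Y))
            if X > Y - lo:
                corners.append((X, X + lo))
        else:            # region truncated by x <= X before the lower diagonal
            corners.append((X, Y))
        if X + hi > Y:
            corners.append((X, X + hi))
        return corners

    def bounding_box(self) -> Tuple[int, int, int, int]:
        """(x_lo, x_hi, y_lo, y_hi) of the minimum axis-aligned rectangle."""
        return (self.x_min, self.x_max, self.y_min, self.y_max)


def build_trapezoid(pair, model) -> Trapezoid:
    """Construct the feasible-breakpoint trapezoid of an RF pair.

    Raises :class:`EmptyTrapezoidError` when the region is empty
    (``l_max < 2r``); callers flag such pairs unusable rather than abort.
    """
    if pair.orientation != "RF":
        raise ValueError(f"pair {pair.pair_id} is {pair.orientation}, not RF")
    if model.l_min > model.l_max:
        raise ValueError(f"malformed model: l_min={model.l_min} > l_max={model.l_max}")
    t = Trapezoid(
        pair_id=pair.pair_id,
        contig=pair.contig,
        s=pair.s,
        e=pair.e,
        r=pair.r,
        l_min=model.l_min,
        l_max=model.l_max,
    )
    if t.is_empty():
        raise EmptyTrapezoidError(
            f"pair {pair.pair_id}: l_max={model.l_max} < 2r={2 * pair.r}; "
            "no breakpoint-pair can induce this everted pair"
        )
    return t


def implied_fragment_length(t: Trapezoid, x: int, y: int) -> int:
    """Fragment length the pair would have if (x, y) were the breakpoints."""
    return y - t.e + t.s - x + t.r + 1


def contains(t: Trapezoid, x: int, y: int) -> bool:
    """Closed-region membership: all four inequalities, boundaries included."""
    if x > t.x_max or y < t.y_min:
        return False
    d = y - x
    return t.diag_lo <= d <= t.diag_hi


def intersects(a: Trapezoid, b: Trapezoid) -> bool:
    """True iff the two closed regions share at least one point.

    Both regions are intersections of the same four half-plane families, so
    their intersection is a region of the same shape; it is nonempty iff the
    combined diagonal band is nonempty and the corner (min x_max, min diag_hi)
    clears the combined y floor.  Because every bound is an integer, a
    nonempty continuous intersection always contains a lattice point.
    """
    if a.contig != b.contig:
        return False
    d_lo = max(a.diag_lo, b.diag_lo)
    d_hi = min(a.diag_hi, b.diag_hi)
    if d_lo > d_hi:
        return False
    x_max = min(a.x_max, b.x_max)
    y_min = max(a.y_min, b.y_min)
    return x_max + d_hi >= y_min
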