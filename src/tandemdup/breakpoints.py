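"""Candidate breakpoint enumeration and fragment-length scoring.

For a cluster S_k the candidate set Omega_k is the set of integer
breakpoint-pairs (x, y) covered by the maximum number of member trapezoids
(the all-member intersection when it is nonempty).  Each candidate is scored
by the product, over the trapezoids containing it, of the empirical
probability of the fragment length that candidate implies for that pair:

    P[(x, y) | S_k]  ∝  prod_{i in Z_(x,y)} P_L[ L = y - e_i + s_i - x + r + 1 ]

The call is the argmax, ties broken uniformly at random with a seeded RNG;
probabilities over Omega_k are normalized stably in log space.

Enumeration works on the sheared (x, d = y - x) grid where each trapezoid is
a d-band clipped by ``x <= x_max`` and ``x >= y_min - d``: per-(d-row)
x-intervals accumulate into a 2-D difference array, so coverage counting and
weight summation are O(grid area), and the implied fragment length depends
only on the row (l = d - diag_lo + l_min), never on x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .clustering import DuplicationCluster
from .fraglen import FragmentLengthModel

__all__ = [
    "TandemDuplicationCall",
    "candidate_region",
    "score_candidates",
    "call_cluster",
    "CellBudgetError",
]

DEFAULT_CELL_BUDGET = 10**7


class CellBudgetError(RuntimeError):
    """Candidate lattice larger than the configured cell budget; raise the
    fragment-length trimming (smaller l_max - l_min shrinks every trapezoid)
    or accept the cluster bounding box without fine scoring."""


@dataclass(frozen=True)
class TandemDuplicationCall:
    """A scored tandem-duplication call: [start, end] inclusive."""

    contig: str
    start: int
    end: int
    support: int            # RF pairs in the cluster
    max_coverage: int       # trapezoids containing the called point
    log_score: float        # unnormalized log probability of the called point
    normalized_probability: float
    cluster_id: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class _Raster:
    """Coverage counts (and optional log-pmf weights) on the cluster grid."""

    def __init__(self, cluster: DuplicationCluster,
                 model: FragmentLengthModel = None,
                 cell_budget: int = DEFAULT_CELL_BUDGET):
        members = cluster.members
        if not members:
            raise ValueError(f"cluster {cluster.cluster_id} is empty")
        self.x_lo = min(t.x_min for t in members)
        self.x_hi = max(t.x_max for t in members)
        self.d_lo = min(t.diag_lo for t in members)
        self.d_hi = max(t.diag_hi for t in members)
        n_rows = self.d_hi - self.d_lo + 1
        n_cols = self.x_hi - self.x_lo + 1
        if n_rows * n_cols > cell_budget:
            raise CellBudgetError(
                f"cluster {cluster.cluster_id}: candidate grid {n_rows}x{n_cols} "
                f"exceeds the cell budget of {cell_budget}; increase fragment-length "
                "trimming or report the bounding box without fine scoring"
            )
        count_diff = np.zeros((n_rows, n_cols + 1), dtype=np.int32)
        weight_diff = np.zeros((n_rows, n_cols + 1), dtype=float) if model else None
        for t in members:
            d_start = max(t.diag_lo, t.y_min - t.x_max)
            if d_start > t.diag_hi:
                continue
            rows = np.arange(d_start - self.d_lo, t.diag_hi - self.d_lo + 1)
            d_vals = rows + self.d_lo
            col_lo = np.maximum(t.y_min - d_vals, self.x_lo) - self.x_lo
            col_hi = t.x_max - self.x_lo
            count_diff[rows, col_lo] += 1
            count_diff[rows, col_hi + 1] -= 1
            if weight_diff is not None:
                # implied fragment length depends only on the row:
                # l = d - (e - s - r - 1) = d - diag_lo + l_min
                w = model.log_pmf(d_vals - t.diag_lo + t.l_min)
                weight_diff[rows, col_lo] += w
                weight_diff[rows, col_hi + 1] -= w
        self.counts = np.cumsum(count_diff, axis=1)[:, :-1]
        # -inf weights (possible only with pseudocount 0) produce nan right of
        # the contributing interval; affected candidates are rejected by the
        # finite-score assertion downstream
        with np.errstate(invalid="ignore"):
            self.weights = (
                np.cumsum(weight_diff, axis=1)[:, :-1] if weight_diff is not None else None
            )

    def cells_to_xy(self, rows: np.ndarray, cols: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        x = cols + self.x_lo
        y = x + rows + self.d_lo
        return x, y

    def omega(self) -> Tuple[np.ndarray, np.ndarray, int]:
        max_cov = int(self.counts.max())
        rows, cols = np.nonzero(self.counts == max_cov)
        return rows, cols, max_cov


def candidate_region(
    cluster: DuplicationCluster,
    cell_budget: int = DEFAULT_CELL_BUDGET,
) -> Tuple[List[Tuple[int, int]], int]:
    """Omega_k: lattice breakpoint-pairs at maximum trapezoid coverage.

    Returns the candidate points and the coverage they achieve
    (``max_coverage <= support``; equality means a common intersection
    exists, as for noise-free clusters).
    """
    raster = _Raster(cluster, cell_budget=cell_budget)
    rows, cols, max_cov = raster.omega()
    x, y = raster.cells_to_xy(rows, cols)
    return list(zip(x.tolist(), y.tolist())), max_cov


def score_candidates(
    cluster: DuplicationCluster,
    omega: Sequence[Tuple[int, int]],
    model: FragmentLengthModel,
    rng_seed: int = 0,
) -> TandemDuplicationCall:
    """Score each candidate and return the maximum-probability call.

    Ties at the maximum are broken uniformly at random; the RNG is seeded
    from ``rng_seed`` and the cluster id so per-cluster results do not depend
    on processing order.
    """
    if not omega:
        raise ValueError(f"cluster {cluster.cluster_id}: empty candidate set")
    raster = _Raster(cluster, model=model)
    xs = np.array([p[0] for p in omega], dtype=np.int64)
    ys = np.array([p[1] for p in omega], dtype=np.int64)
    cols = xs - raster.x_lo
    rows = ys - xs - raster.d_lo
    log_scores = raster.weights[rows, cols]
    coverages = raster.counts[rows, cols]
    if not np.all(np.isfinite(log_scores)):
        raise AssertionError(
            "non-finite candidate log-score; fit the fragment-length model with "
            "pseudocount > 0"
        )
    best = log_scores.max()
    ties = np.flatnonzero(log_scores == best)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, cluster.cluster_id]))
    pick = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
    # stable softmax over Omega
    norm = np.exp(log_scores - best)
    probs = norm / norm.sum()
    return TandemDuplicationCall(
        contig=cluster.contig,
        start=int(xs[pick]),
        end=int(ys[pick]),
        support=cluster.support,
        max_coverage=int(coverages[pick]),
        log_score=float(log_scores[pick]),
        normalized_probability=float(probs[pick]),
        cluster_id=cluster.cluster_id,
    )


def candidate_scores(
    cluster: DuplicationCluster,
    model: FragmentLengthModel,
    cell_budget: int = DEFAULT_CELL_BUDGET,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, y, log_score) for every Omega candidate — heatmap/debug dump."""
    raster = _Raster(cluster, model=model, cell_budget=cell_budget)
    rows, cols, _ = raster.omega()
    x, y = raster.cells_to_xy(rows, cols)
    return x, y, raster.weights[rows, cols]


def call_cluster(
    cluster: DuplicationCluster,
    model: FragmentLengthModel,
    rng_seed: int = 0,
    cell_budget: int = DEFAULT_CELL_BUDGET,
) -> TandemDuplicationCall:
    """candidate_region + score_candidates in one step."""
    omega, _ = candidate_region(cluster, cell_budget=cell_budget)
    return score_candidates(cluster, omega, model, rng_seed=rng_seed)
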