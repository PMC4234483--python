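"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tandemdup.fraglen import FragmentLengthModel
from tandemdup.geometry import Trapezoid, contains
from tandemdup.pairs import FORWARD, REVERSE, ReadPairAlignment


def make_rf_pair(s, e, r=75, pair_id="rf", contig="chr1"):
    return ReadPairAlignment(pair_id=pair_id, contig=contig, s=s, e=e,
                             strand_low=REVERSE, strand_high=FORWARD, r=r)


def make_fr_pair(s, e, r=75, pair_id="fr", contig="chr1"):
    return ReadPairAlignment(pair_id=pair_id, contig=contig, s=s, e=e,
                             strand_low=FORWARD, strand_high=REVERSE, r=r)


def uniform_model(l_min, l_max, pseudocount=1.0):
    """Flat fragment-length model on [l_min, l_max]."""
    return FragmentLengthModel(
        l_min=l_min, l_max=l_max,
        counts=np.zeros(l_max - l_min + 1), pseudocount=pseudocount,
    )


def lattice_points(t: Trapezoid):
    """All integer breakpoint-pairs inside a trapezoid, by exhaustive scan."""
    pts = []
    for x in range(t.x_min, t.x_max + 1):
        for d in range(t.diag_lo, t.diag_hi + 1):
            y = x + d
            if contains(t, x, y):
                pts.append((x, y))
    return pts


def lattice_intersects(a: Trapezoid, b: Trapezoid) -> bool:
    """Brute-force: do the two trapezoids share an integer lattice point?"""
    return bool(set(lattice_points(a)) & set(lattice_points(b)))


def random_trapezoid(rng, span=120, r=20):
    """Small random trapezoid for oracle-equivalence tests."""
    l_min = int(rng.integers(2 * r, 2 * r + 30))
    l_max = l_min + int(rng.integers(0, 25))
    s = int(rng.integers(100, 100 + span))
    e = s + int(rng.integers(0, l_max))
    return Trapezoid(pair_id=f"t{rng.integers(1e6)}", contig="chr1",
                     s=s, e=e, r=r, l_min=l_min, l_max=l_max)


@pytest.fixture
def rng():
    return np.random.default_rng(20240305)
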