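"""Synthetic tandem-duplication data generation and a surrogate mapper.

The generator reproduces a standard spike-in design: pick duplication start
positions uniformly at random on a reference contig, draw duplication sizes
from Normal(10 Kbp, 100 bp), insert an exact copy of each segment
immediately after its end breakpoint, then sequence the donor with
fixed-length paired-end reads (r = 75) whose fragment lengths follow
Normal(200, 10) and whose bases are substituted independently at a given
error rate.  A bundled random-reference generator stands in for a real
genome at desk scale.

The *surrogate mapper* (``oracle_map``) replaces an external aligner: each
read is placed at its true reference-equivalent position (a read straddling
a fusion point maps by its longer side), and a read whose mismatches —
injected errors plus junction-overhang bases differing at the mapped
location — exceed a budget is dropped together with its mate, reproducing
the loss of effective coverage that drives recall down as the error rate
rises.

Coordinate/fragment convention (used consistently by the fragment-length
model and the trapezoid geometry): a fragment starting at donor position v
with length l occupies [v, v + l - 1]; the left read is the forward-strand
bases [v, v + r - 1] and the right read is the reverse complement of
[v + l - r, v + l - 1].  A concordant pair then has outer span
e + r - s = l exactly, and an everted pair straddling a fusion point
satisfies the implied-fragment-length identity at the true breakpoints.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .pairs import PairSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment (defaults: the standard
    spike-in design at desk scale — 5 Mbp reference, 100 duplications)."""

    reference_length: int = 5_000_000
    n_duplications: int = 100
    dup_size_mean: float = 10_000.0
    dup_size_sd: float = 100.0
    coverage: float = 40.0
    read_length: int = 75
    frag_mean: float = 200.0
    frag_sd: float = 10.0
    base_error_rate: float = 0.01
    gc: float = 0.41
    seed: int = 0
    contig: str = "sim1"
    #: when True, "replace with a random base" may re-draw the original base,
    #: making the effective substitution rate 3/4 of nominal
    error_may_keep_base: bool = False
    max_mismatches: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_error_rate < 1.0):
            raise SimulationError("base_error_rate must be in [0, 1)")
        if min(self.reference_length, self.read_length, self.coverage,
               self.frag_mean, self.frag_sd + 1, self.dup_size_mean) <= 0:
            raise SimulationError("simulation parameters must be positive")

    @property
    def effective_error_rate(self) -> float:
        return self.base_error_rate * (0.75 if self.error_may_keep_base else 1.0)


@dataclass
class DuplicationRecord:
    contig: str
    start: int          # x0, reference coordinate, 1-based inclusive
    end: int            # y0
    donor_start: int    # original segment start on the donor
    donor_fusion: int   # donor position of the last base before the fusion point

    @property
    def size(self) -> int:
        return self.end - self.start + 1


class DonorMap:
    """Piecewise-linear donor -> reference coordinate map.

    The donor differs from the reference by tandem insertions only, so the
    map is a sorted list of segment starts with cumulative shifts; segment
    boundaries are the fusion junctions.
    """

    def __init__(self, starts: np.ndarray, shifts: np.ndarray, donor_length: int):
        self.starts = np.asarray(starts, dtype=np.int64)     # donor coord of each segment start
        self.shifts = np.asarray(shifts, dtype=np.int64)     # ref = donor - shift
        self.donor_length = donor_length

    def segment_of(self, pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.starts, pos, side="right") - 1

    def donor_to_ref(self, pos: np.ndarray) -> np.ndarray:
        return np.asarray(pos) - self.shifts[self.segment_of(pos)]

    def map_read_starts(
        self, a: np.ndarray, read_length: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Reference leftmost coordinate and junction overhang of reads
        spanning [a, a + r - 1].

        A read crossing a fusion junction is anchored by its longer side
        (ties go left); the returned overhang is the length of the shorter
        side — the bases that do not belong at the mapped location.
        Duplication sizes >= 2r guarantee at most one junction per read.
        """
        a = np.asarray(a, dtype=np.int64)
        b = a + read_length - 1
        seg_a = self.segment_of(a)
        seg_b = self.segment_of(b)
        ref = a - self.shifts[seg_a]
        overhang = np.zeros(len(a), dtype=np.int64)
        crossing = seg_b > seg_a
        if np.any(crossing):
            boundary = self.starts[seg_a[crossing] + 1]
            left_len = boundary - a[crossing]
            right_len = read_length - left_len
            right_wins = left_len < right_len
            # anchor on the right side: the first base past the junction maps
            # to boundary - shift; extend the read leftwards from there
            right_ref = boundary - self.shifts[seg_b[crossing]] - left_len
            ref[crossing] = np.where(right_wins, right_ref, ref[crossing])
            overhang[crossing] = np.minimum(left_len, right_len)
        return ref, overhang


@dataclass
class ReadLayout:
    """Columnar truth for every simulated pair (donor coordinates)."""

    v: np.ndarray           # fragment start
    frag_len: np.ndarray
    err_left: np.ndarray    # injected substitution count, left read
    err_right: np.ndarray
    read_length: int

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class SimulationTruth:
    duplications: List[DuplicationRecord]
    donor_map: DonorMap
    reference_length: int
    donor_length: int
    reads: Optional[ReadLayout] = None

    @property
    def intervals(self) -> List[Tuple[int, int]]:
        return [(d.start, d.end) for d in self.duplications]


# ---------------------------------------------------------------------------
# Reference and donor genome
# ---------------------------------------------------------------------------


def make_reference(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Random i.i.d. reference sequence with the given GC fraction."""
    if not (0.0 <= gc <= 1.0):
        raise SimulationError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def spike_duplications(
    reference: str,
    cfg: SimulationConfig,
    max_attempts_per_dup: int = 1000,
) -> Tuple[str, SimulationTruth]:
    """Insert non-overlapping tandem duplications into the reference.

    Start positions are uniform; sizes are rounded Normal(dup_size_mean,
    dup_size_sd) draws clipped below at 2r; proposals overlapping an accepted
    duplication (or running off the contig) are rejection-resampled.  The
    copy of [x0, y0] is inserted immediately after y0.
    """
    n_ref = len(reference)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    min_size = 2 * cfg.read_length
    accepted: List[Tuple[int, int]] = []
    attempts = 0
    budget = max_attempts_per_dup * max(cfg.n_duplications, 1)
    while len(accepted) < cfg.n_duplications:
        if attempts >= budget:
            raise SimulationError(
                f"placed only {len(accepted)}/{cfg.n_duplications} duplications "
                f"after {attempts} proposals; lower n_duplications or enlarge "
                "the reference"
            )
        attempts += 1
        size = max(int(round(rng.normal(cfg.dup_size_mean, cfg.dup_size_sd))), min_size)
        x0 = int(rng.integers(1, n_ref + 1))
        y0 = x0 + size - 1
        if y0 > n_ref:
            continue
        if any(x0 <= b and a <= y0 for a, b in accepted):
            continue
        accepted.append((x0, y0))
    accepted.sort()
    return insert_duplications(reference, accepted, contig=cfg.contig)


def insert_duplications(
    reference: str,
    intervals: List[Tuple[int, int]],
    contig: str = "sim1",
) -> Tuple[str, SimulationTruth]:
    """Build the donor genome for given non-overlapping [x0, y0] intervals
    (1-based inclusive, sorted), inserting each copy right after y0."""
    for (a, b), (c, _) in zip(intervals, intervals[1:]):
        if c <= b:
            raise SimulationError("duplication intervals must be sorted and disjoint")
    pieces: List[str] = []
    records: List[DuplicationRecord] = []
    starts = [1]
    shifts = [0]
    prev_end = 0   # last reference position already emitted
    offset = 0     # cumulative inserted length
    for x0, y0 in intervals:
        if not (1 <= x0 <= y0 <= len(reference)):
            raise SimulationError(f"interval ({x0}, {y0}) outside the reference")
        pieces.append(reference[prev_end:y0])
        pieces.append(reference[x0 - 1:y0])
        L = y0 - x0 + 1
        fusion = y0 + offset            # donor position of the last base before the junction
        records.append(
            DuplicationRecord(
                contig=contig,
                start=x0,
                end=y0,
                donor_start=x0 + offset,
                donor_fusion=fusion,
            )
        )
        offset += L
        starts.append(fusion + 1)
        shifts.append(offset)
        prev_end = y0
    pieces.append(reference[prev_end:])
    donor = "".join(pieces)
    truth = SimulationTruth(
        duplications=records,
        donor_map=DonorMap(np.array(starts), np.array(shifts), len(donor)),
        reference_length=len(reference),
        donor_length=len(donor),
    )
    return donor, truth


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def simulate_read_layout(donor_length: int, cfg: SimulationConfig) -> ReadLayout:
    """Draw fragment starts, lengths and per-read injected-error counts.

    The number of pairs is coverage * donor_length / (2r); fragment lengths
    are rounded Normal(frag_mean, frag_sd) clipped below at 2r; each
    fragment start is uniform over the positions where the fragment fits on
    the contig (equivalent to rejection-resampling starts that overflow).
    Error counts are Binomial(r, effective error rate) per read — the
    sequence-level generator injects exactly these counts.
    """
    r = cfg.read_length
    u = int(round(cfg.coverage * donor_length / (2 * r)))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    frag_len = np.maximum(
        np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=u)).astype(np.int64), 2 * r
    )
    if np.any(frag_len > donor_length):
        raise SimulationError("fragments longer than the contig")
    v = 1 + rng.integers(0, donor_length - frag_len + 1, size=u)
    p = cfg.effective_error_rate
    err = rng.binomial(r, p, size=(u, 2)) if p > 0 else np.zeros((u, 2), dtype=np.int64)
    return ReadLayout(v=v, frag_len=frag_len, err_left=err[:, 0],
                      err_right=err[:, 1], read_length=r)


def _revcomp_bytes(seq: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[seq[::-1]]


def generate_read_pairs(
    donor: str,
    cfg: SimulationConfig,
    layout: Optional[ReadLayout] = None,
    fastq_prefix: Optional[Union[str, os.PathLike]] = None,
) -> Tuple[ReadLayout, Optional[List[Tuple[str, str]]]]:
    """Materialize read sequences (and optionally FASTQ files) for a layout.

    Exactly ``err_left``/``err_right`` substitutions are placed per read at
    distinct positions, each drawn from the three non-identical bases (or
    any base when ``cfg.error_may_keep_base`` — in that mode the error
    counts were already thinned to the effective rate, so injected changes
    always differ from the original).  Returns the layout and, when no
    FASTQ prefix is given, the list of (left, right) sequences.
    """
    if layout is None:
        layout = simulate_read_layout(len(donor), cfg)
    r = layout.read_length
    arr = np.frombuffer(donor.encode("ascii"), dtype=np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    qual = "I" * r

    def emit(seq: np.ndarray, n_err: int) -> str:
        seq = seq.copy()
        if n_err:
            pos = rng.choice(r, size=n_err, replace=False)
            for pidx in pos:
                current = seq[pidx]
                others = _BASES[_BASES != current]
                seq[pidx] = rng.choice(others)
        return seq.tobytes().decode("ascii")

    out_pairs: Optional[List[Tuple[str, str]]] = None if fastq_prefix else []
    fq1 = fq2 = None
    if fastq_prefix:
        fq1 = open(f"{fastq_prefix}_1.fastq", "w")
        fq2 = open(f"{fastq_prefix}_2.fastq", "w")
    try:
        for i in range(len(layout)):
            v = int(layout.v[i])
            l = int(layout.frag_len[i])
            left = emit(arr[v - 1: v - 1 + r], int(layout.err_left[i]))
            right = emit(_revcomp_bytes(arr[v + l - r - 1: v + l - 1]),
                         int(layout.err_right[i]))
            if fq1 is not None:
                fq1.write(f"@pair{i}/1\n{left}\n+\n{qual}\n")
                fq2.write(f"@pair{i}/2\n{right}\n+\n{qual}\n")
            else:
                out_pairs.append((left, right))
    finally:
        if fq1 is not None:
            fq1.close()
            fq2.close()
    return layout, out_pairs


# ---------------------------------------------------------------------------
# Surrogate mapper
# ---------------------------------------------------------------------------


def oracle_map(
    layout: ReadLayout,
    donor_map: DonorMap,
    contig: str = "sim1",
    max_mismatches: int = 4,
    with_pair_ids: bool = False,
    seed: int = 0,
) -> PairSet:
    """Map simulated reads to their true reference-equivalent positions.

    A read's mismatch count against the reference at its mapped location is
    its injected-error count plus the junction-overhang bases (the shorter
    side of a junction-crossing read) that happen to differ there — each
    overhang base differs with probability 3/4 in random sequence.  Pairs
    where either read exceeds ``max_mismatches`` are dropped entirely (the
    surrogate for aligner read loss).  The left read is forward-strand, the
    right read reverse-strand; whichever maps to the lower reference
    coordinate becomes the pair's low end, so a fragment straddling a fusion
    point comes out everted (RF).
    """
    r = layout.read_length
    p_f, over_f = donor_map.map_read_starts(layout.v, r)             # left, forward
    p_r, over_r = donor_map.map_read_starts(layout.v + layout.frag_len - r, r)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    mm_left = layout.err_left + rng.binomial(over_f, 0.75)
    mm_right = layout.err_right + rng.binomial(over_r, 0.75)
    keep = (mm_left <= max_mismatches) & (mm_right <= max_mismatches)
    p_f, p_r = p_f[keep], p_r[keep]
    rf = p_r < p_f
    s = np.where(rf, p_r, p_f)
    e = np.where(rf, p_f, p_r)
    strand_low = np.where(rf, 1, 0).astype(np.uint8)      # reverse end is low => RF
    strand_high = np.where(rf, 0, 1).astype(np.uint8)
    ids = None
    if with_pair_ids:
        ids = [f"pair{i}" for i in np.flatnonzero(keep)]
    return PairSet(contig, s, e, strand_low, strand_high, r, pair_ids=ids)


# ---------------------------------------------------------------------------
# Text outputs
# ---------------------------------------------------------------------------


def write_fasta(path: Union[str, os.PathLike], name: str, sequence: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path: Union[str, os.PathLike]) -> List[Tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_truth(truth: SimulationTruth, path: Union[str, os.PathLike]) -> None:
    """Duplication truth as a 1-based inclusive TSV (reference coordinates)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tsize\tdonor_fusion\n")
        for d in truth.duplications:
            fh.write(f"{d.contig}\t{d.start}\t{d.end}\t{d.size}\t{d.donor_fusion}\n")


def read_truth_intervals(path: Union[str, os.PathLike]) -> List[Tuple[int, int]]:
    intervals = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        i_start, i_end = header.index("start"), header.index("end")
        for line in fh:
            if line.strip():
                fields = line.rstrip("\n").split("\t")
                intervals.append((int(fields[i_start]), int(fields[i_end])))
    return intervals
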