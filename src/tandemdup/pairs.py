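"""Paired-end alignment ingest and orientation classification.

A sequenced fragment yields two reads.  After alignment, the pair is
*concordant* (FR) when the lower-coordinate end maps to the forward strand
and the higher-coordinate end to the reverse strand, and *everted* (RF) when
the strands are swapped.  Everted pairs are the signature of a fragment that
straddled the fusion point of a tandem duplication, and are the raw evidence
this package consumes.  Everything downstream works on 1-based inclusive
coordinates; conversion from the 0-based alignment convention happens only at
the BAM/SAM boundary.

Two sources are supported: coordinate-sorted BAM/SAM (via pysam) and a plain
tab-separated "pair table" with columns ``pair_id contig s strand_low e
strand_high r`` (header required, strands written ``+``/``-``), which makes
every downstream stage testable from printed toy inputs without an aligner.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Tuple, Union

import numpy as np

FORWARD = "forward"
REVERSE = "reverse"

#: mapq sentinel for sources (the pair table) that carry no mapping quality
MAPQ_UNKNOWN = 255


class PairSourceError(RuntimeError):
    """Unreadable, truncated or internally inconsistent pair source."""


@dataclass(slots=True)
class ReadPairAlignment:
    """One mapped read pair on a single contig.

    ``s`` and ``e`` are the 1-based leftmost coordinates of the
    lower-coordinate and higher-coordinate ends; ``r`` is the (shared) read
    length.  ``orientation`` is derived from the two strands.
    """

    pair_id: str
    contig: str
    s: int
    e: int
    strand_low: str
    strand_high: str
    r: int
    mapq_low: int = MAPQ_UNKNOWN
    mapq_high: int = MAPQ_UNKNOWN

    def __post_init__(self) -> None:
        if self.s > self.e:
            raise ValueError(
                f"pair {self.pair_id}: s={self.s} > e={self.e} "
                "(s must be the lower-coordinate end)"
            )
        if self.s < 1:
            raise ValueError(f"pair {self.pair_id}: coordinates are 1-based, got s={self.s}")
        if self.r <= 0:
            raise ValueError(f"pair {self.pair_id}: read length must be positive, got {self.r}")

    @property
    def orientation(self) -> str:
        """``"RF"`` (everted), ``"FR"`` (concordant) or ``"other"``."""
        if self.strand_low == REVERSE and self.strand_high == FORWARD:
            return "RF"
        if self.strand_low == FORWARD and self.strand_high == REVERSE:
            return "FR"
        return "other"

    @property
    def span(self) -> int:
        """Outer span e + r - s: the observed fragment length for FR pairs."""
        return self.e + self.r - self.s


# ---------------------------------------------------------------------------
# Columnar container (fast path for simulation-scale inputs)
# ---------------------------------------------------------------------------


class PairSet:
    """Columnar collection of read pairs on a single contig.

    Strand arrays are uint8 with 0 = forward, 1 = reverse.  Used by the
    simulator's surrogate mapper and by the pipeline so that million-pair
    inputs stay in numpy; converts to/from ``ReadPairAlignment`` records.
    """

    def __init__(
        self,
        contig: str,
        s: np.ndarray,
        e: np.ndarray,
        strand_low: np.ndarray,
        strand_high: np.ndarray,
        r: int,
        pair_ids: Optional[Sequence[str]] = None,
        mapq_low: Optional[np.ndarray] = None,
        mapq_high: Optional[np.ndarray] = None,
    ):
        n = len(s)
        self.contig = contig
        self.s = np.asarray(s, dtype=np.int64)
        self.e = np.asarray(e, dtype=np.int64)
        self.strand_low = np.asarray(strand_low, dtype=np.uint8)
        self.strand_high = np.asarray(strand_high, dtype=np.uint8)
        self.r = int(r)
        self.pair_ids = list(pair_ids) if pair_ids is not None else None
        self.mapq_low = mapq_low
        self.mapq_high = mapq_high
        if not (len(self.e) == len(self.strand_low) == len(self.strand_high) == n):
            raise ValueError("PairSet columns have unequal lengths")
        if np.any(self.s > self.e):
            raise ValueError("PairSet requires s <= e for every pair")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def spans(self) -> np.ndarray:
        return self.e + self.r - self.s

    @property
    def is_rf(self) -> np.ndarray:
        return (self.strand_low == 1) & (self.strand_high == 0)

    @property
    def is_fr(self) -> np.ndarray:
        return (self.strand_low == 0) & (self.strand_high == 1)

    def subset(self, mask: np.ndarray) -> "PairSet":
        idx = np.flatnonzero(mask)
        return PairSet(
            self.contig,
            self.s[idx],
            self.e[idx],
            self.strand_low[idx],
            self.strand_high[idx],
            self.r,
            [self.pair_ids[i] for i in idx] if self.pair_ids is not None else None,
            self.mapq_low[idx] if self.mapq_low is not None else None,
            self.mapq_high[idx] if self.mapq_high is not None else None,
        )

    def pair_id(self, i: int) -> str:
        return self.pair_ids[i] if self.pair_ids is not None else f"pair{i}"

    def records(self) -> Iterator[ReadPairAlignment]:
        strands = (FORWARD, REVERSE)
        for i in range(len(self)):
            yield ReadPairAlignment(
                pair_id=self.pair_id(i),
                contig=self.contig,
                s=int(self.s[i]),
                e=int(self.e[i]),
                strand_low=strands[self.strand_low[i]],
                strand_high=strands[self.strand_high[i]],
                r=self.r,
                mapq_low=int(self.mapq_low[i]) if self.mapq_low is not None else MAPQ_UNKNOWN,
                mapq_high=int(self.mapq_high[i]) if self.mapq_high is not None else MAPQ_UNKNOWN,
            )

    @classmethod
    def from_records(cls, records: Iterable[ReadPairAlignment]) -> "PairSet":
        recs = list(records)
        if not recs:
            return cls("", np.empty(0, np.int64), np.empty(0, np.int64),
                       np.empty(0, np.uint8), np.empty(0, np.uint8), 1, [])
        contigs = {p.contig for p in recs}
        if len(contigs) > 1:
            raise ValueError(f"PairSet holds a single contig; got {sorted(contigs)}")
        rs = {p.r for p in recs}
        if len(rs) > 1:
            raise PairSourceError(f"mixed read lengths {sorted(rs)} in pair set")
        return cls(
            recs[0].contig,
            np.array([p.s for p in recs], np.int64),
            np.array([p.e for p in recs], np.int64),
            np.array([0 if p.strand_low == FORWARD else 1 for p in recs], np.uint8),
            np.array([0 if p.strand_high == FORWARD else 1 for p in recs], np.uint8),
            recs[0].r,
            [p.pair_id for p in recs],
            np.array([p.mapq_low for p in recs], np.int64),
            np.array([p.mapq_high for p in recs], np.int64),
        )


# ---------------------------------------------------------------------------
# Pair-table dialect
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["pair_id", "contig", "s", "strand_low", "e", "strand_high", "r"]
_STRAND_OUT = {FORWARD: "+", REVERSE: "-"}
_STRAND_IN = {"+": FORWARD, "-": REVERSE}


def write_pair_table(records: Iterable[ReadPairAlignment], path: Union[str, os.PathLike]) -> int:
    """Write records to the tab-separated pair-table dialect; returns count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for p in records:
            fh.write(
                f"{p.pair_id}\t{p.contig}\t{p.s}\t{_STRAND_OUT[p.strand_low]}"
                f"\t{p.e}\t{_STRAND_OUT[p.strand_high]}\t{p.r}\n"
            )
            n += 1
    return n


def read_pair_table(path: Union[str, os.PathLike]) -> Iterator[ReadPairAlignment]:
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t") != _TABLE_COLUMNS:
            raise PairSourceError(
                f"{path}: expected pair-table header {'	'.join(_TABLE_COLUMNS)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_TABLE_COLUMNS):
                raise PairSourceError(f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns")
            pair_id, contig, s, slow, e, shigh, r = fields
            try:
                yield ReadPairAlignment(
                    pair_id=pair_id,
                    contig=contig,
                    s=int(s),
                    e=int(e),
                    strand_low=_STRAND_IN[slow],
                    strand_high=_STRAND_IN[shigh],
                    r=int(r),
                )
            except (KeyError, ValueError) as exc:
                raise PairSourceError(f"{path}:{lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# BAM / SAM
# ---------------------------------------------------------------------------


def _stream_bam(path, min_mapq: int, contig: Optional[str]) -> Iterator[ReadPairAlignment]:
    import pysam

    skipped_intercontig = 0
    pending = {}
    read_length: Optional[int] = None
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam.fetch(contig=contig) if bam.has_index() else bam:
            if (
                aln.is_unmapped
                or aln.mate_is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
                or not aln.is_paired
            ):
                continue
            if contig is not None and aln.reference_name != contig:
                continue
            if aln.reference_id != aln.next_reference_id:
                skipped_intercontig += 1
                continue
            qname = aln.query_name
            mate = pending.pop(qname, None)
            if mate is None:
                pending[qname] = aln.to_dict() | {
                    "_pos": aln.reference_start,
                    "_rev": aln.is_reverse,
                    "_len": aln.query_length or aln.infer_read_length(),
                    "_mapq": aln.mapping_quality,
                    "_contig": aln.reference_name,
                }
                continue
            rlen = aln.query_length or aln.infer_read_length()
            if read_length is None:
                read_length = rlen
            for ln in (rlen, mate["_len"]):
                if ln != read_length:
                    raise PairSourceError(
                        f"mixed read lengths in {path}: pair {qname} has length {ln}, "
                        f"expected {read_length} (fixed-length library assumption)"
                    )
            # pysam reference_start is 0-based; core coordinates are 1-based
            pos_a, pos_b = mate["_pos"] + 1, aln.reference_start + 1
            rev_a, rev_b = mate["_rev"], aln.is_reverse
            mq_a, mq_b = mate["_mapq"], aln.mapping_quality
            if pos_a <= pos_b:
                s, e = pos_a, pos_b
                strand_low = REVERSE if rev_a else FORWARD
                strand_high = REVERSE if rev_b else FORWARD
                mq_low, mq_high = mq_a, mq_b
            else:
                s, e = pos_b, pos_a
                strand_low = REVERSE if rev_b else FORWARD
                strand_high = REVERSE if rev_a else FORWARD
                mq_low, mq_high = mq_b, mq_a
            if mq_low < min_mapq or mq_high < min_mapq:
                continue
            yield ReadPairAlignment(
                pair_id=qname,
                contig=mate["_contig"],
                s=s,
                e=e,
                strand_low=strand_low,
                strand_high=strand_high,
                r=read_length,
                mapq_low=mq_low,
                mapq_high=mq_high,
            )


def stream_pairs(
    source: Union[str, os.PathLike],
    min_mapq: int = 20,
    contig: Optional[str] = None,
) -> Iterator[ReadPairAlignment]:
    """Stream mapped read pairs from a BAM/SAM file or a pair table.

    Pairs with either end's mapq below ``min_mapq`` are suppressed
    (the operational stand-in for "uniquely mapped"); secondary,
    supplementary and duplicate-flagged records never contribute; pairs
    whose ends map to different contigs are skipped.  Mixed read lengths
    are a fatal configuration error.
    """
    path = str(source)
    if not os.path.exists(path):
        raise PairSourceError(f"pair source not found: {path}")
    if path.endswith((".bam", ".sam", ".cram")):
        yield from _stream_bam(path, min_mapq, contig)
        return
    read_length: Optional[int] = None
    for rec in read_pair_table(path):
        if contig is not None and rec.contig != contig:
            continue
        if read_length is None:
            read_length = rec.r
        elif rec.r != read_length:
            raise PairSourceError(
                f"mixed read lengths in {path}: pair {rec.pair_id} has r={rec.r}, "
                f"expected {read_length}"
            )
        if rec.mapq_low < min_mapq or rec.mapq_high < min_mapq:
            continue
        yield rec


# ---------------------------------------------------------------------------
# Stream splitting
# ---------------------------------------------------------------------------


def split_streams(
    pairs: Iterable[ReadPairAlignment],
    concordant_span_bounds: Optional[Tuple[int, int]] = None,
) -> Tuple[list, list, int]:
    """Partition pairs into (concordant FR, everted RF, discarded count).

    FR pairs whose outer span falls outside ``concordant_span_bounds`` (when
    given) are discarded rather than used for fragment-length fitting; RF
    pairs are always kept; any other orientation is discarded.
    """
    concordant: list = []
    everted: list = []
    discarded = 0
    for p in pairs:
        o = p.orientation
        if o == "RF":
            everted.append(p)
        elif o == "FR":
            if concordant_span_bounds is not None:
                lo, hi = concordant_span_bounds
                if not (lo <= p.span <= hi):
                    discarded += 1
                    continue
            concordant.append(p)
        else:
            discarded += 1
    return concordant, everted, discarded


def split_pairset(
    pairs: PairSet, concordant_span_bounds: Optional[Tuple[int, int]] = None
) -> Tuple[PairSet, PairSet, int]:
    """Vectorized :func:`split_streams` over a columnar :class:`PairSet`."""
    fr = pairs.is_fr
    rf = pairs.is_rf
    if concordant_span_bounds is not None:
        lo, hi = concordant_span_bounds
        spans = pairs.spans
        fr = fr & (spans >= lo) & (spans <= hi)
    discarded = len(pairs) - int(fr.sum()) - int(rf.sum())
    return pairs.subset(fr), pairs.subset(rf), discarded
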