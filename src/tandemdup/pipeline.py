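"""End-to-end calling pipeline.

fit fragment-length model -> build trapezoids from everted pairs ->
cluster -> enumerate and score candidate breakpoints -> resolve conflicts.
Stage counts are collected so a run can be audited (everted pairs in =
cluster members + dropped singletons + unusable pairs).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from . import breakpoints, clustering, conflict, fraglen, geometry, pairs

DEFAULT_MIN_MAPQ = 20


@dataclass
class CallerConfig:
    """All caller knobs with their defaults."""

    min_mapq: int = DEFAULT_MIN_MAPQ
    min_support: int = 2
    trim_quantile: float = 0.001
    pseudocount: float = 0.5
    min_concordant_pairs: int = 100
    cell_budget: int = breakpoints.DEFAULT_CELL_BUDGET
    min_overlap_fraction: float = 0.0   # conflict counts any >= 1 bp overlap
    seed: int = 0


@dataclass
class CallResult:
    calls: List[breakpoints.TandemDuplicationCall]
    removed: List[breakpoints.TandemDuplicationCall]
    model: Optional[fraglen.FragmentLengthModel]
    counts: Dict[str, int] = field(default_factory=dict)


def call_duplications(
    pair_source: Union[pairs.PairSet, Iterable[pairs.ReadPairAlignment]],
    config: CallerConfig = CallerConfig(),
    model: Optional[fraglen.FragmentLengthModel] = None,
) -> CallResult:
    """Run the calling pipeline on the pairs of one contig.

    ``model`` may be supplied to skip fragment-length fitting (e.g. a model
    fitted genome-wide while calling per contig).
    """
    if not isinstance(pair_source, pairs.PairSet):
        pair_source = pairs.PairSet.from_records(pair_source)
    concordant, everted, discarded = pairs.split_pairset(pair_source)
    counts: Dict[str, int] = {
        "input_pairs": len(pair_source),
        "concordant_pairs": len(concordant),
        "everted_pairs": len(everted),
        "discarded_pairs": discarded,
    }
    if model is None:
        model = fraglen.fit(
            concordant,
            trim_quantile=config.trim_quantile,
            pseudocount=config.pseudocount,
            min_pairs=config.min_concordant_pairs,
        )
    if len(everted) == 0:
        counts.update(unusable_everted=0, clusters=0, dropped_low_support=0,
                      conflicts_removed=0, calls=0)
        return CallResult([], [], model, counts)

    trapezoids: List[geometry.Trapezoid] = []
    unusable = 0
    for rec in everted.records():
        try:
            trapezoids.append(geometry.build_trapezoid(rec, model))
        except geometry.EmptyTrapezoidError:
            unusable += 1
    counts["unusable_everted"] = unusable

    clusters, dropped = clustering.connected_components(
        trapezoids, min_support=config.min_support
    )
    counts["clusters"] = len(clusters)
    counts["dropped_low_support"] = dropped

    raw_calls = [
        breakpoints.call_cluster(
            c, model, rng_seed=config.seed, cell_budget=config.cell_budget
        )
        for c in clusters
    ]
    kept, removed = conflict.resolve_conflicts(
        raw_calls, min_overlap_fraction=config.min_overlap_fraction
    )
    kept.sort(key=lambda c: (c.start, c.end))
    counts["conflicts_removed"] = len(removed)
    counts["calls"] = len(kept)
    return CallResult(kept, removed, model, counts)


def run_call(
    alignment_source: Union[str, os.PathLike],
    output_prefix: str,
    config: CallerConfig = CallerConfig(),
    contig: Optional[str] = None,
    reference_fasta: Optional[str] = None,
) -> CallResult:
    """File-to-file pipeline: read pairs, call, write TSV + VCF outputs."""
    records = list(pairs.stream_pairs(alignment_source, min_mapq=config.min_mapq,
                                      contig=contig))
    by_contig: Dict[str, List[pairs.ReadPairAlignment]] = {}
    for rec in records:
        by_contig.setdefault(rec.contig, []).append(rec)

    all_calls: List[breakpoints.TandemDuplicationCall] = []
    merged_counts: Dict[str, int] = {}
    model = None
    for name in sorted(by_contig):
        result = call_duplications(
            pairs.PairSet.from_records(by_contig[name]), config
        )
        model = result.model
        all_calls.extend(result.calls)
        for k, v in result.counts.items():
            merged_counts[k] = merged_counts.get(k, 0) + v

    write_calls_tsv(all_calls, f"{output_prefix}.calls.tsv")
    write_vcf(all_calls, f"{output_prefix}.vcf", reference_fasta=reference_fasta)
    return CallResult(all_calls, [], model, merged_counts)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

_TSV_HEADER = (
    "#coordinates are 1-based inclusive; length = end - start + 1\n"
    "contig\tstart\tend\tlength\tsupport\tmax_coverage\tnormalized_probability\n"
)


def write_calls_tsv(calls, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{c.length}\t{c.support}"
                f"\t{c.max_coverage}\t{c.normalized_probability:.6g}\n"
            )


def read_calls_tsv(path: Union[str, os.PathLike]) -> List[Tuple[int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig\t") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            intervals.append((int(fields[1]), int(fields[2])))
    return intervals


def write_vcf(calls, path: Union[str, os.PathLike],
              reference_fasta: Optional[str] = None,
              contig_lengths: Optional[Dict[str, int]] = None) -> None:
    """Calls as VCF 4.2 DUP records (POS = start, INFO END = end).

    The REF column carries the base at POS when a reference FASTA is given,
    ``N`` otherwise.
    """
    seqs: Dict[str, str] = {}
    if reference_fasta:
        from .simulate import read_fasta

        seqs = dict(read_fasta(reference_fasta))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DUP,Description="Tandem duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the duplicated segment (1-based inclusive)">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Everted read pairs supporting the call">\n')
        fh.write('##INFO=<ID=DB2P,Number=1,Type=Float,Description="Normalized breakpoint probability">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            ref_base = "N"
            if c.contig in seqs and 1 <= c.start <= len(seqs[c.contig]):
                ref_base = seqs[c.contig][c.start - 1]
            info = (
                f"SVTYPE=DUP;END={c.end};SUPPORT={c.support};"
                f"DB2P={c.normalized_probability:.6g}"
            )
            fh.write(
                f"{c.contig}\t{c.start}\ttd{i}\t{ref_base}\t<DUP>\t.\tPASS\t{info}\n"
            )
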