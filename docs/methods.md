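# Methods

## Problem and signal

A tandem duplication copies the genomic segment `[x0, y0]` and inserts the
copy immediately after `y0`.  In a paired-end sequencing experiment, a DNA
fragment that straddles the resulting fusion point (where the end of the
original segment meets the start of its copy) aligns to the reference in an
*everted* orientation: the end with the lower mapping coordinate lands on the
reverse strand and the higher end on the forward strand (an RF pair).
Concordant (FR) pairs, by contrast, measure the fragment length directly:
with `s` and `e` the 1-based leftmost coordinates of the lower and higher
ends and `r` the read length, the outer span `e + r - s` equals the fragment
length.  `tandemdup` detects tandem duplications from RF pairs and — the part
that distinguishes it from range-based callers — localizes their breakpoints
by scoring every feasible breakpoint-pair with the *empirical distribution*
of fragment length estimated from the FR pairs.

## Model

**Fragment-length model.**  The observed spans of concordant pairs form a
histogram over `[l_min, l_max]`, where the bounds are the `q` and `1 - q`
empirical quantiles (default `q = 0.001`; `q = 0` reproduces the strict
min/max reading).  Trimming protects the bounds — and hence the size of every
trapezoid below — from rare chimeric spans.  A pseudocount (default 0.5) is
added to every cell so the pmf is strictly positive on its support: the
breakpoint score is a product of pmf values and must not be annihilated by a
single empty histogram cell.  A 10^4-observation histogram is essentially
unchanged by this floor.

**Trapezoids.**  An RF pair `(s, e, r)` is explained by breakpoints `(x, y)`
iff

```
l(x, y) = y - e + s - x + r + 1  in  [l_min, l_max]     (the implied length)
x <= s                                                   (left read right of x)
y >= e + r - 1                                           (right read left of y)
```

a closed trapezoid in the `(x, y)` plane.  In sheared coordinates
`(x, d = y - x)` the region is `x <= s`, `d in [d_lo, d_hi]`,
`x + d >= e + r - 1` with integer bounds, so membership, emptiness
(`l_max < 2r` — the fragment cannot flank the fusion point) and pairwise
intersection are exact integer arithmetic.  For two such regions the
intersection is nonempty iff the combined `d` band is nonempty and
`min(s) + min(d_hi) >= max(e + r - 1)`; because all bounds are integers a
nonempty intersection always contains a lattice point, so the continuous
predicate and the lattice predicate coincide (verified against a brute-force
lattice scan in the tests).

**Clustering.**  Pairs induced by the same duplication have mutually
intersecting trapezoids, but noise makes the common intersection of a whole
group unreliable.  The grouping criterion is therefore connectivity of the
pairwise-intersection graph, found breadth-first from deterministically
ordered seeds.  A spatial index (an interval tree over bounding-box
x-extents, d-extents filtered on query) prunes candidate neighbours; the
exact predicate confirms each edge, so the index affects speed only.
Components smaller than `min_support` (default 2; the mutual-intersection
condition is unsatisfiable by a singleton) are dropped.

**Breakpoint scoring.**  For cluster `S_k`, the candidate set `Omega_k` is
the set of integer breakpoint-pairs covered by the maximum number of member
trapezoids.  Each candidate `(x, y)` is scored by

```
P[(x, y) | S_k]  ∝  prod_{i in Z_(x,y)}  P_L[ L = l_i(x, y) ]
```

where `Z_(x,y)` is the set of members containing the point and `l_i(x, y)`
the length the candidate implies for pair `i`.  Enumeration rasterizes the
cluster on the `(x, d)` grid: per-row x-intervals accumulate in a 2-D
difference array, so coverage counting and log-score summation cost O(grid
area), and the implied length depends only on the row.  Scores are kept in
log space; the reported probability is a max-shifted softmax over `Omega_k`.
Ties at the maximum are broken uniformly at random by an RNG seeded from the
global seed plus the cluster id, making per-cluster results independent of
processing order.  A configurable cell budget (default 10^7) guards against
pathological clusters.

**Conflict resolution.**  True duplications are assumed non-overlapping, so
overlapping calls mark false positives.  Greedily, the call overlapping the
most others is removed and counts are recomputed until the kept set is
overlap-free.  The tie order (fewer supporting pairs, then lower log score,
then leftmost) is a design choice — weakly supported calls are the likeliest
noise; any >= 1 bp overlap counts by default, with an optional minimum
overlap fraction.

## Simulator and surrogate mapper

The generator emulates the standard spike-in design: duplication starts
uniform on a random i.i.d. reference (GC 0.41), sizes rounded
Normal(10 kbp, 100 bp) draws (clipped at `2r`; never binding at these
defaults), overlapping proposals rejection-resampled, the copy inserted
right after `y0`.  Fragments start uniformly where they fit, lengths are
rounded Normal(200, 10) draws clipped at `2r`, and `coverage * L / (2r)`
pairs are drawn.  The left read is the forward-strand bases
`[v, v + r - 1]`; the right read is the reverse complement of
`[v + l - r, v + l - 1]`; each base is substituted independently with the
base-error probability by one of the three other bases (a mode where the
replacement may re-draw the original base, making the effective rate 3/4 of
nominal, is available but off by default).  This fragment convention makes
the FR span equal `l` exactly and makes the implied-length identity exact at
the true breakpoints, which the tests exploit.

The *surrogate mapper* replaces an external aligner: every read is placed at
its true reference-equivalent coordinate (known from the spike-in bookkeeping).
A read crossing a fusion junction is anchored by its longer side; its
mismatch count is its injected-error count plus a Binomial(overhang, 3/4)
draw for the overhang bases that differ at the mapped location (random
sequence agrees by chance 1/4).  A pair is dropped when either read exceeds
`max_mismatches` (default 4, the short-read-aligner budget for 75 bp reads).
This reproduces the mechanism that drives recall down with the error rate —
pairs supporting a duplication are lost to the mismatch budget — while
keeping precision near perfect, since no spurious placements are generated.

What the simulator does *not* model: alignment ambiguity and spurious
mappings (so measured precision is an upper bound on real-data precision),
quality scores, indels, PCR duplicates, chimeric fragments, diploidy.
Passing benchmarks here demonstrate the geometry, clustering, scoring and
conflict machinery under controlled noise, not robustness to aligner
artefacts.

## Benchmark metrics

A call is a true positive when overlap covers at least 50% of the truth
interval *and* 50% of the call interval (mutual overlap); matching is
greedy one-to-one by decreasing overlap fraction so one call cannot absorb
several truths.  Precision, recall and F1 follow; breakpoint mismatch is
`|Δstart| + |Δend|` averaged over true positives only.

## Problem sizes and reproducibility

The bundled study runs at desk scale: a 5-Mbp reference with 100 spiked
duplications per run (the same per-duplication read geometry as a
genome-scale run; only the number of events is smaller), error rates
{1, 3, 5, 7}% at 40X and coverages {10, 20, 60}X at 1% error, three seeds
per condition.  One run completes in roughly 10-20 s; the full grid in a few
minutes.  A single global seed fans out to per-stage seed sequences
(reference, spike, reads, mapper, per-cluster tie-breaks), so every output
is byte-reproducible.

## Known limitations

- Single-contig events only; inter-chromosomal or non-tandem duplications,
  deletions and inversions are out of scope.
- A cluster merging two nearby true duplications is not split; the
  maximum-support candidate step and conflict resolution arbitrate.
- `min_support = 2` discards single-pair evidence by design; recall at very
  high error rates is limited by surviving pair count, and with a strict
  per-read mismatch budget the caller recovers fewer noisy duplications
  than an aligner with quality-aware dropping and mate rescue would allow.
- The breakpoint estimate is a single point; no credible region is reported.
  Under a point-mass length model all candidates tie and the seeded random
  tie-break decides within the maximum-support segment.
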