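# tandemdup

Tandem-duplication detection from paired-end sequencing data, with
breakpoint localization driven by the empirical fragment-length
distribution.

## The problem

A tandem duplication repeats a genomic segment `[x0, y0]` immediately after
itself.  A sequenced fragment straddling the fusion point of the duplication
maps back to the reference in *everted* (RF) orientation — lower-coordinate
end on the reverse strand, higher end on the forward strand — while ordinary
fragments map concordantly (FR).  Most paired-end callers turn RF evidence
into a broad interval of possible breakpoints.  `tandemdup` goes further:
each RF pair `(s, e)` with read length `r` constrains the breakpoint-pair
`(x, y)` to a trapezoid

```
l_min <= y - e + s - x + r + 1 <= l_max ,    x <= s ,    y >= e + r - 1
```

and every candidate breakpoint-pair in a cluster of RF pairs is scored by

```
P[(x, y) | S]  ∝  Π_{i ∈ Z(x,y)}  P_L[ L = y - e_i + s_i - x + r + 1 ]
```

where `P_L` is the fragment-length distribution estimated from the
concordant pairs and `Z(x,y)` the RF pairs whose trapezoids contain the
point.  The argmax is reported, giving single-digit- to low-double-digit-bp
breakpoint accuracy where interval methods report hundreds of bases.  The
pipeline: fit `P_L` → build trapezoids → cluster intersecting trapezoids
(spatial index + exact integer predicate) → enumerate maximum-support
candidates → score → greedy conflict resolution.

The package also ships the spike-in simulator, a surrogate mapper (so no
aligner or genome download is needed), and the evaluation harness
(precision / recall / F1 / mean breakpoint mismatch at 50% mutual overlap),
making the whole benchmark study reproducible from one seed.  Intended
users: developers of structural-variant methods and anyone needing a
transparent, testable tandem-duplication caller for BAM/SAM input or plain
pair tables.

## Worked example

Simulate a 1-Mbp genome with 10 spiked duplications at 40X and 1% base
error, call, and evaluate:

```bash
$ tandemdup simulate --out-prefix demo --length 1000000 --n-duplications 10 \
      --coverage 40 --error-rate 0.01 --seed 7
simulated 293302 pairs (292419 mapped) over 10 duplications; outputs at demo.*

$ tandemdup call demo.pairs.tsv --out-prefix demo --seed 7
input_pairs=292419
concordant_pairs=292239
everted_pairs=180
discarded_pairs=0
unusable_everted=0
clusters=10
dropped_low_support=0
conflicts_removed=0
calls=10
wrote demo.calls.tsv and demo.vcf

$ tandemdup evaluate --truth demo.truth.tsv --calls demo.calls.tsv
tp=10
fp=0
fn=0
precision=1.0
recall=1.0
f1=1.0
mean_breakpoint_mismatch=6.4
```

The 292 k concordant pairs fit the fragment-length model; the 180 everted
pairs form 10 clusters — one per spiked duplication — and every cluster
yields a call.  All 10 calls match the truth at 50% mutual overlap
(precision = recall = 1) and the called breakpoints sit on average 6.4 bp
from the true ones (|Δstart| + |Δend|).  `demo.calls.tsv` holds one call per
line:

```
#coordinates are 1-based inclusive; length = end - start + 1
contig	start	end	length	support	max_coverage	normalized_probability
sim1	43266	53184	9919	16	16	0.164394
sim1	152854	162875	10022	18	17	0.564749
```

`support` is the number of everted pairs in the cluster, `max_coverage` how
many of their trapezoids contain the called point, and
`normalized_probability` the called point's share of the probability mass
over all maximum-support candidates.  A VCF 4.2 file (`SVTYPE=DUP`, `END`,
`SUPPORT`, `DB2P` score) is written alongside.  `tandemdup bench` sweeps
coverage × error-rate grids and tabulates the four metrics per run.

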