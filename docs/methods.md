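# Methods

## Coordinate model

All internal coordinates are 0-based half-open; only the I/O layer
converts (GFF3 is 1-based closed, BED6 is already half-open). An ORF is
its full genomic span — introns are ignored, which is adequate for the
compact, largely intron-free genomes this package targets. The
stop-codon-adjacent transcript boundary is `orf_end` on `+` and
`orf_start` on `−`; every downstream computation is strand-symmetric, and
the test suite checks invariance under a full genome mirror (coordinate
reflection plus strand swap).

## UTR calling

The caller scans per-base coverage outward from an ORF boundary in the
transcriptional direction, on the gene's own strand only. Parameters, all
exposed on `UtrCallParams`:

| parameter | default | units | role |
|---|---|---|---|
| `min_cov` | 1.0 | reads/base | a base counts as covered at or above this |
| `max_gap` | 5 | bases | longest sub-threshold run bridged inside a UTR |
| `max_utr_len` | 600 | bases | hard cap on a called UTR |
| `expr_min_mean_cov` | 1.0 | reads/base | mean-ORF-coverage gate for "expressed" |

The walk extends to the last covered base before a sub-threshold run
longer than `max_gap` (so a call never ends on an uncovered base), and is
clipped at `max_utr_len` and the chromosome end. The defaults are
deliberately permissive: a single read per base suffices, short dips
(mappability gaps) are bridged, and the cap sits far above the 9–211 bp
range of experimentally confirmed yeast 3′-UTR lengths, so it never binds
in practice. The call is monotone in its thresholds — raising `min_cov`
can only shorten a UTR, raising `max_gap` only lengthen it — which the
suite verifies property-style.

Restricting the walk to the gene's own strand is essential: a convergent
partner's antisense transcript covers the same bases on the opposite
strand, and counting it would inflate both UTRs and manufacture overlaps.

"Unexpressed" (for cross-dataset validation) means mean per-base ORF
coverage below `expr_min_mean_cov`. The gate is a parameter, not an
inference: different assay types (nascent vs mature RNA) warrant
different gates, and the default of 1 read/base is the weakest defensible
choice.

## Pair classification

Candidate pairs are genes consecutive in ORF-start order on a chromosome;
distant same-strand overlaps are not searched, since the phenomenon of
interest lives in shared intergenic regions of neighbors. Strands fix the
class (convergent `+/−`, divergent `−/+`, consistent same-strand), and a
pair is emitted only when its class-defining overlap — 3′-UTR intervals
for convergent, 5′-UTR intervals for divergent, transcript spans for
consistent — intersects by ≥ 1 bp.

`gap_bp` is the signed distance between the facing ORF boundaries and may
be negative when the ORFs themselves overlap. Two overlap measures are
always reported:

* `utr_overlap_bp` — intersection of the two class-defining UTR
  intervals (the membership criterion);
* `transcript_overlap_bp` — intersection of the full transcript spans,
  equal for convergent pairs to `max(0, u_up + u_down − gap)`.

The transcript-level measure is the one matching published per-pair
overlap lengths: it can exceed the shorter UTR when one transcript runs
past its partner's stop codon into the ORF (e.g. 3′-UTRs of 53 and 9 bp
separated by 33 bp overlap by 29 bp at the transcript level, more than
the 9 bp UTR). Reporting both makes the choice explicit instead of
guessing a single tally rule. The classifier computes the explicit
interval intersection; the closed formula is verified equivalent on
random triples (including negative gaps) against a per-base oracle.

A gene can appear in at most one convergent pair. With a single-stranded
annotation this holds automatically; a tie-break (larger UTR overlap,
then leftmost) covers duplicate/anomalous annotations deterministically.

## Correlation statistics

Expression is analyzed on the log2 scale; linear input is transformed as
log2(x + 1). The pseudocount of 1 is the standard convention and is
stated here because it matters for near-zero single-cell values.

Per condition, the anti-regulation statistic is Pearson *r* over
(up, down) log2 expression across convergent pairs. Two significance
measures are reported: the analytic two-sided p-value from the t
transform of *r*, and a one-sided (toward anti-correlation) permutation
p-value from shuffling the downstream partners across pairs — this breaks
the pairing while preserving each gene's marginal distribution. The
directional hypothesis argues for the one-sided permutation test;
published correlation tables conventionally report two-sided p-values, so
both are given rather than silently choosing. Permutation p-values are
smoothed as (1 + k)/(n_perm + 1) (default n_perm = 10,000) and are
uniform under a simulated null (KS-checked in the suite). No
multiple-testing correction is applied across conditions; the
per-condition values are raw by design, flagged here.

The permutation shuffles the *downstream* side. *r* and the analytic p
are exactly invariant to swapping all (up, down) labels; the realized
permutation p differs between orientations only by Monte-Carlo error.

`relative_expression_ddct` implements the qPCR fold ratio
2^−((Ct_target,test − Ct_ref,test) − (Ct_target,ctrl − Ct_ref,ctrl)).

## Cross-dataset validation

Confirmation re-runs the full caller + classifier on the second dataset's
coverage with the same parameters, rather than intersecting pre-made pair
lists — this keeps every threshold explicit and lets the gate be varied.
Statuses are mutually exclusive and exhaustive, with
`partner_unexpressed` taking precedence: a pair is only `not_confirmed`
when both genes are expressed yet the re-called UTRs no longer meet.
Percentages are reported to one decimal. Read-depth normalization between
datasets is out of scope; depth differences surface as shifts in the
unexpressed fraction, which is why the gate is exposed.

## Synthetic data: what it emulates, and what not

The generator lays out motifs (convergent / divergent / consistent pairs,
isolated genes) left-to-right, round-robin across chromosomes, separated
by `spacing` (default 700 bp) of empty sequence — more than `max_utr_len`,
so no called UTR can bridge motifs and the planted truth is unambiguous.
Within a convergent motif the gap is drawn so the facing UTR intervals
intersect by construction (1 ≤ gap ≤ u_up + u_down − 1); likewise for the
other pair classes. UTR lengths default to uniform on 9–211 bp (the span
of experimentally confirmed yeast 3′-UTRs), ORF lengths to 300–1500 bp,
and the config validates that ORFs are at least as long as the largest
UTR bound so transcript run-ins stay inside ORF spans.

Coverage is `depth` (default 10 reads/base) over each planted transcript
span on its strand, optionally Poisson-distributed with mean `depth`
(`noise_sd` acts as the switch; a Poisson's spread is fixed by its mean).
Expression matrices draw each pair from a bivariate normal on the log2
scale (marginal mean 8, sd 2 — typical microarray log2 intensities) with
the planted correlation; the single-cell generator is the same bivariate
draw (mean 5, sd 2) followed by independent zeroing with probability
`dropout_p`, the simplest emulation of capture loss.

What passing tests therefore show: the coordinate arithmetic, the caller
and the classifier are exact on clean data, and the statistics recover
planted effect sizes at the expected sampling error. What they do not
show: robustness to real coverage artifacts (mappability holes longer
than `max_gap`, overlapping isoforms, internal priming), to non-Gaussian
expression distributions, or to structured single-cell dropout that
depends on expression level. One identifiability limit is intrinsic, not
an implementation gap: the two transcripts of a same-strand (consistent)
pair merge into a single coverage run, so their inner UTR boundaries
cannot be recovered from coverage alone — the pair's class still is, and
exact UTR plant-and-recover is asserted for convergent, divergent and
isolated genes.

## Numerical and design choices

* Degenerate inputs fail loudly: < 3 usable pairs/cells, constant vectors
  (the error names which side), non-finite values, unknown chromosomes,
  unsorted classifier input.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give bit-identical annotations, coverage, matrices and
  permutation p-values. Per-condition permutation streams are derived
  from the run seed deterministically.
* Problem sizes in the test and acceptance runs (genomes of ~1,600–6,500
  genes, 10,000-triple oracles, 500-replicate null calibrations, 20-seed
  Monte-Carlo means) were chosen as the smallest at which the targeted
  effects are unambiguous at the stated tolerances; the whole suite runs
  in well under a minute on one CPU.
* The pipeline manifest records versions, parameters, seed and input
  checksums, making a run reproducible from the manifest alone.

## Known limitations

No isoform resolution or poly-A site clustering; one UTR per gene end.
No read-level simulation (FASTQ) or alignment. UTRs are not trimmed at a
neighbor's ORF boundary — deliberately, since transcript-level overlaps
of real convergent pairs demonstrably run into partner ORFs. Microarray
normalization (RMA) and probe summarization are upstream of this package:
expression matrices are consumed already normalized.
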