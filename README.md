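# convutr

Detection of **convergent gene pairs with overlapping 3′-UTRs** from a gene
annotation plus strand-specific coverage, and quantification of the
**anti-regulation (transcriptional interference)** between the partners.

In compact genomes such as budding yeast, adjacent genes frequently share
intergenic sequence through their untranslated regions. When two neighbors
sit on opposite strands with their 3′ ends facing each other, their
3′-UTRs can overlap — the two loci produce partially complementary
transcripts, and transcription of one can interfere with the other. The
signature of that interference is a negative Pearson correlation between
the partners' expression levels across conditions, and even across single
cells.

`convutr` is for computational biologists who have (a) a gene annotation
(GFF3 or BED6) and (b) strand-specific per-base coverage (bedGraph, one
file per strand), and want the full chain: UTR boundaries → pair
classification → anti-correlation statistics → cross-dataset confirmation.
A synthetic-data generator with recorded ground truth makes every stage
testable without any external dataset.

## Method

**UTR calling.** For each ORF the caller walks outward from the stop codon
(3′) or start codon (5′) in the transcriptional direction on the gene's
own strand, extending while per-base coverage ≥ `min_cov` (default 1
read/base), tolerating sub-threshold runs ≤ `max_gap` (default 5 bp),
trimming trailing sub-threshold bases, and capping at `max_utr_len`
(default 600 bp). Antisense coverage never counts toward a gene's UTR.

**Pair classification.** Genes consecutive in coordinate order on a
chromosome form a candidate pair, classified by strands: convergent
(`+`,`−`; 3′ ends facing), divergent (`−`,`+`; 5′ ends facing), or
consistent (same strand). A pair is emitted when the class-defining
overlap is ≥ 1 bp. For a convergent pair with 3′-UTR lengths
*u*<sub>up</sub>, *u*<sub>down</sub> and stop-codon separation *g*, the
transcript-level overlap is

&nbsp;&nbsp;&nbsp;&nbsp;overlap = max(0, *u*<sub>up</sub> + *u*<sub>down</sub> − *g*)

which can exceed the shorter UTR when one transcript runs past its
partner's stop codon (both the UTR-interval and transcript-level measures
are reported).

**Anti-regulation statistics.** For each condition, Pearson *r* over the
points (log2 expr<sub>up</sub>, log2 expr<sub>down</sub>) of all
convergent pairs, with the analytic two-sided p-value and a one-sided
permutation p-value from shuffling downstream partners across pairs
(default 10,000 shuffles, `(1 + k)/(n + 1)` smoothing). Also included:
UTR-length vs expression correlation, two-gene single-cell correlation,
and the 2<sup>−ΔΔCt</sup> fold ratio for qPCR relative quantification.

**Cross-validation.** Reference convergent pairs are re-assessed in a
second dataset by re-running the caller + classifier on its coverage:
`confirmed` (still convergent with overlapping 3′-UTRs),
`partner_unexpressed` (either gene below the mean-ORF-coverage gate), or
`not_confirmed`.

## Worked example

```python
from convutr import (GenomeSimConfig, generate_genome, generate_coverage,
                     generate_expression, call_all, classify_adjacent_pairs,
                     summarize, pair_correlation, compute_transcript_overlap)

# A convergent pair with 127 bp and 178 bp 3'-UTRs whose stop codons are
# 141 bp apart overlaps at the transcript level by:
compute_transcript_overlap(127, 178, 141)   # -> 164

# Plant a genome, recover it through the full pipeline:
cfg = GenomeSimConfig(n_convergent=200, n_divergent=20, n_consistent=20,
                      n_isolated=60, seed=1)
annot, truth = generate_genome(cfg)
cov = generate_coverage(annot, truth, depth=10)
models = call_all(annot, cov)
pairs = classify_adjacent_pairs(models)
print(summarize(pairs, annot).to_dict())
# {'n_convergent': 200, 'n_divergent': 20, 'n_consistent': 20,
#  'n_genes_total': 540, 'convergent_gene_fraction': 0.7407407407407407}

# Expression with a planted anti-correlation of -0.14 and its recovery:
conv = truth.pairs_of_class("convergent")
expr = generate_expression(conv, r_target=-0.14, n_conditions=1, seed=1)
res = pair_correlation(conv, expr, "cond_1", n_perm=10_000, seed=1)
print(f"r = {res.r:.3f}  p_perm = {res.p_perm:.4f}  n_pairs = {res.n_pairs}")
# r = -0.133  p_perm = 0.0316  n_pairs = 200
```

The planted class counts come back exactly (noiseless coverage makes UTR
recovery exact for convergent/divergent/isolated genes), and the
correlation estimate `-0.133` sits within sampling error
(≈ (1 − r²)/√(n − 1) ≈ 0.07 at n = 200) of the planted `-0.14`; the
one-sided permutation p-value of 0.03 rejects the no-coupling null.

## Command line

```bash
convutr simulate genome --config sim.yaml --seed 1 --out-prefix sim
convutr simulate coverage --annotation sim.gff3 --truth-genes sim.truth_genes.tsv --out-prefix sim
convutr call-utrs --annotation sim.gff3 --cov-plus sim.plus.bedgraph \
                  --cov-minus sim.minus.bedgraph --out models.tsv
convutr classify --models models.tsv --out-pairs pairs.tsv --out-summary summary.json
convutr correlate --pairs pairs.tsv --expression expr.tsv --seed 1 --out corr.tsv
convutr run --config pipeline.yaml      # all stages + reproducibility manifest
```

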