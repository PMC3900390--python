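"""Orientation/overlap classification of adjacent gene pairs.

Adjacent genes (consecutive in ORF-start order on a chromosome) fall into
three classes by strand configuration:

* **convergent** — upstream (leftmost) gene on '+', downstream on '-', their
  3' ends face each other across the intergenic region and their 3'-UTR
  intervals overlap by >= 1 bp;
* **divergent** — upstream on '-', downstream on '+', 5' ends face and the
  5'-UTR intervals overlap by >= 1 bp;
* **consistent** — same strand, transcript spans overlap by >= 1 bp.

Two overlap measures are always reported.  ``utr_overlap_bp`` is the
intersection of the two class-defining UTR intervals (the membership
criterion).  ``transcript_overlap_bp`` is the intersection of the full
transcript spans; for a convergent pair with facing 3'-UTR lengths
``u_up``/``u_down`` separated by a stop-codon gap ``g`` it equals
``max(0, u_up + u_down - g)`` — this transcript-level measure is the one a
3'-RACE-style "length of sequence overlap" reports, and it can exceed the
shorter UTR when one gene's UTR runs past its partner's stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .annotation_io import Annotation
from .utr_caller import TranscriptModel

PAIR_CLASSES = ("convergent", "divergent", "consistent")


def _intersect(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Length of the intersection of two half-open intervals (>= 0)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass(frozen=True)
class GenePair:
    """Two adjacent transcript models and their orientation/overlap facts.

    ``up`` is always the leftmost gene by coordinate.  ``gap_bp`` is the
    signed distance between the facing ORF boundaries (stop codons for
    convergent, start codons for divergent pairs); it is negative when the
    ORFs themselves overlap.
    """

    up: TranscriptModel
    down: TranscriptModel
    pair_class: str
    gap_bp: int
    utr_overlap_bp: int
    transcript_overlap_bp: int

    def __post_init__(self) -> None:
        if self.pair_class not in PAIR_CLASSES:
            raise ValueError(f"unknown pair class {self.pair_class!r}")
        if self.utr_overlap_bp > self.transcript_overlap_bp:
            raise ValueError(
                "UTR-level overlap cannot exceed transcript-level overlap"
            )

    @property
    def gene_ids(self) -> Tuple[str, str]:
        return (self.up.gene.gene_id, self.down.gene.gene_id)


@dataclass(frozen=True)
class ClassificationSummary:
    n_convergent: int
    n_divergent: int
    n_consistent: int
    n_genes_total: int
    convergent_gene_fraction: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "n_convergent": self.n_convergent,
            "n_divergent": self.n_divergent,
            "n_consistent": self.n_consistent,
            "n_genes_total": self.n_genes_total,
            "convergent_gene_fraction": self.convergent_gene_fraction,
        }


def compute_transcript_overlap(utr3_up: int, utr3_down: int, gap_bp: int) -> int:
    """Transcript-level overlap of a convergent pair from lengths and gap.

    ``max(0, utr3_up + utr3_down - gap_bp)``: the two transcripts run toward
    each other from stop codons ``gap_bp`` apart, so their spans share
    whatever the combined UTR lengths exceed the gap by.  Equals the
    per-base intersection of the two transcript intervals whenever the ORFs
    are long enough to contain the opposing run-in (always true for real
    ORFs; the classifier itself uses the explicit interval intersection).
    """
    if utr3_up < 0 or utr3_down < 0:
        raise ValueError("UTR lengths must be >= 0")
    return max(0, utr3_up + utr3_down - gap_bp)


def classify_adjacent_pairs(
    models: Sequence[TranscriptModel],
) -> List[GenePair]:
    """Emit classified pairs for consecutive genes on each chromosome.

    Input must be sorted by ``orf_start`` within each chromosome (the order
    :func:`convutr.utr_caller.call_all` produces).  A pair is emitted only
    when its class-defining overlap is >= 1 bp.  A gene may appear in at
    most one convergent pair: under annotation anomalies where both
    neighbors qualify, the pair with the larger UTR overlap wins, ties going
    to the left neighbor.
    """
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.gene.chrom, []).append(m)
    pairs: List[GenePair] = []
    for chrom in sorted(by_chrom):
        chrom_models = by_chrom[chrom]
        starts = [m.gene.orf_start for m in chrom_models]
        if starts != sorted(starts):
            raise ValueError(f"models on {chrom!r} are not sorted by orf_start")
        for a, b in zip(chrom_models, chrom_models[1:]):
            pair = _classify_one(a, b)
            if pair is not None:
                pairs.append(pair)
    return _dedup_convergent(pairs)


def _classify_one(a: TranscriptModel, b: TranscriptModel) -> GenePair | None:
    tx_ov = _intersect((a.tx_start, a.tx_end), (b.tx_start, b.tx_end))
    sa, sb = a.gene.strand, b.gene.strand
    if sa == "+" and sb == "-":
        utr_ov = _intersect(a.utr3_interval, b.utr3_interval)
        if utr_ov < 1:
            return None
        gap = b.gene.orf_start - a.gene.orf_end  # facing stop codons
        cls = "convergent"
    elif sa == "-" and sb == "+":
        utr_ov = _intersect(a.utr5_interval, b.utr5_interval)
        if utr_ov < 1:
            return None
        gap = b.gene.orf_start - a.gene.orf_end  # facing start codons
        cls = "divergent"
    else:  # same strand
        if tx_ov < 1:
            return None
        # the facing UTRs are a's inner/downstream-side and b's inner side
        if sa == "+":
            utr_ov = _intersect(a.utr3_interval, b.utr5_interval)
        else:
            utr_ov = _intersect(a.utr5_interval, b.utr3_interval)
        gap = b.gene.orf_start - a.gene.orf_end
        cls = "consistent"
    return GenePair(
        up=a,
        down=b,
        pair_class=cls,
        gap_bp=gap,
        utr_overlap_bp=utr_ov,
        transcript_overlap_bp=tx_ov,
    )


def _dedup_convergent(pairs: List[GenePair]) -> List[GenePair]:
    """Enforce at-most-one convergent pair per gene (annotation anomalies).

    With a correctly stranded annotation this is a no-op: a '+' gene can
    only be the upstream member and a '-' gene only the downstream member
    of a convergent pair.  Kept for duplicate/odd annotations: the pair with
    larger ``utr_overlap_bp`` wins, ties break to the leftmost pair.
    """
    conv = [p for p in pairs if p.pair_class == "convergent"]
    if not conv:
        return pairs
    keep: Dict[int, GenePair] = {}
    best_for_gene: Dict[str, GenePair] = {}
    order = {id(p): i for i, p in enumerate(pairs)}
    for p in conv:
        ok = True
        for gid in p.gene_ids:
            q = best_for_gene.get(gid)
            if q is not None:
                better = p.utr_overlap_bp > q.utr_overlap_bp or (
                    p.utr_overlap_bp == q.utr_overlap_bp
                    and order[id(p)] < order[id(q)]
                )
                if better:
                    keep.pop(id(q), None)
                    for g2 in q.gene_ids:
                        if best_for_gene.get(g2) is q:
                            del best_for_gene[g2]
                else:
                    ok = False
        if ok:
            keep[id(p)] = p
            for gid in p.gene_ids:
                best_for_gene[gid] = p
    return [
        p
        for p in pairs
        if p.pair_class != "convergent" or id(p) in keep
    ]


def summarize(
    pairs: Sequence[GenePair], annot: Annotation
) -> ClassificationSummary:
    """Tally pair classes and the fraction of genes in convergent pairs."""
    n_conv = sum(1 for p in pairs if p.pair_class == "convergent")
    n_div = sum(1 for p in pairs if p.pair_class == "divergent")
    n_cons = sum(1 for p in pairs if p.pair_class == "consistent")
    n_total = annot.n_genes
    frac = (2.0 * n_conv / n_total) if n_total else 0.0
    return ClassificationSummary(
        n_convergent=n_conv,
        n_divergent=n_div,
        n_consistent=n_cons,
        n_genes_total=n_total,
        convergent_gene_fraction=frac,
    )
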