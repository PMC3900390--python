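"""Synthetic genomes, coverage tracks and expression matrices with known truth.

Every stage of the pipeline is testable without external downloads by
generating toy data whose ground truth is recorded in a :class:`TruthTable`:

* a multi-chromosome annotation laid out as isolated "motifs" — convergent
  pairs (facing 3'-UTRs forced to overlap by >= 1 bp), divergent pairs
  (facing 5'-UTRs overlapping), consistent pairs (same-strand transcript
  overlap) and isolated genes — separated by enough empty space that no
  unintended pair can arise;
* strand-specific per-base coverage equal to ``depth`` over each planted
  transcript span (optionally Poisson-distributed around it);
* expression matrices in which partner genes are drawn from a bivariate
  normal on the log2 scale with a planted Pearson correlation;
* two-gene single-cell profiles with a planted correlation and optional
  dropout;
* a "second dataset" coverage variant planting a chosen partition of
  confirmed / partner-unexpressed / not-confirmed statuses for the
  cross-validation stage.

All generators are deterministic under a fixed seed.

One identifiability note: the two transcripts of a *consistent* (same
strand) pair merge into a single coverage run, so their inner UTR lengths
cannot be recovered from coverage alone — the pair's class can, and is.
Exact plant-and-recover of UTR lengths therefore holds for convergent,
divergent and isolated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_io import Annotation, GeneRecord
from .pair_classifier import compute_transcript_overlap
from .expression_stats import ExpressionMatrix
from .utr_caller import CoverageTrack


class SimConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class GenomeSimConfig:
    """Layout parameters of the synthetic genome.

    UTR length ranges default to the span observed for experimentally
    confirmed yeast 3'-UTRs (9-211 bp).  ``spacing`` is the empty distance
    left between consecutive motifs' transcript extents; it must comfortably
    exceed the UTR ranges so planted motifs stay isolated.
    """

    n_convergent: int = 0
    n_divergent: int = 0
    n_consistent: int = 0
    n_isolated: int = 0
    utr3_len_range: Tuple[int, int] = (9, 211)
    utr5_len_range: Tuple[int, int] = (9, 211)
    gap_range: Tuple[int, int] = (1, 300)
    orf_len_range: Tuple[int, int] = (300, 1500)
    n_chromosomes: int = 16
    spacing: int = 700
    chrom_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_convergent", "n_divergent", "n_consistent", "n_isolated"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        for name in ("utr3_len_range", "utr5_len_range", "orf_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise SimConfigError(f"{name} must satisfy 1 <= lo <= hi")
        if self.n_chromosomes < 1:
            raise SimConfigError("need at least one chromosome")
        utr_hi = max(self.utr3_len_range[1], self.utr5_len_range[1])
        if self.orf_len_range[0] < utr_hi:
            raise SimConfigError(
                "orf_len_range[0] must be >= the largest UTR bound "
                f"({utr_hi}) so transcript overlaps stay within ORF spans"
            )
        if self.spacing < 2 * utr_hi + 50:
            raise SimConfigError(
                f"spacing ({self.spacing}) too small to isolate motifs; "
                f"need >= {2 * utr_hi + 50}"
            )


@dataclass(frozen=True)
class TrueGene:
    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    utr5_len: int
    utr3_len: int

    @property
    def tx_start(self) -> int:
        return self.orf_start - (self.utr5_len if self.strand == "+" else self.utr3_len)

    @property
    def tx_end(self) -> int:
        return self.orf_end + (self.utr3_len if self.strand == "+" else self.utr5_len)

    def to_record(self) -> GeneRecord:
        return GeneRecord(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            orf_start=self.orf_start,
            orf_end=self.orf_end,
        )


@dataclass(frozen=True)
class TruePair:
    up_id: str
    down_id: str
    pair_class: str
    gap_bp: int
    utr_overlap_bp: int
    transcript_overlap_bp: int


@dataclass
class TruthTable:
    """Ground truth planted by the generators."""

    genes: List[TrueGene] = field(default_factory=list)
    pairs: List[TruePair] = field(default_factory=list)
    #: (up_id, down_id) -> planted validation status
    validation: Dict[Tuple[str, str], str] = field(default_factory=dict)
    #: planted correlation parameters, e.g. {"r_target": -0.14}
    correlation: Dict[str, float] = field(default_factory=dict)

    def gene(self, gene_id: str) -> TrueGene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def pairs_of_class(self, pair_class: str) -> List[TruePair]:
        return [p for p in self.pairs if p.pair_class == pair_class]


def _interval_intersection(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _sample_gap(rng: np.random.Generator, cfg: GenomeSimConfig, total: int) -> int:
    """A gap in [1, total-1] intersected with cfg.gap_range when possible."""
    lo = max(1, cfg.gap_range[0])
    hi = min(cfg.gap_range[1], total - 1)
    if hi < lo:
        lo, hi = 1, total - 1
    return int(rng.integers(lo, hi + 1))


class _Layout:
    """Mutable per-chromosome cursor used while placing motifs."""

    def __init__(self, cfg: GenomeSimConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.genes: List[TrueGene] = []
        self.pairs: List[TruePair] = []
        self.cursor: Dict[str, int] = {
            f"chr{i + 1}": cfg.spacing for i in range(cfg.n_chromosomes)
        }
        self._gene_no = 0

    def _next_id(self) -> str:
        self._gene_no += 1
        return f"g{self._gene_no:05d}"

    def _utr3(self) -> int:
        lo, hi = self.cfg.utr3_len_range
        return int(self.rng.integers(lo, hi + 1))

    def _utr5(self) -> int:
        lo, hi = self.cfg.utr5_len_range
        return int(self.rng.integers(lo, hi + 1))

    def _orf(self) -> int:
        lo, hi = self.cfg.orf_len_range
        return int(self.rng.integers(lo, hi + 1))

    def _add_gene(
        self, chrom: str, strand: str, orf_start: int, orf_len: int,
        utr5: int, utr3: int,
    ) -> TrueGene:
        g = TrueGene(
            gene_id=self._next_id(),
            chrom=chrom,
            strand=strand,
            orf_start=orf_start,
            orf_end=orf_start + orf_len,
            utr5_len=utr5,
            utr3_len=utr3,
        )
        self.genes.append(g)
        return g

    def place_convergent(self, chrom: str) -> None:
        c = self.cursor[chrom]
        u3a, u3b = self._utr3(), self._utr3()
        gap = _sample_gap(self.rng, self.cfg, u3a + u3b)
        a = self._add_gene(chrom, "+", c, self._orf(), self._utr5(), u3a)
        b = self._add_gene(
            chrom, "-", a.orf_end + gap, self._orf(), self._utr5(), u3b
        )
        utr_ov = _interval_intersection(
            (a.orf_end, a.orf_end + u3a), (b.orf_start - u3b, b.orf_start)
        )
        tx_ov = _interval_intersection(
            (a.tx_start, a.tx_end), (b.tx_start, b.tx_end)
        )
        assert tx_ov == compute_transcript_overlap(u3a, u3b, gap)
        assert utr_ov >= 1
        self.pairs.append(
            TruePair(a.gene_id, b.gene_id, "convergent", gap, utr_ov, tx_ov)
        )
        self.cursor[chrom] = max(a.tx_end, b.tx_end) + self.cfg.spacing

    def place_divergent(self, chrom: str) -> None:
        c = self.cursor[chrom]
        u5a, u5b = self._utr5(), self._utr5()
        gap = _sample_gap(self.rng, self.cfg, u5a + u5b)
        a = self._add_gene(chrom, "-", c, self._orf(), u5a, self._utr3())
        b = self._add_gene(
            chrom, "+", a.orf_end + gap, self._orf(), u5b, self._utr3()
        )
        utr_ov = _interval_intersection(
            (a.orf_end, a.orf_end + u5a), (b.orf_start - u5b, b.orf_start)
        )
        tx_ov = _interval_intersection(
            (a.tx_start, a.tx_end), (b.tx_start, b.tx_end)
        )
        assert utr_ov >= 1
        self.pairs.append(
            TruePair(a.gene_id, b.gene_id, "divergent", gap, utr_ov, tx_ov)
        )
        self.cursor[chrom] = max(a.tx_end, b.tx_end) + self.cfg.spacing

    def place_consistent(self, chrom: str) -> None:
        c = self.cursor[chrom]
        strand = "+" if self.rng.integers(0, 2) == 0 else "-"
        if strand == "+":
            # a's 3'-UTR runs into b's 5' side
            inner_a, inner_b = self._utr3(), self._utr5()
            gap = _sample_gap(self.rng, self.cfg, inner_a + inner_b)
            a = self._add_gene(chrom, "+", c, self._orf(), self._utr5(), inner_a)
            b = self._add_gene(
                chrom, "+", a.orf_end + gap, self._orf(), inner_b, self._utr3()
            )
            utr_ov = _interval_intersection(
                (a.orf_end, a.orf_end + inner_a),
                (b.orf_start - inner_b, b.orf_start),
            )
        else:
            # a's 5'-UTR (rightward on '-') meets b's 3'-UTR (leftward)
            inner_a, inner_b = self._utr5(), self._utr3()
            gap = _sample_gap(self.rng, self.cfg, inner_a + inner_b)
            a = self._add_gene(chrom, "-", c, self._orf(), inner_a, self._utr3())
            b = self._add_gene(
                chrom, "-", a.orf_end + gap, self._orf(), self._utr5(), inner_b
            )
            utr_ov = _interval_intersection(
                (a.orf_end, a.orf_end + inner_a),
                (b.orf_start - inner_b, b.orf_start),
            )
        tx_ov = _interval_intersection(
            (a.tx_start, a.tx_end), (b.tx_start, b.tx_end)
        )
        assert tx_ov >= 1
        self.pairs.append(
            TruePair(a.gene_id, b.gene_id, "consistent", gap, utr_ov, tx_ov)
        )
        self.cursor[chrom] = max(a.tx_end, b.tx_end) + self.cfg.spacing

    def place_isolated(self, chrom: str) -> None:
        c = self.cursor[chrom]
        strand = "+" if self.rng.integers(0, 2) == 0 else "-"
        g = self._add_gene(chrom, strand, c, self._orf(), self._utr5(), self._utr3())
        self.cursor[chrom] = g.tx_end + self.cfg.spacing


def generate_genome(config: GenomeSimConfig) -> Tuple[Annotation, TruthTable]:
    """Lay out planted motifs left-to-right across chromosomes.

    Motifs are shuffled and distributed round-robin; each is separated from
    the next by ``config.spacing`` bases of empty sequence so classification
    can never couple genes of different motifs.  Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    motifs = (
        ["convergent"] * config.n_convergent
        + ["divergent"] * config.n_divergent
        + ["consistent"] * config.n_consistent
        + ["isolated"] * config.n_isolated
    )
    rng.shuffle(motifs)
    layout = _Layout(config, rng)
    chroms = list(layout.cursor)
    place = {
        "convergent": layout.place_convergent,
        "divergent": layout.place_divergent,
        "consistent": layout.place_consistent,
        "isolated": layout.place_isolated,
    }
    for i, motif in enumerate(motifs):
        place[motif](chroms[i % len(chroms)])

    chrom_lengths = {c: layout.cursor[c] for c in chroms}
    if config.chrom_length is not None:
        for c, needed in chrom_lengths.items():
            if needed > config.chrom_length:
                raise SimConfigError(
                    f"chromosome {c} needs {needed} bases but chrom_length "
                    f"is {config.chrom_length}"
                )
        chrom_lengths = {c: config.chrom_length for c in chroms}

    annot = Annotation(
        (g.to_record() for g in layout.genes), chrom_lengths=chrom_lengths
    )
    truth = TruthTable(genes=layout.genes, pairs=layout.pairs)
    return annot, truth


def generate_coverage(
    annot: Annotation,
    truth: TruthTable,
    depth: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CoverageTrack:
    """Per-base coverage of ``depth`` over each planted transcript span.

    When ``noise_sd > 0`` the per-base counts over transcript spans are
    Poisson-distributed with mean ``depth`` instead of constant (a Poisson's
    spread is fixed by its mean; ``noise_sd`` acts as the noise switch).
    Bases outside every transcript span are zero.
    """
    rng = np.random.default_rng(seed)
    track = CoverageTrack.zeros(annot.chrom_lengths)
    for g in truth.genes:
        arr = track.get(g.chrom, g.strand)
        span = slice(g.tx_start, g.tx_end)
        n = g.tx_end - g.tx_start
        if noise_sd > 0:
            arr[span] += rng.poisson(depth, size=n)
        else:
            arr[span] += depth
    return track


def generate_validation_coverage(
    annot: Annotation,
    truth: TruthTable,
    n_confirmed: int,
    n_partner_unexpressed: int,
    n_not_confirmed: int,
    depth: float = 10.0,
    seed: int = 0,
) -> Tuple[CoverageTrack, Dict[Tuple[str, str], str]]:
    """Plant a validation partition over the truth table's convergent pairs.

    Builds a "second dataset" coverage track in which a random subset of
    convergent pairs is made unconfirmable (coverage restricted to the ORFs,
    so re-called UTRs no longer overlap), another subset has its downstream
    gene silenced entirely (partner unexpressed), and the rest keep their
    full transcript coverage (confirmed).  Returns the coverage and the
    planted status of each pair; statuses are also recorded in
    ``truth.validation``.
    """
    conv = truth.pairs_of_class("convergent")
    total = n_confirmed + n_partner_unexpressed + n_not_confirmed
    if total != len(conv):
        raise SimConfigError(
            f"status counts sum to {total} but there are {len(conv)} "
            "convergent pairs"
        )
    rng = np.random.default_rng(seed)
    order = list(conv)
    rng.shuffle(order)
    statuses: Dict[Tuple[str, str], str] = {}
    for i, pair in enumerate(order):
        if i < n_confirmed:
            statuses[(pair.up_id, pair.down_id)] = "confirmed"
        elif i < n_confirmed + n_partner_unexpressed:
            statuses[(pair.up_id, pair.down_id)] = "partner_unexpressed"
        else:
            statuses[(pair.up_id, pair.down_id)] = "not_confirmed"

    silenced: Dict[str, str] = {}  # gene_id -> treatment
    for (up_id, down_id), status in statuses.items():
        if status == "partner_unexpressed":
            silenced[down_id] = "silenced"
        elif status == "not_confirmed":
            silenced[up_id] = "orf_only"
            silenced[down_id] = "orf_only"

    track = CoverageTrack.zeros(annot.chrom_lengths)
    for g in truth.genes:
        treatment = silenced.get(g.gene_id)
        if treatment == "silenced":
            continue
        arr = track.get(g.chrom, g.strand)
        if treatment == "orf_only":
            arr[g.orf_start : g.orf_end] += depth
        else:
            arr[g.tx_start : g.tx_end] += depth
    truth.validation.update(statuses)
    return track, statuses


def generate_expression(
    pairs: Sequence[TruePair],
    r_target: float,
    n_conditions: int = 7,
    noise_sd: float = 0.0,
    seed: int = 0,
    mean_log2: float = 8.0,
    sd_log2: float = 2.0,
    extra_gene_ids: Sequence[str] = (),
) -> ExpressionMatrix:
    """Expression matrix with a planted pairwise correlation.

    For each pair and condition, (up, down) log2 values are drawn from a
    bivariate normal with marginal mean ``mean_log2``, sd ``sd_log2`` and
    correlation ``r_target``.  ``extra_gene_ids`` get independent draws.
    ``noise_sd`` adds independent Gaussian noise on top, which attenuates
    the realized correlation by ``sd_log2**2 / (sd_log2**2 + noise_sd**2)``.
    """
    if not -1.0 <= r_target <= 1.0:
        raise SimConfigError(f"r_target must be in [-1, 1], got {r_target}")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sd_log2**2, r_target * sd_log2**2],
            [r_target * sd_log2**2, sd_log2**2],
        ]
    )
    gene_ids: List[str] = []
    rows: List[np.ndarray] = []
    for pair in pairs:
        draws = rng.multivariate_normal(
            [mean_log2, mean_log2], cov, size=n_conditions, method="eigh"
        )  # n_conditions x 2
        gene_ids.extend([pair.up_id, pair.down_id])
        rows.append(draws[:, 0])
        rows.append(draws[:, 1])
    for gid in extra_gene_ids:
        gene_ids.append(gid)
        rows.append(rng.normal(mean_log2, sd_log2, size=n_conditions))
    values = np.asarray(rows)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    df = pd.DataFrame(
        values,
        index=gene_ids,
        columns=[f"cond_{i + 1}" for i in range(n_conditions)],
    )
    return ExpressionMatrix(df, scale="log2")


def generate_single_cell(
    r_target: float,
    n_cells: int,
    mean_log2: float = 5.0,
    sd_log2: float = 2.0,
    dropout_p: float = 0.0,
    seed: int = 0,
    gene_ids: Tuple[str, str] = ("gene_up", "gene_down"),
) -> ExpressionMatrix:
    """Two-gene single-cell profile with planted correlation and dropout.

    Cells are bivariate-normal draws on the log2 scale (a Gaussian copula
    with Gaussian marginals); dropout then zeroes each value independently
    with probability ``dropout_p``, emulating single-cell capture loss.
    """
    if not -1.0 <= r_target <= 1.0:
        raise SimConfigError(f"r_target must be in [-1, 1], got {r_target}")
    if not 0.0 <= dropout_p <= 1.0:
        raise SimConfigError(f"dropout_p must be in [0, 1], got {dropout_p}")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sd_log2**2, r_target * sd_log2**2],
            [r_target * sd_log2**2, sd_log2**2],
        ]
    )
    draws = rng.multivariate_normal(
        [mean_log2, mean_log2], cov, size=n_cells, method="eigh"
    ).T  # 2 x n_cells
    if dropout_p > 0:
        mask = rng.random(size=draws.shape) < dropout_p
        draws = np.where(mask, 0.0, draws)
    df = pd.DataFrame(
        draws,
        index=list(gene_ids),
        columns=[f"cell_{i + 1}" for i in range(n_cells)],
    )
    return ExpressionMatrix(df, scale="log2")


# --- file output -----------------------------------------------------------


def write_genome_gff(annot: Annotation, path: str | Path) -> None:
    """Write the annotation as GFF3 gene rows with sequence-region pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annot.chroms:
            fh.write(
                f"##sequence-region {chrom} 1 {annot.chrom_lengths[chrom]}\n"
            )
        for g in annot.all_genes():
            fh.write(
                f"{g.chrom}\tconvutr_sim\tgene\t{g.orf_start + 1}\t{g.orf_end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_truth_table(
    genes_path: str | Path, pairs_path: Optional[str | Path] = None
) -> TruthTable:
    """Rebuild a TruthTable from the TSVs written by :func:`write_truth_table`."""
    gdf = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = [
        TrueGene(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            strand=row["strand"],
            orf_start=int(row["orf_start"]),
            orf_end=int(row["orf_end"]),
            utr5_len=int(row["utr5_len"]),
            utr3_len=int(row["utr3_len"]),
        )
        for _, row in gdf.iterrows()
    ]
    pairs: List[TruePair] = []
    if pairs_path is not None:
        pdf = pd.read_csv(
            pairs_path, sep="\t", dtype={"gene_up": str, "gene_down": str}
        )
        pairs = [
            TruePair(
                up_id=row["gene_up"],
                down_id=row["gene_down"],
                pair_class=row["pair_class"],
                gap_bp=int(row["gap_bp"]),
                utr_overlap_bp=int(row["utr_overlap_bp"]),
                transcript_overlap_bp=int(row["transcript_overlap_bp"]),
            )
            for _, row in pdf.iterrows()
        ]
    return TruthTable(genes=genes, pairs=pairs)


def write_truth_table(truth: TruthTable, genes_path: str | Path,
                      pairs_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "orf_start": g.orf_start,
                "orf_end": g.orf_end,
                "utr5_len": g.utr5_len,
                "utr3_len": g.utr3_len,
            }
            for g in truth.genes
        ]
    ).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_up": p.up_id,
                "gene_down": p.down_id,
                "pair_class": p.pair_class,
                "gap_bp": p.gap_bp,
                "utr_overlap_bp": p.utr_overlap_bp,
                "transcript_overlap_bp": p.transcript_overlap_bp,
            }
            for p in truth.pairs
        ]
    ).to_csv(pairs_path, sep="\t", index=False)
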