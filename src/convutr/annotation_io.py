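"""Gene-annotation I/O with a single internal coordinate convention.

Every coordinate inside the package is 0-based, half-open (``[start, end)``),
the convention BED already uses.  Only the I/O layer converts: GFF3 rows are
1-based closed and are shifted on read/write.  Keeping one convention
internally makes all downstream overlap arithmetic a plain interval
intersection with no off-by-one cases.

A gene here is its ORF's full genomic span; introns are ignored (the compact
yeast-like genomes this package targets are treated as contiguous ORFs).
Overlapping same-strand ORF annotations are retained — they can legitimately
form "consistent" pairs downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

try:  # gffutils carries the GFF3 attribute-string dialect handling
    from gffutils.feature import feature_from_line
except ImportError:  # pragma: no cover
    from gffutils import feature_from_line  # type: ignore

STRANDS = ("+", "-")

#: Column order of the pair table written by :func:`write_pairs`.
PAIR_TABLE_COLUMNS = (
    "gene_up",
    "gene_down",
    "chrom",
    "pair_class",
    "gap_bp",
    "utr_overlap_bp",
    "transcript_overlap_bp",
)


class AnnotationError(ValueError):
    """Any structural problem with an annotation or annotation file."""


class MalformedRecordError(AnnotationError):
    """A single unparseable/inconsistent record; message names the line."""


@dataclass(frozen=True)
class GeneRecord:
    """One ORF: identity, chromosome, strand and genomic span.

    ``orf_start``/``orf_end`` are 0-based half-open with
    ``orf_start < orf_end`` regardless of strand.  ``source_line`` records
    the 1-based line of the file the record came from (-1 when synthetic).
    """

    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    source_line: int = -1

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise MalformedRecordError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
                + (f" (line {self.source_line})" if self.source_line > 0 else "")
            )
        if not self.orf_start < self.orf_end:
            raise MalformedRecordError(
                f"gene {self.gene_id!r}: orf_start ({self.orf_start}) must be < "
                f"orf_end ({self.orf_end})"
                + (f" (line {self.source_line})" if self.source_line > 0 else "")
            )
        if self.orf_start < 0:
            raise MalformedRecordError(
                f"gene {self.gene_id!r}: negative start {self.orf_start}"
            )

    @property
    def stop_boundary(self) -> int:
        """Coordinate of the stop-codon-adjacent transcript boundary.

        The 3' end of the ORF: ``orf_end`` on '+', ``orf_start`` on '-'.
        Strand-symmetric by construction.
        """
        return self.orf_end if self.strand == "+" else self.orf_start

    @property
    def start_boundary(self) -> int:
        """Coordinate of the start-codon-adjacent (5') boundary."""
        return self.orf_start if self.strand == "+" else self.orf_end

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start


class Annotation:
    """A set of genes grouped per chromosome, sorted by ``orf_start``.

    Gene ids are unique.  ``chrom_lengths`` may be supplied (e.g. from GFF
    ``##sequence-region`` pragmas); when absent each chromosome's length is
    inferred as the rightmost ORF end plus a margin so UTR extension has room.
    """

    #: margin added to the rightmost ORF end when inferring chromosome length
    INFER_MARGIN = 1000

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ) -> None:
        by_chrom: Dict[str, List[GeneRecord]] = {}
        seen: Dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene id {g.gene_id!r}")
            seen[g.gene_id] = g
            by_chrom.setdefault(g.chrom, []).append(g)
        for lst in by_chrom.values():
            lst.sort(key=lambda g: (g.orf_start, g.orf_end, g.gene_id))
        self._by_chrom = by_chrom
        self._by_id = seen
        if chrom_lengths is None:
            self.chrom_lengths = {
                c: (max(g.orf_end for g in lst) + self.INFER_MARGIN)
                for c, lst in by_chrom.items()
            }
        else:
            self.chrom_lengths = dict(chrom_lengths)
            for c, lst in by_chrom.items():
                if c not in self.chrom_lengths:
                    raise AnnotationError(f"no length for chromosome {c!r}")
                L = self.chrom_lengths[c]
                for g in lst:
                    if g.orf_end > L:
                        raise AnnotationError(
                            f"gene {g.gene_id!r} extends past end of {c} ({L})"
                        )

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    @property
    def n_genes(self) -> int:
        return len(self._by_id)

    def genes_on(self, chrom: str) -> List[GeneRecord]:
        return list(self._by_chrom.get(chrom, []))

    def all_genes(self) -> List[GeneRecord]:
        out: List[GeneRecord] = []
        for c in self.chroms:
            out.extend(self._by_chrom[c])
        return out

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return self.n_genes


def read_gff(
    path: str | Path,
    feature_types: Sequence[str] = ("gene", "CDS"),
    id_attribute: str = "ID",
) -> Annotation:
    """Read a GFF3 annotation into the internal 0-based half-open convention.

    Rows whose feature type is in ``feature_types`` become genes; the gene id
    is taken from ``id_attribute``.  GFF's 1-based closed ``[start, end]``
    becomes ``[start-1, end)``.  ``##sequence-region`` pragmas, when present,
    provide chromosome lengths.
    """
    wanted = set(feature_types)
    genes: List[GeneRecord] = []
    chrom_lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    # pragma gives 1-based closed [1, length]
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise MalformedRecordError(
                    f"line {lineno}: expected 9 tab-separated GFF columns, "
                    f"got {len(fields)}"
                )
            if fields[2] not in wanted:
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise MalformedRecordError(f"line {lineno}: {exc}") from exc
            if feat.end < feat.start:
                raise MalformedRecordError(
                    f"line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            ids = feat.attributes.get(id_attribute, [])
            if not ids:
                raise MalformedRecordError(
                    f"line {lineno}: missing {id_attribute!r} attribute"
                )
            genes.append(
                GeneRecord(
                    gene_id=ids[0],
                    chrom=feat.seqid,
                    strand=feat.strand,
                    orf_start=feat.start - 1,
                    orf_end=feat.end,
                    source_line=lineno,
                )
            )
    return Annotation(genes, chrom_lengths or None)


def read_bed(path: str | Path) -> Annotation:
    """Read a BED6 annotation (already 0-based half-open)."""
    genes: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise MalformedRecordError(
                    f"line {lineno}: BED6 requires >= 6 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(
                GeneRecord(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    orf_start=int(start),
                    orf_end=int(end),
                    source_line=lineno,
                )
            )
    return Annotation(genes)


def _pair_to_row(pair) -> dict:
    """Duck-typed GenePair -> pair-table row (avoids a circular import)."""
    return {
        "gene_up": pair.up.gene.gene_id,
        "gene_down": pair.down.gene.gene_id,
        "chrom": pair.up.gene.chrom,
        "pair_class": pair.pair_class,
        "gap_bp": pair.gap_bp,
        "utr_overlap_bp": pair.utr_overlap_bp,
        "transcript_overlap_bp": pair.transcript_overlap_bp,
    }


def write_pairs(pairs: Sequence, path: str | Path) -> None:
    """Write gene pairs as a TSV table (header always present).

    Accepts ``GenePair`` objects or anything exposing the same attributes;
    the written table round-trips losslessly through :func:`read_pairs`.
    """
    df = pd.DataFrame(
        [_pair_to_row(p) for p in pairs], columns=list(PAIR_TABLE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a pair table written by :func:`write_pairs`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "gene_up": str,
            "gene_down": str,
            "chrom": str,
            "pair_class": str,
        },
    )
    missing = set(PAIR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"pair table missing columns: {sorted(missing)}")
    for col in ("gap_bp", "utr_overlap_bp", "transcript_overlap_bp"):
        df[col] = df[col].astype(int)
    return df[list(PAIR_TABLE_COLUMNS)]
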