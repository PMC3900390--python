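"""Shared fixtures and genome-manipulation helpers for the test suite."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from convutr import (
    Annotation,
    CoverageTrack,
    GeneRecord,
    TranscriptModel,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_gene(
    gene_id: str,
    strand: str,
    orf_start: int,
    orf_end: int,
    chrom: str = "chrI",
) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        orf_start=orf_start,
        orf_end=orf_end,
    )


def convergent_models(
    utr3_up: int,
    utr3_down: int,
    gap: int,
    orf_len: int = 1000,
    offset: int = 2000,
    chrom: str = "chrI",
) -> Tuple[TranscriptModel, TranscriptModel]:
    """Two facing transcript models: '+' gene, then '-' gene ``gap`` bp away."""
    up_gene = make_gene("up", "+", offset, offset + orf_len, chrom)
    down_start = offset + orf_len + gap
    down_gene = make_gene("down", "-", down_start, down_start + orf_len, chrom)
    up = TranscriptModel(gene=up_gene, utr5_len=50, utr3_len=utr3_up)
    down = TranscriptModel(gene=down_gene, utr5_len=50, utr3_len=utr3_down)
    return up, down


def mirror_genome(
    annot: Annotation, cov: CoverageTrack
) -> Tuple[Annotation, CoverageTrack]:
    """Reverse-complement the whole genome: flip coordinates, swap strands.

    Position ``x`` maps to ``L - 1 - x``; interval ``[s, e)`` to
    ``[L - e, L - s)``; '+' coverage becomes reversed '-' coverage.  Called
    UTR lengths and pair classes must be invariant under this map.
    """
    lengths = annot.chrom_lengths
    flipped = [
        GeneRecord(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand="-" if g.strand == "+" else "+",
            orf_start=lengths[g.chrom] - g.orf_end,
            orf_end=lengths[g.chrom] - g.orf_start,
        )
        for g in annot.all_genes()
    ]
    m_annot = Annotation(flipped, chrom_lengths=lengths)
    m_arrays: Dict[Tuple[str, str], np.ndarray] = {}
    for (chrom, strand), arr in cov.items():
        m_arrays[(chrom, "-" if strand == "+" else "+")] = arr[::-1].copy()
    return m_annot, CoverageTrack(m_arrays)


@pytest.fixture
def uniform_coverage():
    """Factory: a one-chromosome CoverageTrack built from explicit arrays."""

    def build(
        plus: np.ndarray | list,
        minus: np.ndarray | list | None = None,
        chrom: str = "chrI",
    ) -> CoverageTrack:
        plus = np.asarray(plus, dtype=float)
        minus = (
            np.zeros_like(plus)
            if minus is None
            else np.asarray(minus, dtype=float)
        )
        return CoverageTrack({(chrom, "+"): plus, (chrom, "-"): minus})

    return build
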