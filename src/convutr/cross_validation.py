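"""Confirmation of reference convergent pairs in a second dataset.

A convergent pair predicted from one transcriptome dataset (e.g. mRNA-Seq)
can be checked against an orthogonal one (nascent-transcript NET-Seq or
strand-specific ssRNA-Seq): UTRs are re-called from the second dataset's
coverage, pairs re-classified, and each reference pair assigned one of
three mutually exclusive statuses:

* ``partner_unexpressed`` — at least one of the two genes falls below the
  expression gate (mean ORF coverage < ``expr_min_mean_cov``) in the second
  dataset, so the pair cannot be assessed there;
* ``confirmed`` — both genes expressed and the pair is again classified as
  convergent with overlapping 3'-UTRs (>= 1 bp);
* ``not_confirmed`` — both genes expressed but the re-called UTRs no longer
  overlap.

The unexpressed gate takes precedence: a pair is only "not confirmed" when
both genes are actually expressed in the second dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .annotation_io import Annotation
from .pair_classifier import GenePair, classify_adjacent_pairs
from .utr_caller import CoverageTrack, UtrCallParams, call_all, mean_orf_coverage

VALIDATION_STATUSES = ("confirmed", "partner_unexpressed", "not_confirmed")


class ValidationError(ValueError):
    """Inputs unusable for cross-dataset validation."""


@dataclass(frozen=True)
class ValidationRecord:
    up_id: str
    down_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in VALIDATION_STATUSES:
            raise ValueError(f"unknown validation status {self.status!r}")


@dataclass(frozen=True)
class ValidationSummary:
    n_total: int
    n_confirmed: int
    n_partner_unexpressed: int
    n_not_confirmed: int
    pct_confirmed: float
    pct_partner_unexpressed: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "n_total": self.n_total,
            "n_confirmed": self.n_confirmed,
            "n_partner_unexpressed": self.n_partner_unexpressed,
            "n_not_confirmed": self.n_not_confirmed,
            "pct_confirmed": self.pct_confirmed,
            "pct_partner_unexpressed": self.pct_partner_unexpressed,
        }


def _ids(pair) -> Tuple[str, str]:
    """A reference pair is a GenePair or a plain (up_id, down_id) tuple."""
    if isinstance(pair, tuple):
        return pair
    return pair.gene_ids


def validate_pairs(
    ref_pairs: Sequence,
    other_annot: Annotation,
    other_cov: CoverageTrack,
    params: UtrCallParams = UtrCallParams(),
) -> List[ValidationRecord]:
    """Assign each reference pair a status in the second dataset.

    The full caller + classifier is re-run on the second dataset (rather
    than comparing pre-made pair lists) so that the confirmation criterion
    uses exactly the same thresholds as the original prediction.
    ``ref_pairs`` may be ``GenePair`` objects or ``(up_id, down_id)`` tuples.
    """
    missing = sorted(
        {
            gid
            for p in ref_pairs
            for gid in _ids(p)
            if gid not in other_annot
        }
    )
    if missing:
        raise ValidationError(
            f"genes absent from the validation annotation: {missing}"
        )
    models = call_all(other_annot, other_cov, params)
    other_pairs = classify_adjacent_pairs(models)
    convergent_sets = {
        frozenset(p.gene_ids)
        for p in other_pairs
        if p.pair_class == "convergent" and p.utr_overlap_bp >= 1
    }
    records: List[ValidationRecord] = []
    for pair in ref_pairs:
        up_id, down_id = _ids(pair)
        up_cov = mean_orf_coverage(other_annot[up_id], other_cov)
        down_cov = mean_orf_coverage(other_annot[down_id], other_cov)
        if up_cov < params.expr_min_mean_cov or down_cov < params.expr_min_mean_cov:
            status = "partner_unexpressed"
        elif frozenset((up_id, down_id)) in convergent_sets:
            status = "confirmed"
        else:
            status = "not_confirmed"
        records.append(ValidationRecord(up_id=up_id, down_id=down_id, status=status))
    return records


def summarize_validation(
    records: Sequence[ValidationRecord],
) -> ValidationSummary:
    """Counts and one-decimal percentages over the three statuses."""
    if not records:
        raise ValidationError("cannot summarize an empty validation record list")
    n_total = len(records)
    n_conf = sum(1 for r in records if r.status == "confirmed")
    n_unexpr = sum(1 for r in records if r.status == "partner_unexpressed")
    n_not = sum(1 for r in records if r.status == "not_confirmed")
    return ValidationSummary(
        n_total=n_total,
        n_confirmed=n_conf,
        n_partner_unexpressed=n_unexpr,
        n_not_confirmed=n_not,
        pct_confirmed=round(100.0 * n_conf / n_total, 1),
        pct_partner_unexpressed=round(100.0 * n_unexpr / n_total, 1),
    )


def write_validation_records(
    records: Sequence[ValidationRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"gene_up": r.up_id, "gene_down": r.down_id, "status": r.status}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
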