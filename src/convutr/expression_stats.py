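"""Correlation and relative-expression statistics for gene pairs.

The central question for a convergent pair is whether the two genes
anti-regulate each other: across conditions (or across single cells) the
log2 expression of one partner should fall as the other's rises, giving a
negative Pearson correlation over pairs.  Significance is assessed two
ways: the analytic two-sided p-value from the t transform of r, and a
one-sided permutation p-value obtained by shuffling the downstream partners
across pairs, which preserves each gene's marginal distribution while
breaking the pairing.  Both are reported because the directional hypothesis
(anti-correlation) naturally calls for a one-sided test while published
correlation tables conventionally print two-sided p-values.

Also here: the correlation of UTR length with expression level, the
two-gene single-cell correlation, and the 2^-ddCt fold-ratio used for
relative qPCR quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .utr_caller import TranscriptModel

#: a pair for correlation purposes: a GenePair or a plain (up_id, down_id)
PairLike = Union[Tuple[str, str], "object"]


class ExpressionStatsError(ValueError):
    """Degenerate or insufficient expression data."""


class ExpressionMatrix:
    """log2 expression values, genes x samples.

    ``scale`` declares the input scale; linear-scale values are converted to
    ``log2(value + 1)`` (pseudocount 1) at construction so that all analysis
    runs on the log2 scale.  Gene ids must be unique and values finite.
    """

    def __init__(self, values: pd.DataFrame, scale: str = "log2") -> None:
        if scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")
        df = values.astype(float)
        if scale == "linear":
            if (df.values < 0).any():
                raise ExpressionStatsError(
                    "linear-scale expression values must be >= 0"
                )
            df = np.log2(df + 1.0)
        if not np.isfinite(df.values).all():
            raise ExpressionStatsError("expression values must be finite")
        df.index.name = None
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ExpressionStatsError(f"duplicate gene ids: {dupes}")
        self._df = df
        self.scale = "log2"

    @property
    def gene_ids(self) -> List[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self._df.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self._df[sample_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._df.index

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str = "log2") -> "ExpressionMatrix":
        """Read a TSV with gene ids in the first column, samples in the header."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, scale=scale)

    def write_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class PairCorrelationResult:
    """Pearson anti-correlation of pair partners in one sample/condition."""

    sample_id: str
    n_pairs: int
    r: float
    p_analytic: float
    p_perm: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "sample_id": self.sample_id,
            "n_pairs": self.n_pairs,
            "r": self.r,
            "p_analytic": self.p_analytic,
            "p_perm": self.p_perm,
        }


@dataclass(frozen=True)
class LengthExpressionResult:
    n_genes: int
    r: float
    p_analytic: float


class MultiConditionResult(NamedTuple):
    results: List[PairCorrelationResult]
    r_min: float
    r_max: float


def _pair_ids(pair: PairLike) -> Tuple[str, str]:
    """Accepts (up_id, down_id) tuples, GenePair or TruePair objects."""
    if isinstance(pair, tuple):
        return pair
    if hasattr(pair, "gene_ids"):
        return pair.gene_ids  # type: ignore[attr-defined]
    return (pair.up_id, pair.down_id)  # type: ignore[attr-defined]


def _pearson(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pair_correlation(
    pairs: Sequence[PairLike],
    expr: ExpressionMatrix,
    sample_id: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PairCorrelationResult:
    """Pearson correlation between pair partners in one condition.

    Pairs with either gene absent from the matrix are dropped (``n_pairs``
    reflects what was used).  The permutation null shuffles the downstream
    partner values across pairs ``n_perm`` times; ``p_perm`` is the
    one-sided (toward anti-correlation) fraction of shuffles with
    ``r_perm <= r_obs``, smoothed as ``(1 + count) / (n_perm + 1)``.
    """
    col = expr.column(sample_id)
    xs, ys = [], []
    for pair in pairs:
        up_id, down_id = _pair_ids(pair)
        if up_id in expr and down_id in expr:
            xs.append(col.loc[up_id])
            ys.append(col.loc[down_id])
    n = len(xs)
    if n < 3:
        raise ExpressionStatsError(
            f"need >= 3 usable pairs in sample {sample_id!r}, got {n}"
        )
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(x) == 0:
        raise ExpressionStatsError(
            f"upstream expression values are constant in sample {sample_id!r}"
        )
    if np.ptp(y) == 0:
        raise ExpressionStatsError(
            f"downstream expression values are constant in sample {sample_id!r}"
        )
    r_obs, p_analytic = _pearson(x, y)

    rng = np.random.default_rng(seed)
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    perms = rng.permuted(np.tile(yz, (n_perm, 1)), axis=1)
    r_perm = perms @ xz / n
    p_perm = (1.0 + int(np.sum(r_perm <= r_obs))) / (n_perm + 1.0)
    return PairCorrelationResult(
        sample_id=sample_id,
        n_pairs=n,
        r=r_obs,
        p_analytic=p_analytic,
        p_perm=float(p_perm),
    )


def correlate_all_conditions(
    pairs: Sequence[PairLike],
    expr: ExpressionMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MultiConditionResult:
    """Run :func:`pair_correlation` for every sample column.

    Each condition gets its own permutation stream derived from ``seed``.
    No multiple-testing correction is applied across conditions; the
    per-condition p-values are reported raw.
    """
    results = []
    for i, sample_id in enumerate(expr.sample_ids):
        sub_seed = (seed * 100_003 + i) % (2**31 - 1)
        results.append(
            pair_correlation(pairs, expr, sample_id, n_perm=n_perm, seed=sub_seed)
        )
    rs = [res.r for res in results]
    return MultiConditionResult(results=results, r_min=min(rs), r_max=max(rs))


def utr_length_expression_correlation(
    models: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    sample_id: str,
    utr_side: str = "3",
) -> LengthExpressionResult:
    """Pearson correlation between UTR length and log2 expression level.

    Uses genes with a called UTR (length >= 1) on ``utr_side`` ('5' or '3')
    and an expression value in ``sample_id``.
    """
    if utr_side not in ("5", "3"):
        raise ValueError("utr_side must be '5' or '3'")
    col = expr.column(sample_id)
    lens, vals = [], []
    for m in models:
        L = m.utr5_len if utr_side == "5" else m.utr3_len
        if L >= 1 and m.gene.gene_id in expr:
            lens.append(L)
            vals.append(col.loc[m.gene.gene_id])
    n = len(lens)
    if n < 3:
        raise ExpressionStatsError(
            f"need >= 3 genes with a {utr_side}'-UTR and expression, got {n}"
        )
    x = np.asarray(lens, dtype=float)
    y = np.asarray(vals, dtype=float)
    if np.ptp(x) == 0:
        raise ExpressionStatsError("all UTR lengths are equal (degenerate)")
    if np.ptp(y) == 0:
        raise ExpressionStatsError("all expression values are equal (degenerate)")
    r, p = _pearson(x, y)
    return LengthExpressionResult(n_genes=n, r=r, p_analytic=p)


def single_cell_pair_correlation(
    cell_expr: ExpressionMatrix,
) -> Tuple[float, float]:
    """Pearson correlation of a two-gene expression profile across cells.

    ``cell_expr`` must hold exactly two genes (rows) over >= 3 cells
    (columns); values are on the log2 scale (linear input is log2(v+1)
    transformed at matrix construction).  Returns ``(r, p_analytic)``.
    """
    if len(cell_expr.gene_ids) != 2:
        raise ExpressionStatsError(
            f"expected exactly 2 genes, got {len(cell_expr.gene_ids)}"
        )
    n_cells = len(cell_expr.sample_ids)
    if n_cells < 3:
        raise ExpressionStatsError(f"need >= 3 cells, got {n_cells}")
    x = cell_expr.values.iloc[0].to_numpy(dtype=float)
    y = cell_expr.values.iloc[1].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ExpressionStatsError(
            f"gene {cell_expr.gene_ids[0]!r} is constant across cells"
        )
    if np.ptp(y) == 0:
        raise ExpressionStatsError(
            f"gene {cell_expr.gene_ids[1]!r} is constant across cells"
        )
    return _pearson(x, y)


def relative_expression_ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression fold ratio by the ddCt method.

    ``2 ** -((Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl))``:
    each condition's target Ct is normalized against a reference gene, and
    the test condition is expressed relative to the control.  A higher Ct
    means later amplification, i.e. lower abundance, hence the negative
    exponent.
    """
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ExpressionStatsError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def write_correlation_results(
    results: Sequence[PairCorrelationResult], path: str | Path
) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t", index=False)
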