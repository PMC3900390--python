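"""Correlation statistics: Pearson oracle, permutation null, ddCt, recovery."""

import numpy as np
import pandas as pd
import pytest

from convutr import (
    ExpressionMatrix,
    ExpressionStatsError,
    TranscriptModel,
    correlate_all_conditions,
    generate_expression,
    generate_single_cell,
    pair_correlation,
    relative_expression_ddct,
    single_cell_pair_correlation,
    utr_length_expression_correlation,
)
from convutr.synthetic_data import TruePair

from conftest import make_gene


def matrix(values, genes, samples, scale="log2"):
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )


def simple_pairs(n):
    return [(f"u{i}", f"d{i}") for i in range(n)]


def paired_matrix(x, y, sample="s1"):
    """One-condition matrix where pair i is (u_i, d_i) = (x[i], y[i])."""
    genes = [g for i in range(len(x)) for g in (f"u{i}", f"d{i}")]
    vals = [v for xy in zip(x, y) for v in xy]
    return matrix(np.array(vals)[:, None], genes, [sample])


class TestPairCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.linspace(1, 8, 10)
        expr = paired_matrix(x, -x)
        res = pair_correlation(simple_pairs(10), expr, "s1", n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.n_pairs == 10

    def test_fewer_than_three_pairs_rejected(self):
        expr = paired_matrix([1, 2], [2, 1])
        with pytest.raises(ExpressionStatsError, match=">= 3"):
            pair_correlation(simple_pairs(2), expr, "s1", n_perm=9, seed=0)

    def test_constant_side_named_in_error(self):
        expr = paired_matrix([5, 5, 5], [1, 2, 3])
        with pytest.raises(ExpressionStatsError, match="upstream"):
            pair_correlation(simple_pairs(3), expr, "s1", n_perm=9, seed=0)
        expr = paired_matrix([1, 2, 3], [4, 4, 4])
        with pytest.raises(ExpressionStatsError, match="downstream"):
            pair_correlation(simple_pairs(3), expr, "s1", n_perm=9, seed=0)

    def test_pairs_with_missing_genes_are_dropped(self):
        expr = paired_matrix([1, 2, 3, 4], [4, 3, 2, 1])
        pairs = simple_pairs(4) + [("absent", "d0")]
        res = pair_correlation(pairs, expr, "s1", n_perm=9, seed=0)
        assert res.n_pairs == 4

    def test_pearson_agrees_with_covariance_oracle(self):
        """r equals cov(x,y)/(sd_x sd_y) computed directly, to 1e-12."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = 0.3 * x + rng.normal(size=200)
        expr = paired_matrix(x, y)
        res = pair_correlation(simple_pairs(200), expr, "s1", n_perm=9, seed=0)
        oracle = float(
            np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        )
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_fixed_seed_gives_bit_identical_p_perm(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        expr = paired_matrix(x, y)
        r1 = pair_correlation(simple_pairs(50), expr, "s1", n_perm=500, seed=9)
        r2 = pair_correlation(simple_pairs(50), expr, "s1", n_perm=500, seed=9)
        assert r1.p_perm == r2.p_perm

    def test_swapping_up_down_labels_is_invariant(self):
        """r and the analytic p are exactly label-symmetric; the permutation
        p differs only by Monte-Carlo error (the shuffled side changes)."""
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=120), rng.normal(size=120)
        expr = paired_matrix(x, y)
        pairs = simple_pairs(120)
        swapped = [(d, u) for u, d in pairs]
        a = pair_correlation(pairs, expr, "s1", n_perm=4000, seed=3)
        b = pair_correlation(swapped, expr, "s1", n_perm=4000, seed=3)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p_analytic == pytest.approx(b.p_analytic, abs=1e-12)
        assert a.p_perm == pytest.approx(b.p_perm, abs=0.05)

    def test_planted_anticorrelation_recovered_across_seeds(self):
        """645 pairs planted at r = -0.14: estimate within +/-0.08 for >=18/20 seeds."""
        pairs = [TruePair(f"u{i}", f"d{i}", "convergent", 1, 1, 1) for i in range(645)]
        hits = 0
        for seed in range(20):
            expr = generate_expression(pairs, r_target=-0.14, n_conditions=1, seed=seed)
            res = pair_correlation(pairs, expr, "cond_1", n_perm=99, seed=seed)
            hits += abs(res.r - (-0.14)) <= 0.08
        assert hits >= 18

    def test_null_permutation_p_is_calibrated(self):
        """Independent partners: mean permutation p over 200 reps near 0.5."""
        pairs = [TruePair(f"u{i}", f"d{i}", "convergent", 1, 1, 1) for i in range(100)]
        expr = generate_expression(pairs, r_target=0.0, n_conditions=200, seed=17)
        ps = [
            pair_correlation(pairs, expr, f"cond_{i + 1}", n_perm=199, seed=i).p_perm
            for i in range(200)
        ]
        assert 0.45 <= float(np.mean(ps)) <= 0.55


class TestCorrelateAllConditions:
    def test_seven_conditions_recover_planted_r(self):
        pairs = [TruePair(f"u{i}", f"d{i}", "convergent", 1, 1, 1) for i in range(645)]
        expr = generate_expression(pairs, r_target=-0.14, n_conditions=7, seed=10)
        multi = correlate_all_conditions(pairs, expr, n_perm=199, seed=10)
        assert len(multi.results) == 7
        for res in multi.results:
            assert abs(res.r - (-0.14)) <= 0.08
        assert multi.r_min <= multi.r_max

    def test_single_condition(self):
        pairs = [TruePair(f"u{i}", f"d{i}", "convergent", 1, 1, 1) for i in range(10)]
        expr = generate_expression(pairs, r_target=-0.5, n_conditions=1, seed=4)
        multi = correlate_all_conditions(pairs, expr, n_perm=99, seed=4)
        assert len(multi.results) == 1
        assert multi.r_min == multi.r_max == multi.results[0].r


class TestUtrLengthExpressionCorrelation:
    def _models(self, lengths):
        models = []
        pos = 1000
        for i, L in enumerate(lengths):
            g = make_gene(f"g{i}", "+", pos, pos + 500)
            models.append(TranscriptModel(g, utr5_len=0, utr3_len=int(L)))
            pos += 2000
        return models

    def test_equal_lengths_degenerate(self):
        models = self._models([50, 50, 50, 50])
        expr = matrix(
            np.arange(4, dtype=float)[:, None], [f"g{i}" for i in range(4)], ["s1"]
        )
        with pytest.raises(ExpressionStatsError, match="degenerate"):
            utr_length_expression_correlation(models, expr, "s1", utr_side="3")

    def test_planted_negative_dependence_detected(self):
        rng = np.random.default_rng(0)
        n = 2000
        expr_vals = rng.normal(8, 2, size=n)
        lengths = np.clip(
            np.round(150 - 8 * expr_vals + rng.normal(0, 40, size=n)), 1, None
        )
        models = self._models(lengths)
        expr = matrix(expr_vals[:, None], [f"g{i}" for i in range(n)], ["s1"])
        res = utr_length_expression_correlation(models, expr, "s1", utr_side="3")
        assert res.r < 0
        assert res.p_analytic < 0.05
        assert res.n_genes == n

    def test_independent_lengths_give_near_zero_r(self):
        rng = np.random.default_rng(1)
        n = 2000
        rs = []
        for _ in range(100):
            lengths = rng.integers(9, 212, size=n)
            expr_vals = rng.normal(8, 2, size=n)
            models = self._models(lengths)
            expr = matrix(expr_vals[:, None], [f"g{i}" for i in range(n)], ["s1"])
            rs.append(
                utr_length_expression_correlation(models, expr, "s1", "3").r
            )
        assert abs(float(np.mean(rs))) < 0.05


class TestSingleCell:
    def test_perfect_anticorrelation(self):
        vals = np.array([[1.0, 2, 3, 4, 5], [5.0, 4, 3, 2, 1]])
        expr = matrix(vals, ["a", "b"], [f"c{i}" for i in range(5)])
        r, _ = single_cell_pair_correlation(expr)
        assert r == pytest.approx(-1.0)

    def test_two_cells_rejected(self):
        expr = matrix(np.array([[1.0, 2], [2.0, 1]]), ["a", "b"], ["c1", "c2"])
        with pytest.raises(ExpressionStatsError, match="cells"):
            single_cell_pair_correlation(expr)

    def test_linear_scale_is_log_transformed_with_pseudocount(self):
        vals = np.array([[0.0, 1, 3], [3.0, 1, 0]])
        expr = matrix(vals, ["a", "b"], ["c1", "c2", "c3"], scale="linear")
        assert expr.values.iloc[0, 0] == pytest.approx(0.0)  # log2(0+1)
        assert expr.values.iloc[0, 2] == pytest.approx(2.0)  # log2(3+1)

    def test_planted_correlation_recovered_in_mean_over_seeds(self):
        rs = [
            single_cell_pair_correlation(
                generate_single_cell(-0.38, 1000, seed=seed)
            )[0]
            for seed in range(20)
        ]
        assert abs(float(np.mean(rs)) - (-0.38)) <= 0.05


class TestRelativeExpressionDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 20, 20, 20), 1.0),  # ddCt = 0
            ((21, 20, 20, 20), 0.5),  # ddCt = 1
            ((18, 20, 20, 20), 4.0),  # ddCt = -2
        ],
    )
    def test_fold_ratio(self, cts, expected):
        assert relative_expression_ddct(*cts) == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ExpressionStatsError, match="non-finite"):
            relative_expression_ddct(float("nan"), 20, 20, 20)


class TestExpressionMatrix:
    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["g", "g"], columns=["s1"])
        with pytest.raises(ExpressionStatsError, match="duplicate"):
            ExpressionMatrix(df)

    def test_non_finite_rejected(self):
        df = pd.DataFrame([[np.inf]], index=["g"], columns=["s1"])
        with pytest.raises(ExpressionStatsError, match="finite"):
            ExpressionMatrix(df)

    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.5, 2.5], [3.5, 4.5]], index=["a", "b"], columns=["s1", "s2"]
        )
        m = ExpressionMatrix(df)
        m.write_tsv(tmp_path / "e.tsv")
        back = ExpressionMatrix.read_tsv(tmp_path / "e.tsv")
        pd.testing.assert_frame_equal(back.values, m.values)
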