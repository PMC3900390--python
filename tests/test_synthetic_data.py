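"""Synthetic-data generators: determinism, truth consistency, recovery."""

import numpy as np
import pandas as pd
import pytest

from convutr import (
    Annotation,
    call_all,
    classify_adjacent_pairs,
    compute_transcript_overlap,
    generate_coverage,
    generate_expression,
    generate_genome,
    generate_single_cell,
    mean_orf_coverage,
    pair_correlation,
    single_cell_pair_correlation,
)
from convutr.expression_stats import ExpressionStatsError
from convutr.synthetic_data import (
    GenomeSimConfig,
    SimConfigError,
    TrueGene,
    TruthTable,
    read_truth_table,
    write_genome_gff,
    write_truth_table,
)


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = GenomeSimConfig(n_convergent=10, n_divergent=3, n_isolated=5, seed=4)
        for run in ("a", "b"):
            annot, truth = generate_genome(cfg)
            write_genome_gff(annot, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_no_motifs_only_isolated_genes_emit_no_pairs(self):
        annot, truth = generate_genome(GenomeSimConfig(n_isolated=10, seed=1))
        cov = generate_coverage(annot, truth, depth=10)
        assert classify_adjacent_pairs(call_all(annot, cov)) == []
        assert truth.pairs == []

    def test_truth_overlaps_consistent_with_formula(self):
        cfg = GenomeSimConfig(n_convergent=50, seed=9)
        _, truth = generate_genome(cfg)
        for p in truth.pairs_of_class("convergent"):
            up = truth.gene(p.up_id)
            dn = truth.gene(p.down_id)
            assert p.transcript_overlap_bp == compute_transcript_overlap(
                up.utr3_len, dn.utr3_len, p.gap_bp
            )
            assert 1 <= p.utr_overlap_bp <= p.transcript_overlap_bp

    def test_infeasible_chrom_length_rejected(self):
        cfg = GenomeSimConfig(n_convergent=100, n_chromosomes=1, chrom_length=5000)
        with pytest.raises(SimConfigError, match="chrom"):
            generate_genome(cfg)

    def test_orf_shorter_than_utr_bound_rejected(self):
        with pytest.raises(SimConfigError, match="orf_len_range"):
            GenomeSimConfig(n_convergent=1, orf_len_range=(100, 200))

    def test_truth_table_tsv_round_trip(self, tmp_path):
        cfg = GenomeSimConfig(n_convergent=5, n_divergent=2, seed=3)
        annot, truth = generate_genome(cfg)
        gp, pp = tmp_path / "genes.tsv", tmp_path / "pairs.tsv"
        write_truth_table(truth, gp, pp)
        back = read_truth_table(gp, pp)
        assert back.genes == truth.genes
        assert back.pairs == truth.pairs


class TestGenerateCoverage:
    def test_noiseless_full_pipeline_recovers_truth_exactly(self):
        """Genome -> coverage -> UTR caller -> classifier reproduces the
        truth table with zero discrepancies (convergent/divergent/isolated;
        same-strand pairs merge coverage runs and are covered separately)."""
        cfg = GenomeSimConfig(
            n_convergent=40, n_divergent=15, n_isolated=20, seed=21
        )
        annot, truth = generate_genome(cfg)
        cov = generate_coverage(annot, truth, depth=10)
        models = call_all(annot, cov)
        by_id = {m.gene.gene_id: m for m in models}
        for g in truth.genes:
            assert by_id[g.gene_id].utr5_len == g.utr5_len
            assert by_id[g.gene_id].utr3_len == g.utr3_len
        pairs = classify_adjacent_pairs(models)
        got = {
            p.gene_ids: (p.pair_class, p.gap_bp, p.utr_overlap_bp,
                         p.transcript_overlap_bp)
            for p in pairs
        }
        planted = {
            (t.up_id, t.down_id): (t.pair_class, t.gap_bp, t.utr_overlap_bp,
                                   t.transcript_overlap_bp)
            for t in truth.pairs
        }
        assert got == planted

    def test_consistent_pair_class_recovered_despite_merged_runs(self):
        cfg = GenomeSimConfig(n_consistent=25, seed=6)
        annot, truth = generate_genome(cfg)
        cov = generate_coverage(annot, truth, depth=10)
        pairs = classify_adjacent_pairs(call_all(annot, cov))
        got = {p.gene_ids: p.pair_class for p in pairs}
        planted = {(t.up_id, t.down_id): "consistent" for t in truth.pairs}
        assert got == planted

    def test_zero_depth_means_all_genes_unexpressed(self):
        cfg = GenomeSimConfig(n_convergent=5, seed=2)
        annot, truth = generate_genome(cfg)
        cov = generate_coverage(annot, truth, depth=0)
        assert all(
            mean_orf_coverage(g, cov) == 0.0 for g in annot.all_genes()
        )

    def test_same_seed_same_arrays(self):
        cfg = GenomeSimConfig(n_convergent=5, seed=2)
        annot, truth = generate_genome(cfg)
        a = generate_coverage(annot, truth, depth=7, noise_sd=1.0, seed=3)
        b = generate_coverage(annot, truth, depth=7, noise_sd=1.0, seed=3)
        for key, arr in a.items():
            np.testing.assert_array_equal(arr, b.get(*key))

    def test_table1_style_fixture_recovers_printed_overlaps(self):
        """Four convergent pairs with the published UTR lengths and derived
        gaps yield transcript overlaps 164, 157, 206, 29."""
        rows = [  # (utr3_up, utr3_down, gap, expected_overlap)
            (127, 178, 141, 164),
            (211, 180, 234, 157),
            (98, 206, 98, 206),
            (53, 9, 33, 29),
        ]
        genes, cursor, expected = [], 1000, {}
        for i, (u_up, u_dn, gap, ov) in enumerate(rows):
            up = TrueGene(f"up{i}", "chrI", "+", cursor, cursor + 900, 60, u_up)
            dn_start = up.orf_end + gap
            dn = TrueGene(f"dn{i}", "chrI", "-", dn_start, dn_start + 900, 60, u_dn)
            genes += [up, dn]
            expected[(up.gene_id, dn.gene_id)] = ov
            cursor = dn.tx_end + 800
        truth = TruthTable(genes=genes)
        annot = Annotation(
            [g.to_record() for g in genes], chrom_lengths={"chrI": cursor + 800}
        )
        cov = generate_coverage(annot, truth, depth=10)
        pairs = classify_adjacent_pairs(call_all(annot, cov))
        got = {p.gene_ids: p.transcript_overlap_bp for p in pairs}
        assert got == expected


class TestGenerateExpression:
    def _pairs(self, n):
        from convutr.synthetic_data import TruePair

        return [TruePair(f"u{i}", f"d{i}", "convergent", 1, 1, 1) for i in range(n)]

    def test_perfect_anticorrelation_plant(self):
        pairs = self._pairs(20)
        expr = generate_expression(pairs, r_target=-1.0, n_conditions=1, seed=0)
        res = pair_correlation(pairs, expr, "cond_1", n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0, abs=1e-9)

    def test_null_plant_gives_near_zero_r(self):
        """r_target = 0 with 645 pairs: |r| < 0.08 for >= 18 of 20 seeds."""
        pairs = self._pairs(645)
        hits = 0
        for seed in range(20):
            expr = generate_expression(pairs, r_target=0.0, n_conditions=1, seed=seed)
            res = pair_correlation(pairs, expr, "cond_1", n_perm=9, seed=seed)
            hits += abs(res.r) < 0.08
        assert hits >= 18

    def test_extra_genes_are_included(self):
        pairs = self._pairs(3)
        expr = generate_expression(
            pairs, r_target=0.0, n_conditions=2, seed=1, extra_gene_ids=["solo"]
        )
        assert "solo" in expr

    def test_invalid_r_target_rejected(self):
        with pytest.raises(SimConfigError, match="r_target"):
            generate_expression(self._pairs(2), r_target=1.5, seed=0)


class TestGenerateSingleCell:
    def test_same_seed_identical_matrix(self):
        a = generate_single_cell(-0.38, 100, seed=5)
        b = generate_single_cell(-0.38, 100, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_full_dropout_makes_correlation_degenerate(self):
        expr = generate_single_cell(-0.38, 50, dropout_p=1.0, seed=1)
        assert (expr.values.values == 0).all()
        with pytest.raises(ExpressionStatsError, match="constant"):
            single_cell_pair_correlation(expr)

    def test_dropout_probability_respected(self):
        expr = generate_single_cell(0.0, 4000, dropout_p=0.3, seed=2)
        frac = float((expr.values.values == 0).mean())
        assert abs(frac - 0.3) < 0.03
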