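"""Variant-to-gene preparation pipeline."""

import numpy as np
import pandas as pd
import pytest

import runner_burden as rb
from runner_burden.burden import filter_consequence
from runner_burden.exceptions import DomainError, SchemaError


class TestFilterRare:
    def test_common_removed_rare_kept(self, toy_records):
        out = rb.filter_rare(toy_records, 0.01)
        # the 4th record has panel AF 0.02 in both panels
        assert len(out) == 3
        assert 400 not in out["pos"].values

    def test_absent_from_reference_kept(self, toy_records):
        out = rb.filter_rare(toy_records, 0.01)
        assert 200 in out["pos"].values  # NaN AFs treated as 0

    def test_threshold_boundary(self):
        rec = pd.DataFrame({"gene_id": ["G"], "af_p1": [0.01]})
        assert len(rb.filter_rare(rec, 0.01)) == 1


class TestCaseEnrichment:
    @staticmethod
    def _rec(case_af, ctrl_af, an=1000):
        return pd.DataFrame({
            "gene_id": ["G"], "case_ac": [int(case_af * an)], "case_an": [an],
            "ctrl_ac": [int(ctrl_af * an)], "ctrl_an": [an],
        })

    def test_case_enriched_kept(self):
        assert len(rb.filter_case_enriched(self._rec(0.01, 0.001), 2)) == 1

    def test_control_enriched_removed(self):
        assert len(rb.filter_case_enriched(self._rec(0.001, 0.01), 2)) == 0

    def test_no_controls_identity(self):
        rec = pd.DataFrame({"gene_id": ["G"], "case_ac": [1], "case_an": [100]})
        out = rb.filter_case_enriched(rec, 2)
        assert out.equals(rec)

    def test_strict_mode(self):
        # equal frequencies survive the default reading but not the strict one
        rec = self._rec(0.005, 0.005)
        assert len(rb.filter_case_enriched(rec, 2)) == 1
        assert len(rb.filter_case_enriched(rec, 2, mode="require_case_enriched")) == 0


class TestWeights:
    def test_equal_weight_special_case(self):
        assert rb.score_to_weight(1.0, 1.0) == 1

    @pytest.mark.parametrize("s,b,w", [(0.5, 0.05, 10), (0.51, 0.05, 11),
                                       (0.2, 0.1, 2), (1.0, 0.05, 20)])
    def test_least_integer(self, s, b, w):
        assert rb.score_to_weight(s, b) == w

    def test_floor_at_one(self):
        assert rb.score_to_weight(0.0, 0.05) == 1

    def test_equal_weights_mode(self):
        w = rb.score_to_weight(np.array([0.1, 0.9]), 0.05, equal_weights=True)
        assert (w == 1).all()

    def test_score_out_of_range(self):
        with pytest.raises(DomainError):
            rb.score_to_weight(1.2, 0.1)


class TestImputation:
    def test_gene_mean(self):
        rec = pd.DataFrame({"gene_id": ["G1"] * 3,
                            "score": [0.2, np.nan, 0.4]})
        out = rb.impute_missing_scores(rec)
        assert out["score"].iloc[1] == pytest.approx(0.3)

    def test_unscored_gene_uses_global_mean(self):
        rec = pd.DataFrame({"gene_id": ["G1", "G1", "G2"],
                            "score": [np.nan, np.nan, 0.5]})
        out = rb.impute_missing_scores(rec)
        assert (out.loc[out.gene_id == "G1", "score"] == 0.5).all()

    def test_no_missing_identity(self):
        rec = pd.DataFrame({"gene_id": ["G1"], "score": [0.7]})
        assert rb.impute_missing_scores(rec).equals(rec)


class TestCounts:
    def test_weighted_sum(self):
        rec = pd.DataFrame({"gene_id": ["G", "G"], "case_ac": [1, 2],
                            "consequence": ["missense", "missense"]})
        out = rb.weighted_gene_counts(rec, [3, 1])
        assert out.loc["G", "y"] == 5
        assert out.loc["G", "y_raw"] == 3
        assert out.loc["G", "m"] == 2

    def test_equal_weights_equal_raw_tally(self):
        # 61 minor alleles at unit weight stay 61
        rec = pd.DataFrame({"gene_id": ["RET"] * 4, "case_ac": [20, 20, 20, 1],
                            "consequence": ["missense"] * 4})
        out = rb.weighted_gene_counts(rec, np.ones(4, dtype=int))
        assert out.loc["RET", "y"] == 61

    def test_consequence_split(self):
        rec = pd.DataFrame({"gene_id": ["G", "G"], "case_ac": [2, 3],
                            "consequence": ["missense", "frameshift"]})
        out = rb.weighted_gene_counts(rec, [1, 1])
        assert out.loc["G", "missense_alleles"] == 2
        assert out.loc["G", "lof_alleles"] == 3


class TestFrequencyScore:
    def test_no_variants_zero(self, toy_annotation):
        empty = pd.DataFrame({"gene_id": [], "af_p1": []})
        x2 = rb.frequency_score(empty, [])
        table = rb.assemble_predictors(toy_annotation, x2)
        assert (table["x2"] == 0).all()

    def test_weighted_accumulation(self):
        rec = pd.DataFrame({"gene_id": ["G", "G"], "af_p1": [0.001, 0.002]})
        x2 = rb.frequency_score(rec, [2, 1])
        assert x2["G"] == pytest.approx(0.004)

    def test_panels_averaged_then_weighted(self):
        rec = pd.DataFrame({"gene_id": ["G"], "af_p1": [0.002], "af_p2": [0.004]})
        assert rb.frequency_score(rec, [1])["G"] == pytest.approx(0.003)


class TestAssemble:
    def test_interaction_zero_when_no_variants(self, toy_annotation):
        x2 = pd.Series(dtype=float)
        table = rb.assemble_predictors(toy_annotation, x2)
        assert table.loc["GENE1", "x1"] == pytest.approx(3.477)
        assert table.loc["GENE1", "x3"] == 0.0

    def test_interaction_product(self, toy_annotation):
        x2 = pd.Series({"GENE2": 0.5})
        table = rb.assemble_predictors(toy_annotation, x2)
        assert table.loc["GENE2", "x3"] == pytest.approx(1.0)

    def test_missing_annotation_median_imputed_and_flagged(self, toy_annotation):
        table = rb.assemble_predictors(toy_annotation, pd.Series(dtype=float))
        assert table.loc["GENE2", "annotation_imputed"]
        assert table.loc["GENE2", "x4"] == pytest.approx(0.9)  # column median

    def test_missing_columns_raise(self):
        with pytest.raises(SchemaError):
            rb.assemble_predictors(pd.DataFrame({"gene_id": ["G"]}),
                                   pd.Series(dtype=float))


class TestPipeline:
    def test_interaction_invariant_everywhere(self, toy_records, toy_annotation):
        table = rb.prepare_burden_table(toy_records, toy_annotation,
                                        rb.WeightConfig(b=0.1, d=None))
        assert np.allclose(table["x3"], table["x1"] * table["x2"])

    def test_weighted_at_least_raw(self, small_variant_dataset):
        records, ann, _, _ = small_variant_dataset
        table = rb.prepare_burden_table(records, ann, rb.WeightConfig(b=0.05))
        assert (table["y"] >= table["y_raw"]).all()
        equal = rb.prepare_burden_table(records, ann,
                                        rb.WeightConfig(b=1.0, equal_weights=True))
        assert (equal["y"] == equal["y_raw"]).all()

    def test_filters_idempotent(self, small_variant_dataset):
        records, _, _, _ = small_variant_dataset
        cfg = rb.WeightConfig()
        once = rb.filter_case_enriched(
            rb.filter_rare(filter_consequence(records, cfg.consequences),
                           cfg.rare_af_max), cfg.d)
        once = rb.impute_missing_scores(once)
        twice = rb.filter_case_enriched(
            rb.filter_rare(filter_consequence(once, cfg.consequences),
                           cfg.rare_af_max), cfg.d)
        twice = rb.impute_missing_scores(twice)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_overlapping_genes_both_counted(self, toy_annotation):
        rec = pd.DataFrame({
            "chrom": ["chr1"] * 2, "pos": [100] * 2, "ref": ["A"] * 2,
            "alt": ["G"] * 2, "gene_id": ["GENE1", "GENE2"],
            "consequence": ["missense"] * 2, "score": [0.5] * 2,
            "case_ac": [2] * 2, "case_an": [100] * 2,
            "af_p1": [0.001] * 2,
        })
        table = rb.prepare_burden_table(rec, toy_annotation,
                                        rb.WeightConfig(b=1.0, d=None))
        assert table.loc["GENE1", "y_raw"] == 2
        assert table.loc["GENE2", "y_raw"] == 2

    def test_gene_without_variants_zero_row(self, toy_annotation):
        rec = pd.DataFrame({
            "chrom": ["chr1"], "pos": [100], "ref": ["A"], "alt": ["G"],
            "gene_id": ["GENE1"], "consequence": ["missense"], "score": [0.5],
            "case_ac": [2], "case_an": [100], "af_p1": [0.001],
        })
        table = rb.prepare_burden_table(rec, toy_annotation,
                                        rb.WeightConfig(b=1.0, d=None))
        assert table.loc["GENE2", "y"] == 0
        assert table.loc["GENE2", "m"] == 0
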