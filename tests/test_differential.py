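"""Fold change, Levene-gated t-tests, BH-FDR, and significance calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gcbmi
from gcbmi.differential import (
    EXPRESSION_DEFAULTS,
    DiffThresholds,
    annotate_significance,
    bh_fdr,
    call_significant,
    differential_table,
    fold_change,
    variance_gated_test,
)

from oracles import bh_stepup, pooled_t_p, welch_t_p


def _raw_matrix(tumor_rows, normal_rows, genes):
    rows = np.asarray(list(tumor_rows) + list(normal_rows), float)
    idx = [f"T{i}" for i in range(len(tumor_rows))] + [f"N{i}" for i in range(len(normal_rows))]
    labels = pd.Series(["tumor"] * len(tumor_rows) + ["normal"] * len(normal_rows), index=idx)
    return gcbmi.OmicsMatrix("expression", pd.DataFrame(rows, index=idx, columns=genes), labels)


class TestFoldChange:
    def test_ratio_of_class_means(self):
        m = _raw_matrix([[4.0], [4.0]], [[2.0], [2.0]], ["G"])
        fc = fold_change(m)
        assert fc.loc["G", "fc"] == 2.0
        assert fc.loc["G", "abs_fc"] == 2.0

    def test_reciprocal_convention_for_downregulation(self):
        m = _raw_matrix([[1.0], [1.0]], [[2.0], [2.0]], ["G"])
        fc = fold_change(m)
        assert fc.loc["G", "fc"] == 0.5
        assert fc.loc["G", "abs_fc"] == 2.0

    def test_equal_means_give_unit_fold_change(self):
        m = _raw_matrix([[3.0], [3.0]], [[3.0], [3.0]], ["G"])
        assert fold_change(m).loc["G", "abs_fc"] == 1.0

    def test_nonpositive_class_mean_flags_gene(self):
        m = _raw_matrix([[-1.0], [1.0]], [[2.0], [2.0]], ["G"])
        fc = fold_change(m)
        assert not fc.loc["G", "fc_defined"]
        assert np.isnan(fc.loc["G", "fc"])


class TestVarianceGatedTest:
    def test_identical_groups_give_p_one(self):
        _, _, p = variance_gated_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_pooled_branch_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        levene_p, variant, p = variance_gated_test(a, b)
        assert variant == "pooled"
        assert p == pytest.approx(0.28786, abs=1e-4)
        assert p == pytest.approx(pooled_t_p(a, b), abs=1e-12)

    def test_heteroscedastic_groups_route_to_welch(self):
        a = [0.0, 0.1, -0.1, 0.05]
        b = [5.0, -5.0, 10.0, -10.0]
        levene_p, variant, p = variance_gated_test(a, b)
        assert variant == "welch"
        assert p == pytest.approx(welch_t_p(a, b), abs=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            variance_gated_test([1.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pooled_equals_welch_for_equal_sizes_and_variances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = a[::-1] + rng.normal()  # same sample variance, shifted mean
        assert pooled_t_p(a, b) == pytest.approx(welch_t_p(a, b), abs=1e-12)
        _, _, p = variance_gated_test(a, b)  # either branch gives the same p here
        assert p == pytest.approx(pooled_t_p(a, b), abs=1e-9)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_stepup_worked_example(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12)

    def test_tied_p_values(self):
        assert bh_fdr([0.05, 0.05, 0.05]) == pytest.approx([0.05] * 3, abs=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 50))
    def test_matches_stepup_oracle_and_is_monotone(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        q = bh_fdr(p)
        assert q == pytest.approx(bh_stepup(p), abs=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()


class TestCallSignificant:
    @staticmethod
    def _records(rows):
        df = pd.DataFrame(rows).set_index("gene")
        df["fc_defined"] = df.get("fc_defined", True)
        return df

    def test_all_thresholds_met_included(self):
        rec = self._records([{"gene": "G", "abs_fc": 2.5, "p_value": 0.001, "q_value": 0.005}])
        assert call_significant(rec, EXPRESSION_DEFAULTS) == ["G"]

    def test_single_failed_criterion_excludes(self):
        rec = self._records([{"gene": "G", "abs_fc": 2.5, "p_value": 0.001, "q_value": 0.02}])
        assert call_significant(rec, EXPRESSION_DEFAULTS) == []

    def test_fc_undefined_gene_excluded(self):
        rec = self._records(
            [{"gene": "G", "abs_fc": np.nan, "p_value": 0.001, "q_value": 0.001,
              "fc_defined": False}]
        )
        assert call_significant(rec, EXPRESSION_DEFAULTS) == []

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        rec = self._records(
            [
                {"gene": f"G{i}", "abs_fc": 1 + 3 * rng.random(),
                 "p_value": rng.random() * 0.2, "q_value": rng.random() * 0.2}
                for i in range(20)
            ]
        )
        tight = DiffThresholds(2.0, 0.05, 0.01)
        loose = DiffThresholds(1.5, 0.1, 0.05)
        assert set(call_significant(rec, tight)) <= set(call_significant(rec, loose))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            DiffThresholds(0.0, 0.05, 0.01)
        with pytest.raises(ValueError):
            DiffThresholds(2.0, 1.5, 0.01)


class TestDifferentialTable:
    def test_batch_path_matches_scalar_gate_per_gene(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(40)]
        raw = _raw_matrix(
            np.exp(rng.normal(1, 1, size=(12, 40))), np.exp(rng.normal(0, 2, size=(15, 40))),
            genes,
        )
        params = gcbmi.fit_standardizer(raw)
        std = gcbmi.apply_standardizer(raw, params)
        table = differential_table(raw, std, std.gene_ids)
        tumor, normal = std.split_by_label()
        for g in std.gene_ids:
            lp, variant, p = variance_gated_test(tumor[g].to_numpy(), normal[g].to_numpy())
            assert table.loc[g, "levene_p"] == pytest.approx(lp, abs=1e-10)
            assert table.loc[g, "test_variant"] == variant
            assert table.loc[g, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_q_values_computed_over_tested_universe(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(10)]
        raw = _raw_matrix(
            np.exp(rng.normal(size=(6, 10))), np.exp(rng.normal(size=(6, 10))), genes
        )
        std = gcbmi.apply_standardizer(raw, gcbmi.fit_standardizer(raw))
        table = differential_table(raw, std, genes)
        assert table["q_value"].to_numpy() == pytest.approx(
            bh_stepup(table["p_value"].to_numpy()), abs=1e-12
        )

    def test_significant_column_consistent_with_call(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(15)]
        raw = _raw_matrix(
            np.exp(rng.normal(1.5, 0.3, size=(8, 15))), np.exp(rng.normal(0, 0.3, size=(8, 15))),
            genes,
        )
        std = gcbmi.apply_standardizer(raw, gcbmi.fit_standardizer(raw))
        table = annotate_significance(differential_table(raw, std, genes), EXPRESSION_DEFAULTS)
        assert sorted(table.index[table["significant"]]) == call_significant(
            table, EXPRESSION_DEFAULTS
        )


class TestPlantedRecovery:
    def test_sensitivity_and_fdr_on_planted_cohort(self, small_cohort):
        """Both modalities recover ≥90% of their differential genes with
        empirical FDR ≤0.1 at the default thresholds."""
        expr, meth, truth = small_cohort
        cfg = gcbmi.PipelineConfig()
        sel = gcbmi.select_biomarkers(expr, meth, cfg)
        expr_true = truth.planted_biomarkers | truth.expr_only_genes
        meth_true = truth.planted_biomarkers | truth.meth_only_genes
        for called, true_set in ((set(sel.deg), expr_true), (set(sel.dmp), meth_true)):
            assert len(called & true_set) / len(true_set) >= 0.9
            assert len(called - true_set) / max(len(called), 1) <= 0.1
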