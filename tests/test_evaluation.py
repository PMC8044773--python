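"""Confusion metrics, AUC, and the cross-validated pipeline orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gcbmi
from gcbmi.evaluation import (
    ConfusionCounts,
    PipelineConfig,
    _stratified_folds,
    auc,
    metrics,
    run_cv,
    run_pipeline_fold,
    select_biomarkers,
)

from oracles import confusion_metrics, pair_counting_auc


class TestMetrics:
    def test_worked_confusion_table(self):
        m = metrics(ConfusionCounts(tp=2, fp=1, tn=3, fn=0))
        assert m["accuracy"] == pytest.approx(5 / 6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == 1.0
        assert m["f1"] == pytest.approx(0.8)

    def test_perfect_classifier_scores_one_everywhere(self):
        m = metrics(ConfusionCounts(tp=4, fp=0, tn=5, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_denominators_default_to_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=2, fn=3))
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f1"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_matches_direct_formula_oracle(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        got = metrics(ConfusionCounts(tp, fp, tn, fn))
        expected = confusion_metrics(tp, fp, tn, fn)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)

    def test_counts_from_predictions(self):
        c = ConfusionCounts.from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)
        assert c.total == 5


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_one_of_two_pairs_ordered(self):
        assert auc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    def test_matches_pair_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        truth = rng.integers(0, 2, size=n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        assert auc(scores, truth) == pytest.approx(
            pair_counting_auc(scores, truth), abs=1e-12
        )


class TestPipelineConfig:
    def test_published_operating_point_defaults(self):
        cfg = PipelineConfig()
        assert cfg.mi_top_n == 3000
        assert cfg.expr_thresholds == gcbmi.DiffThresholds(2.0, 0.05, 0.01)
        assert cfg.meth_thresholds == gcbmi.DiffThresholds(1.8, 0.05, 0.01)
        assert cfg.n_folds == 5

    def test_from_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "mi_top_n: 500\n"
            "expr_thresholds: {abs_fc_min: 2.1, p_max: 0.05, q_max: 0.01}\n"
            "dnn: {epochs: 3, seed: 9}\n"
        )
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.mi_top_n == 500
        assert cfg.expr_thresholds.abs_fc_min == 2.1
        assert cfg.dnn.epochs == 3

    def test_invalid_classifier_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(classifier="tree")


class TestFolding:
    def test_fold_sizes_match_published_worked_example(self):
        """268 expression samples under 5-fold CV give training folds of 214±1."""
        rng = np.random.default_rng(0)
        ids = [f"S{i}" for i in range(268)]
        values = pd.DataFrame(rng.normal(size=(268, 3)), index=ids, columns=["A", "B", "C"])
        labels = pd.Series(["tumor"] * 134 + ["normal"] * 134, index=ids)
        m = gcbmi.OmicsMatrix("expression", values, labels)
        folds = _stratified_folds(m, 5, seed=0)
        train_sizes = {len(tr) for tr, _ in folds}
        assert train_sizes <= {214, 215}

    def test_fold_missing_a_class_raises_before_fitting(self):
        rng = np.random.default_rng(0)
        ids = [f"S{i}" for i in range(12)]
        values = pd.DataFrame(rng.normal(size=(12, 2)), index=ids, columns=["A", "B"])
        labels = pd.Series(["tumor"] * 2 + ["normal"] * 10, index=ids)
        m = gcbmi.OmicsMatrix("expression", values, labels)
        with pytest.raises(ValueError, match="stratified"):
            _stratified_folds(m, 5, seed=0)


FAST = PipelineConfig(dnn=gcbmi.DNNConfig(epochs=4, seed=0), cv_seed=5)


class TestPipelineFold:
    def test_fold_recovers_planted_biomarkers(self, small_cohort):
        expr, meth, truth = small_cohort
        report = run_cv(expr, meth, FAST)
        for fold in report.folds:
            sel = set(fold.selected_genes)
            assert len(sel & truth.planted_biomarkers) / len(truth.planted_biomarkers) >= 0.9
        assert report.means["accuracy"] >= 0.95

    def test_no_biomarkers_status_instead_of_crash(self):
        cfg = gcbmi.null_config(seed=5, n_genes_expr=150, n_genes_meth=150)
        expr, meth, _ = gcbmi.simulate_cohort(cfg)
        e_tr = expr.subset_samples(expr.sample_ids[::2])
        e_te = expr.subset_samples(expr.sample_ids[1::2])
        m_tr = meth.subset_samples(meth.sample_ids[::2])
        m_te = meth.subset_samples(meth.sample_ids[1::2])
        result = run_pipeline_fold(e_tr, e_te, m_tr, m_te, FAST)
        assert result.status == "no_biomarkers"
        assert result.selected_genes == []
        assert np.isnan(result.accuracy)

    def test_leakage_sentinel_test_values_never_change_selection(self, small_cohort):
        expr, meth, _ = small_cohort
        e_ids, m_ids = expr.sample_ids, meth.sample_ids
        e_tr, e_te = expr.subset_samples(e_ids[::2]), expr.subset_samples(e_ids[1::2])
        m_tr, m_te = meth.subset_samples(m_ids[::2]), meth.subset_samples(m_ids[1::2])
        sel_before = select_biomarkers(e_tr, m_tr, FAST)
        corrupted = gcbmi.OmicsMatrix(
            "expression", e_te.values * 1000.0 + 7.0, e_te.labels
        )
        run_pipeline_fold(e_tr, corrupted, m_tr, m_te, FAST)
        sel_after = select_biomarkers(e_tr, m_tr, FAST)
        assert sel_before.selected_genes == sel_after.selected_genes
        assert sel_before.expr_rank.genes == sel_after.expr_rank.genes
        pd.testing.assert_series_equal(sel_before.expr_params.mean, sel_after.expr_params.mean)


class TestRunCv:
    def test_identical_seeds_reproduce_the_report(self, small_cohort):
        expr, meth, _ = small_cohort
        r1 = run_cv(expr, meth, FAST)
        r2 = run_cv(expr, meth, FAST)
        pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())
        assert r1.consensus_genes == r2.consensus_genes

    def test_consensus_is_intersection_of_fold_lists(self, small_cohort):
        expr, meth, _ = small_cohort
        report = run_cv(expr, meth, FAST)
        expected = gcbmi.consensus_across_folds(report.fold_gene_lists())
        assert report.consensus_genes == expected

    def test_report_saves_fold_lists_and_consensus(self, small_cohort, tmp_path):
        expr, meth, _ = small_cohort
        report = run_cv(expr, meth, FAST)
        report.save(tmp_path)
        assert (tmp_path / "cv_report.tsv").exists()
        assert (tmp_path / "consensus_genes.txt").exists()
        for fold in report.folds:
            listed = (tmp_path / f"fold_{fold.fold_index}_genes.txt").read_text().split()
            assert listed == fold.selected_genes
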