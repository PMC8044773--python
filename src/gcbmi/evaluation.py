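"""Cross-validated evaluation of the full biomarker pipeline.

The orchestration follows a strict leakage discipline: each modality is
split independently into stratified folds (the two cohorts share no
samples, so they cannot share a split), and within a fold every fitted
object — the per-gene standardizer, the mutual-information ranks, the
differential-calling thresholds' statistics — is computed on the training
partition only and frozen before the held-out partition is touched.

Per fold the pipeline runs:
standardize → MI TopN per modality → fold-change + variance-gated t-test +
BH-FDR per modality → DEG ∩ DMP → Cartesian pairing → classifier train /
predict → confusion-derived metrics plus rank-based AUC over test pairs.

Metrics (positive class = tumor):
    accuracy  = (TP+TN)/(TP+FP+TN+FN)
    precision = TP/(TP+FP)
    recall    = TP/(TP+FN)
    F1        = 2·precision·recall/(precision+recall)
with a zero denominator yielding 0 by convention. Across-fold summaries are
arithmetic means of the per-fold metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import dnn
from .differential import (
    EXPRESSION_DEFAULTS,
    METHYLATION_DEFAULTS,
    DiffThresholds,
    annotate_significance,
    call_significant,
    differential_table,
)
from .integration import PairedDataset, cartesian_pair, consensus_across_folds, intersect_biomarkers
from .matrix import OmicsMatrix
from .preprocess import apply_standardizer, fit_standardizer
from .ranking import rank_topn

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion table; positive class = tumor."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from a confusion table."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    if (counts.tp + counts.fp) == 0 or (counts.tp + counts.fn) == 0:
        logger.info("degenerate confusion table %s: precision/recall defaulted to 0", counts)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) AUC; tied scores contribute 1/2."""
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings; defaults follow the method's published operating point."""

    mi_top_n: int = 3000
    mi_bins: int = 10
    expr_thresholds: DiffThresholds = EXPRESSION_DEFAULTS
    meth_thresholds: DiffThresholds = METHYLATION_DEFAULTS
    gate_alpha: float = 0.05
    dnn: dnn.DNNConfig = dnn.DNNConfig()
    classifier: str = "dnn"  # "dnn" or a baseline name (knn|svm|nb)
    n_folds: int = 5
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.mi_top_n < 1 or self.mi_bins < 1:
            raise ValueError("mi_top_n and mi_bins must be >= 1")
        if not 0 < self.gate_alpha < 1:
            raise ValueError("gate_alpha must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.classifier not in ("dnn",) + dnn.BASELINE_NAMES:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, default in (("expr_thresholds", EXPRESSION_DEFAULTS),
                             ("meth_thresholds", METHYLATION_DEFAULTS)):
            if key in d and isinstance(d[key], dict):
                d[key] = DiffThresholds(**d[key])
        if "dnn" in d and isinstance(d["dnn"], dict):
            d["dnn"] = dnn.DNNConfig(**d["dnn"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Fold-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """One fold's selected genes, confusion counts and metrics."""

    fold_index: int
    selected_genes: list[str]
    n_deg: int
    n_dmp: int
    status: str  # "ok" | "no_biomarkers"
    counts: ConfusionCounts | None = None
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    auc: float = float("nan")
    n_train_pairs: int = 0
    n_test_pairs: int = 0


@dataclass
class CVReport:
    """Per-fold results, across-fold metric means, and the consensus gene set."""

    folds: list[FoldResult]
    consensus_genes: list[str]

    @property
    def means(self) -> dict[str, float]:
        ok = [f for f in self.folds if f.status == "ok"]
        if not ok:
            return {name: float("nan") for name in METRIC_NAMES}
        return {name: float(np.mean([getattr(f, name) for f in ok])) for name in METRIC_NAMES}

    def fold_gene_lists(self) -> list[list[str]]:
        return [f.selected_genes for f in self.folds]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            rows.append(
                {
                    "fold": f.fold_index,
                    "status": f.status,
                    "n_selected": len(f.selected_genes),
                    "n_deg": f.n_deg,
                    "n_dmp": f.n_dmp,
                    "n_train_pairs": f.n_train_pairs,
                    "n_test_pairs": f.n_test_pairs,
                    **{name: getattr(f, name) for name in METRIC_NAMES},
                }
            )
        df = pd.DataFrame(rows)
        mean_row = {"fold": "mean", "status": "", **self.means}
        return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "cv_report.tsv", sep="\t", index=False)
        for f in self.folds:
            (out / f"fold_{f.fold_index}_genes.txt").write_text(
                "\n".join(f.selected_genes) + ("\n" if f.selected_genes else "")
            )
        (out / "consensus_genes.txt").write_text(
            "\n".join(self.consensus_genes) + ("\n" if self.consensus_genes else "")
        )


@dataclass
class SelectionArtifacts:
    """Everything fitted during a fold's feature selection (training data only)."""

    selected_genes: list[str]
    deg: list[str]
    dmp: list[str]
    expr_params: object
    meth_params: object
    expr_rank: object
    meth_rank: object
    expr_table: pd.DataFrame
    meth_table: pd.DataFrame


def select_biomarkers(
    expr_train: OmicsMatrix, meth_train: OmicsMatrix, config: PipelineConfig
) -> SelectionArtifacts:
    """Training-only feature selection: standardize → MI TopN → differential → intersect."""
    expr_params = fit_standardizer(expr_train)
    meth_params = fit_standardizer(meth_train)
    expr_std = apply_standardizer(expr_train, expr_params)
    meth_std = apply_standardizer(meth_train, meth_params)

    expr_rank = rank_topn(expr_std, config.mi_top_n, bins=config.mi_bins)
    meth_rank = rank_topn(meth_std, config.mi_top_n, bins=config.mi_bins)

    expr_table = annotate_significance(
        differential_table(expr_train, expr_std, expr_rank.genes, gate_alpha=config.gate_alpha),
        config.expr_thresholds,
    )
    meth_table = annotate_significance(
        differential_table(meth_train, meth_std, meth_rank.genes, gate_alpha=config.gate_alpha),
        config.meth_thresholds,
    )
    deg = call_significant(expr_table, config.expr_thresholds)
    dmp = call_significant(meth_table, config.meth_thresholds)
    selected = intersect_biomarkers(deg, dmp)
    return SelectionArtifacts(
        selected_genes=selected,
        deg=deg,
        dmp=dmp,
        expr_params=expr_params,
        meth_params=meth_params,
        expr_rank=expr_rank,
        meth_rank=meth_rank,
        expr_table=expr_table,
        meth_table=meth_table,
    )


def _fit_predict(train_ds: PairedDataset, test_ds: PairedDataset, config: PipelineConfig):
    if config.classifier == "dnn":
        model = dnn.train(train_ds, config.dnn)
        return dnn.predict(model, test_ds)
    adapter = dnn.baseline_classifiers(config.classifier)
    adapter.fit(train_ds.features, train_ds.labels)
    return adapter.predict(test_ds.features)


def run_pipeline_fold(
    expr_train: OmicsMatrix,
    expr_test: OmicsMatrix,
    meth_train: OmicsMatrix,
    meth_test: OmicsMatrix,
    config: PipelineConfig,
    fold_index: int = 0,
) -> FoldResult:
    """Execute one complete fold; everything is fitted on the train side only."""
    sel = select_biomarkers(expr_train, meth_train, config)
    if not sel.selected_genes:
        return FoldResult(
            fold_index=fold_index,
            selected_genes=[],
            n_deg=len(sel.deg),
            n_dmp=len(sel.dmp),
            status="no_biomarkers",
        )

    genes = sel.selected_genes
    expr_std_tr = apply_standardizer(expr_train, sel.expr_params).subset_genes(genes)
    meth_std_tr = apply_standardizer(meth_train, sel.meth_params).subset_genes(genes)
    expr_std_te = apply_standardizer(expr_test, sel.expr_params).subset_genes(genes)
    meth_std_te = apply_standardizer(meth_test, sel.meth_params).subset_genes(genes)

    train_ds = cartesian_pair(expr_std_tr, meth_std_tr)
    test_ds = cartesian_pair(expr_std_te, meth_std_te)
    scores, hard = _fit_predict(train_ds, test_ds, config)

    counts = ConfusionCounts.from_predictions(test_ds.labels, hard)
    m = metrics(counts)
    fold_auc = auc(scores, test_ds.labels)
    logger.info(
        "fold %d: |DEG|=%d |DMP|=%d |selected|=%d train_pairs=%d test_pairs=%d acc=%.4f",
        fold_index, len(sel.deg), len(sel.dmp), len(genes),
        train_ds.n_rows, test_ds.n_rows, m["accuracy"],
    )
    return FoldResult(
        fold_index=fold_index,
        selected_genes=genes,
        n_deg=len(sel.deg),
        n_dmp=len(sel.dmp),
        status="ok",
        counts=counts,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        auc=fold_auc,
        n_train_pairs=train_ds.n_rows,
        n_test_pairs=test_ds.n_rows,
    )


def _stratified_folds(matrix: OmicsMatrix, n_folds: int, seed: int):
    y = matrix.tumor_mask.astype(int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < n_folds:
        raise ValueError(
            f"cannot build {n_folds} stratified folds: class counts {class_counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = np.array(matrix.sample_ids)
    return [(ids[tr], ids[te]) for tr, te in skf.split(np.zeros(len(y)), y)]


def run_cv(expr: OmicsMatrix, meth: OmicsMatrix, config: PipelineConfig = PipelineConfig()) -> CVReport:
    """Stratified k-fold CV over both modalities, folded independently.

    The modalities have disjoint sample sets, so each is split on its own
    with the same ``cv_seed``; fold k of the combined pipeline pairs
    expression-fold-k with methylation-fold-k. A fold that would lack one
    class in either modality raises before any fitting.
    """
    expr_folds = _stratified_folds(expr, config.n_folds, config.cv_seed)
    meth_folds = _stratified_folds(meth, config.n_folds, config.cv_seed)
    results = []
    for k in range(config.n_folds):
        e_tr, e_te = expr_folds[k]
        m_tr, m_te = meth_folds[k]
        results.append(
            run_pipeline_fold(
                expr.subset_samples(e_tr),
                expr.subset_samples(e_te),
                meth.subset_samples(m_tr),
                meth.subset_samples(m_te),
                config,
                fold_index=k + 1,
            )
        )
    fold_sets = [r.selected_genes for r in results]
    consensus = consensus_across_folds(fold_sets) if fold_sets else []
    return CVReport(folds=results, consensus_genes=consensus)
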