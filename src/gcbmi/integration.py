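"""Cross-modality integration: biomarker intersection and Cartesian pairing.

The working hypothesis is that a gene that is both differentially expressed
and differentially methylated between tumor and normal is a candidate
biomarker, so the per-fold gene set is the exact intersection DEG ∩ DMP,
and the pipeline's final output is the consensus of that intersection
across all cross-validation folds.

Because the two modalities are measured on *different* patients, combined
training examples are manufactured by the Cartesian product of same-label
samples: every (tumor expression sample, tumor methylation sample) pair
becomes one synthetic tumor example whose feature vector is the expression
block followed by the methylation block over the same selected genes — so
T_e tumor + N_e normal expression samples crossed with T_m + N_m
methylation samples give T_e·T_m + N_e·N_m rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import NORMAL, TUMOR, FoldGeneLists, OmicsMatrix

logger = logging.getLogger(__name__)


def intersect_biomarkers(deg: Iterable[str], dmp: Iterable[str]) -> list[str]:
    """DEG ∩ DMP, returned lexicographically sorted; empty is a valid outcome."""
    out = sorted(set(deg) & set(dmp))
    if not out:
        logger.warning("DEG/DMP intersection is empty — no candidate biomarkers this fold")
    return out


def consensus_across_folds(fold_lists: FoldGeneLists | Sequence[Iterable[str]]) -> list[str]:
    """Genes present in every fold's list, lexicographically sorted."""
    if isinstance(fold_lists, FoldGeneLists):
        sets = fold_lists.as_sets()
    else:
        sets = [frozenset(g.strip().upper() for g in lst) for lst in fold_lists]
    if not sets:
        raise ValueError("need at least one fold list")
    return sorted(frozenset.intersection(*sets))


@dataclass
class PairedDataset:
    """Cartesian-paired cross-omics examples with full provenance.

    ``features`` has one row per (expression sample, methylation sample)
    pair: the standardized expression values of ``selected_genes`` followed
    by the standardized methylation values of the same genes (vector length
    2·|genes|). ``labels`` is 1 for tumor, 0 for normal.
    """

    features: np.ndarray
    labels: np.ndarray
    expr_sample_ids: list[str]
    meth_sample_ids: list[str]
    selected_genes: list[str]

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.expr_sample_ids) == len(self.meth_sample_ids) == n):
            raise ValueError("provenance columns must align with the feature rows")
        if self.features.shape[1] != 2 * len(self.selected_genes):
            raise ValueError("feature vector length must be 2 × |selected genes|")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_tumor(self) -> int:
        return int(self.labels.sum())

    @property
    def n_normal(self) -> int:
        return self.n_rows - self.n_tumor

    def to_frame(self) -> pd.DataFrame:
        cols = [f"expr:{g}" for g in self.selected_genes] + [
            f"meth:{g}" for g in self.selected_genes
        ]
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "expr_sample", self.expr_sample_ids)
        df.insert(1, "meth_sample", self.meth_sample_ids)
        df.insert(2, "label", np.where(self.labels == 1, TUMOR, NORMAL))
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def expected_pair_count(n_tumor_expr: int, n_tumor_meth: int,
                        n_normal_expr: int, n_normal_meth: int) -> int:
    """Closed form for the Cartesian-paired row count."""
    return n_tumor_expr * n_tumor_meth + n_normal_expr * n_normal_meth


def cartesian_pair(expr: OmicsMatrix, meth: OmicsMatrix) -> PairedDataset:
    """All same-label cross-modality pairs, expression sample-major order.

    Both matrices must already be standardized and restricted to the same
    ordered selected-gene list. Rows follow the expression matrix's sample
    order; within one expression sample, methylation samples of the same
    label appear in their matrix order.
    """
    if list(expr.gene_ids) != list(meth.gene_ids):
        raise ValueError("expression and methylation matrices must share the same ordered gene list")
    if expr.n_samples == 0 or meth.n_samples == 0:
        raise ValueError("both matrices need at least one sample")
    genes = list(expr.gene_ids)
    g = len(genes)

    feats: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    expr_ids: list[str] = []
    meth_ids: list[str] = []
    meth_by_label = {
        lab: meth.values.loc[meth.labels == lab] for lab in (TUMOR, NORMAL)
    }
    ev = expr.values.to_numpy()
    for i, (sid, lab) in enumerate(zip(expr.sample_ids, expr.labels)):
        partners = meth_by_label[lab]
        k = partners.shape[0]
        if k == 0:
            continue
        block = np.empty((k, 2 * g))
        block[:, :g] = ev[i]
        block[:, g:] = partners.to_numpy()
        feats.append(block)
        labels.append(np.full(k, 1 if lab == TUMOR else 0, dtype=np.intp))
        expr_ids.extend([sid] * k)
        meth_ids.extend(partners.index.tolist())

    if feats:
        features = np.vstack(feats)
        label_arr = np.concatenate(labels)
    else:
        features = np.empty((0, 2 * g))
        label_arr = np.empty(0, dtype=np.intp)
    return PairedDataset(
        features=features,
        labels=label_arr,
        expr_sample_ids=expr_ids,
        meth_sample_ids=meth_ids,
        selected_genes=genes,
    )


def majority_by_source(dataset: PairedDataset, hard_labels: np.ndarray,
                       side: str = "expr") -> pd.Series:
    """Optional per-source-sample aggregation of per-pair predictions.

    Maps each source sample (``side`` = ``"expr"`` or ``"meth"``) to the
    majority vote of the hard labels over all pairs it participates in
    (ties go to tumor = 1). Off the default evaluation path: metrics are
    computed per pair.
    """
    ids = dataset.expr_sample_ids if side == "expr" else dataset.meth_sample_ids
    votes = pd.DataFrame({"sample": ids, "pred": np.asarray(hard_labels)})
    frac = votes.groupby("sample")["pred"].mean()
    return (frac >= 0.5).astype(int)
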