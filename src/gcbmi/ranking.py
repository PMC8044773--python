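"""Mutual-information relevance ranking of genes against the class label.

Continuous gene values are quantile-binned (default 10 bins; duplicate
quantile edges collapse, so heavily tied columns use fewer bins) and the
plug-in discrete mutual information with the binary label is computed in
bits:

    MI = Σ_{x,y} p(x, y) · log2[ p(x, y) / (p(x) p(y)) ]

with empty cells contributing 0. Quantile binning makes the score invariant
under strictly monotone transforms of the values (up to tie structure), and
the estimator has no internal randomness, so ranks are fully deterministic:
genes sort by MI descending with lexicographic gene-symbol tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix


def quantile_bin(values: np.ndarray, bins: int = 10) -> np.ndarray:
    """Assign each value to a quantile bin; returns integer codes.

    Duplicate quantile edges (ties) are merged, so the number of distinct
    codes can be smaller than ``bins``; a constant column yields one bin.
    """
    values = np.asarray(values, dtype=float)
    if bins < 1:
        raise ValueError("bins must be >= 1")
    inner = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(inner)
    return np.searchsorted(edges, values, side="right")


def mi_score(values: np.ndarray, labels: np.ndarray, bins: int = 10) -> float:
    """Plug-in mutual information (bits) between binned values and labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must align")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels contain a single class; MI undefined")
    x = quantile_bin(values, bins=bins)
    y = np.searchsorted(classes, labels)
    return _plugin_mi(x, y)


def _plugin_mi(x: np.ndarray, y: np.ndarray) -> float:
    n = x.shape[0]
    nx = int(x.max()) + 1
    ny = int(y.max()) + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny) / n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


@dataclass
class GeneRankTable:
    """Per-gene MI scores with a deterministic 1-based rank."""

    table: pd.DataFrame  # columns: gene, mi_bits, rank

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rank_topn(matrix: OmicsMatrix, n: int, *, bins: int = 10) -> GeneRankTable:
    """Score every gene's MI with the label and keep the top ``n``.

    ``n`` larger than the gene count returns all genes, ranked. Ties in MI
    break lexicographically on the gene symbol.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    matrix.require_complete()
    y = matrix.tumor_mask.astype(np.intp)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class; MI undefined")
    vals = matrix.values.to_numpy()
    scores = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        scores[j] = _plugin_mi(quantile_bin(vals[:, j], bins=bins), y)
    df = pd.DataFrame({"gene": matrix.gene_ids, "mi_bits": scores})
    df = df.sort_values(["mi_bits", "gene"], ascending=[False, True], kind="mergesort")
    df = df.head(min(n, len(df))).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return GeneRankTable(df)
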