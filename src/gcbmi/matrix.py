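"""Core data model and text I/O for single-modality omics matrices.

The central container is :class:`OmicsMatrix`: a samples × genes table of
real values together with a per-sample tumor/normal label. Matrices are read
from and written to plain delimited text (TSV/CSV) with a header row of IDs;
GEO-style files are typically genes (or probes) × samples and are transposed
on load via the ``orientation`` flag.

Gene symbols are case-normalized to uppercase everywhere so that set
operations (intersections, consensus) are never confounded by case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"
VALID_LABELS = frozenset({TUMOR, NORMAL})
VALID_MODALITIES = frozenset({"expression", "methylation"})


class MatrixFormatError(ValueError):
    """Raised when an input table violates the matrix contract."""


@dataclass
class OmicsMatrix:
    """One modality's samples × genes value table with binary labels.

    Parameters
    ----------
    modality:
        ``"expression"`` or ``"methylation"``.
    values:
        DataFrame indexed by sample ID with gene IDs as columns. Missing
        values (NaN) are tolerated only at the probe level, before
        :func:`collapse_probes`; downstream stages require complete data.
    labels:
        Series mapping every sample ID to ``"tumor"`` or ``"normal"``.
    """

    modality: str
    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.modality not in VALID_MODALITIES:
            raise MatrixFormatError(
                f"unknown modality {self.modality!r}; expected one of {sorted(VALID_MODALITIES)}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample IDs: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene IDs: {dups}")
        self.labels = self.labels.reindex(self.values.index)
        missing = self.labels.index[self.labels.isna()].tolist()
        if missing:
            raise MatrixFormatError(f"samples without a label: {missing}")
        bad = sorted(set(self.labels.unique()) - VALID_LABELS)
        if bad:
            raise MatrixFormatError(f"invalid labels {bad}; expected {sorted(VALID_LABELS)}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise MatrixFormatError("value table contains non-numeric columns")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def tumor_mask(self) -> np.ndarray:
        return (self.labels == TUMOR).to_numpy()

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def require_complete(self) -> None:
        """Raise if any value is missing; pipeline stages call this."""
        if self.has_missing():
            n = int(self.values.isna().sum().sum())
            raise MatrixFormatError(f"matrix has {n} missing values; collapse/clean first")

    def subset_genes(self, genes: Iterable[str]) -> "OmicsMatrix":
        genes = list(genes)
        absent = [g for g in genes if g not in self.values.columns]
        if absent:
            raise KeyError(f"genes not in matrix: {absent[:10]}")
        return OmicsMatrix(self.modality, self.values.loc[:, genes].copy(), self.labels.copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        sample_ids = list(sample_ids)
        return OmicsMatrix(
            self.modality, self.values.loc[sample_ids].copy(), self.labels.loc[sample_ids].copy()
        )

    def split_by_label(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (tumor values, normal values) sub-frames."""
        mask = self.tumor_mask
        return self.values.loc[mask], self.values.loc[~mask]


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV/CSV into a Series."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise MatrixFormatError(f"label table {path} needs two columns (sample_id, label)")
    first = str(df.iloc[0, 1]).strip().lower()
    if first not in VALID_LABELS:  # tolerate a header row
        df = df.iloc[1:]
    labels = pd.Series(
        df.iloc[:, 1].str.strip().str.lower().to_numpy(),
        index=df.iloc[:, 0].str.strip().to_numpy(),
        name="label",
    )
    if labels.index.duplicated().any():
        raise MatrixFormatError("duplicate sample IDs in label table")
    return labels


def read_matrix(
    path: str | Path,
    *,
    modality: str,
    labels: pd.Series | Mapping[str, str] | str | Path,
    orientation: str = "genes_by_samples",
) -> OmicsMatrix:
    """Read a delimited value table into the internal samples × genes layout.

    ``orientation`` declares the file layout: ``"genes_by_samples"`` (the
    GEO convention — first column feature IDs, header row sample IDs) or
    ``"samples_by_genes"``. Blank/NA cells become NaN (cleaned later by
    probe collapsing); any other non-numeric cell raises naming the row and
    column.
    """
    if orientation not in {"genes_by_samples", "samples_by_genes"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise MatrixFormatError(f"{path}: no data rows")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()  # NA-style strings already parse to NaN
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    if orientation == "genes_by_samples":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str).str.strip()
    numeric.columns = numeric.columns.astype(str).str.strip().str.upper()
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    elif isinstance(labels, Mapping):
        labels = pd.Series(labels)
    return OmicsMatrix(modality=modality, values=numeric, labels=labels.astype(str).str.lower())


def write_matrix(
    matrix: OmicsMatrix, path: str | Path, *, orientation: str = "genes_by_samples"
) -> None:
    """Write the value table back to delimited text (inverse of read)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = matrix.values.T if orientation == "genes_by_samples" else matrix.values
    table.to_csv(path, sep=sep)


def write_labels(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.labels.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Probe annotation and collapsing
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_symbol) mapping; drops unmapped probes."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    mapping: dict[str, str] = {}
    dropped = 0
    for probe, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gene = "" if gene is None or (isinstance(gene, float) and np.isnan(gene)) else str(gene).strip()
        if not gene or gene.lower() in {"na", "nan", "---"}:
            dropped += 1
            continue
        mapping[str(probe).strip()] = gene.upper()
    if dropped:
        logger.info("annotation: dropped %d unmapped probes", dropped)
    return mapping


def collapse_probes(matrix: OmicsMatrix, annotation: Mapping[str, str]) -> OmicsMatrix:
    """Collapse a probe-keyed matrix to gene level by per-sample median.

    A gene measured by several probes takes, in each sample, the median of
    its probes' values (midpoint of the two central values for an even
    count). Probes absent from the annotation are dropped, and genes left
    with any missing value across samples are removed entirely.
    """
    probe_to_gene = {p: g.strip().upper() for p, g in annotation.items() if g and g.strip()}
    present = [p for p in matrix.gene_ids if p in probe_to_gene]
    if not present:
        raise MatrixFormatError("annotation maps no probe present in the matrix")
    sub = matrix.values.loc[:, present]
    gene_index = pd.Index([probe_to_gene[p] for p in present], name="gene")
    # median per gene; NaNs propagate so that incomplete genes can be dropped
    collapsed = sub.T.groupby(gene_index).median(numeric_only=True).T
    incomplete = collapsed.columns[collapsed.isna().any(axis=0)]
    if len(incomplete):
        logger.info("collapse_probes: removing %d genes with null values", len(incomplete))
        collapsed = collapsed.drop(columns=incomplete)
    collapsed = collapsed.sort_index(axis=1)
    return OmicsMatrix(matrix.modality, collapsed, matrix.labels.copy())


# ---------------------------------------------------------------------------
# Bundled reference fold lists
# ---------------------------------------------------------------------------

@dataclass
class FoldGeneLists:
    """Ordered gene-symbol lists per cross-validation fold (1-based keys)."""

    lists: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, genes in self.lists.items():
            seen: set[str] = set()
            cleaned = []
            for g in genes:
                g = g.strip().upper()
                if g and g not in seen:
                    seen.add(g)
                    cleaned.append(g)
            self.lists[k] = cleaned

    @property
    def n_folds(self) -> int:
        return len(self.lists)

    @property
    def fold_indices(self) -> list[int]:
        return sorted(self.lists)

    def genes(self, fold: int) -> list[str]:
        if fold not in self.lists:
            raise IndexError(f"fold out of range: {fold} (have {self.fold_indices})")
        return list(self.lists[fold])

    def as_sets(self) -> list[frozenset[str]]:
        return [frozenset(self.lists[k]) for k in self.fold_indices]


def load_reference_fold_lists() -> FoldGeneLists:
    """Load the bundled gastric-cancer per-fold biomarker lists (5 folds).

    These are the DEG ∩ DMP gene lists reported per cross-validation fold by
    a published gastric tumor/normal expression + methylation integration;
    their five cardinalities are 17, 19, 17, 24 and 17, and eight genes are
    common to all folds.
    """
    text = resources.files("gcbmi").joinpath("data/gastric_fold_genes.txt").read_text()
    lists: dict[int, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fold_str, genes_str = line.split("\t", 1)
        lists[int(fold_str)] = [g for g in genes_str.split(",") if g.strip()]
    return FoldGeneLists(lists)
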