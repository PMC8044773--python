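"""Train-set-fitted z-score standardization, applied without leakage.

Each gene column is centered and scaled by the mean and sample standard
deviation (n−1 denominator) estimated on the *training* samples only:
``x' = (x − x̄) / σ``. Held-out data are transformed with the frozen
training parameters, never refitted, so no information flows from test to
train. Genes with zero variance on the fitting set are undefined under this
transform and are excluded (and recorded) rather than floored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .matrix import OmicsMatrix


@dataclass
class StandardizationParams:
    """Frozen per-gene (mean, sd) pairs plus the zero-variance exclusions."""

    mean: pd.Series
    sd: pd.Series
    excluded: list[str] = field(default_factory=list)
    fitted_on: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd}).rename_axis("gene")

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def fit_standardizer(train: OmicsMatrix) -> StandardizationParams:
    """Estimate per-gene mean and sample sd (ddof=1) on training samples.

    Genes whose training sd is exactly zero carry no class information and
    are flagged for exclusion downstream.
    """
    if train.n_samples < 2:
        raise ValueError(f"need at least 2 training samples, got {train.n_samples}")
    train.require_complete()
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=1)
    zero = sd.index[sd == 0.0].tolist()
    keep = sd.index[sd > 0.0]
    return StandardizationParams(
        mean=mean.loc[keep],
        sd=sd.loc[keep],
        excluded=zero,
        fitted_on=train.sample_ids,
    )


def apply_standardizer(matrix: OmicsMatrix, params: StandardizationParams) -> OmicsMatrix:
    """Transform a matrix with frozen params; drops excluded genes.

    Every gene in the matrix must be covered by the params (either retained
    or explicitly excluded) — an uncovered gene indicates the params were
    fitted on different data, i.e. a leakage hazard, and raises.
    """
    covered = set(params.mean.index) | set(params.excluded)
    uncovered = [g for g in matrix.gene_ids if g not in covered]
    if uncovered:
        raise KeyError(
            f"genes not covered by standardization params (leakage hazard): {uncovered[:10]}"
        )
    keep = [g for g in matrix.gene_ids if g in set(params.mean.index)]
    values = matrix.values.loc[:, keep]
    z = (values - params.mean.loc[keep]) / params.sd.loc[keep]
    return OmicsMatrix(matrix.modality, z, matrix.labels.copy())
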