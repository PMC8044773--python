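"""Seeded simulator of unpaired expression + methylation tumor/normal cohorts.

The generator emulates the data regime the pipeline targets: two
high-dimensional matrices measured on *different* sample sets (no
patient-level pairing), sharing most of their gene universe, with a small
set of planted true biomarkers that are differential in BOTH modalities
and additional modality-private differential genes that must NOT survive
the cross-modality intersection.

Expression model
    Per-gene baseline abundance is drawn on the log2 scale (uniform in
    [5, 10], the central range of microarray intensities); each value is
    ``2 ** (baseline + shift·is_tumor + N(0, noise_sd))``, hence strictly
    positive. Differential genes receive a signed log2 shift in tumor
    samples.

Methylation model
    Beta values arise from a logit-normal draw: ``expit(logit(m) +
    N(0, noise_sd))`` around a per-gene, per-group mean ``m``, hence
    strictly inside (0, 1). Non-differential genes get a broad baseline
    (uniform in [0.05, 0.95]). Differential genes are modeled as promoter
    events in the low-methylation regime, where an absolute beta shift is a
    proportionally large change: a gene gaining methylation in tumor starts
    at beta ≈ 0.08–0.15 and a gene losing methylation starts at
    beta ≈ 0.23–0.30. For planted biomarkers the methylation shift has the
    opposite sign to the expression shift (promoter hypermethylation ↔
    transcriptional downregulation).

All randomness flows from a single integer seed; identical configs produce
byte-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .matrix import NORMAL, TUMOR, OmicsMatrix

# promoter-regime baseline windows for differential methylation events
_HYPER_BASELINE = (0.08, 0.15)   # tumor gains methylation
_HYPO_BASELINE = (0.23, 0.30)    # tumor loses methylation


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters.

    Defaults mirror the scale of the real gastric-cancer cohorts the
    pipeline was designed around: ~13.5k expression features over 134 tumor
    + 134 normal samples and ~14.5k methylation features over 203 tumor +
    94 normal samples, with unpaired sample sets.
    """

    n_genes_expr: int = 13515
    n_genes_meth: int = 14476
    shared_gene_fraction: float = 0.8
    n_tumor_expr: int = 134
    n_normal_expr: int = 134
    n_tumor_meth: int = 203
    n_normal_meth: int = 94
    n_planted: int = 20
    n_expr_only: int = 20
    n_meth_only: int = 20
    expr_log2_effect: float = 1.5
    meth_beta_effect: float = 0.15
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes_expr, self.n_genes_meth,
            self.n_tumor_expr, self.n_normal_expr,
            self.n_tumor_meth, self.n_normal_meth,
            self.n_planted, self.n_expr_only, self.n_meth_only,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if not 0.0 <= self.shared_gene_fraction <= 1.0:
            raise ValueError("shared_gene_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted + self.n_expr_only + self.n_meth_only > self.n_shared:
            raise ValueError(
                "planted + modality-private differential genes exceed the shared gene pool"
            )

    @property
    def n_shared(self) -> int:
        return int(round(self.shared_gene_fraction * min(self.n_genes_expr, self.n_genes_meth)))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort.

    ``expr_log2_shift`` / ``meth_beta_shift`` record the signed planted
    shift per differential gene (keys cover planted + the respective
    private set).
    """

    planted_biomarkers: frozenset[str]
    expr_only_genes: frozenset[str]
    meth_only_genes: frozenset[str]
    expr_log2_shift: dict[str, float] = field(default_factory=dict)
    meth_beta_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.planted_biomarkers, self.expr_only_genes, self.meth_only_genes]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("truth sets must be pairwise disjoint")


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def _sample_ids(prefix: str, n_tumor: int, n_normal: int) -> tuple[list[str], pd.Series]:
    ids = [f"{prefix}T{i:04d}" for i in range(1, n_tumor + 1)]
    ids += [f"{prefix}N{i:04d}" for i in range(1, n_normal + 1)]
    labels = pd.Series([TUMOR] * n_tumor + [NORMAL] * n_normal, index=ids, name="label")
    return ids, labels


def simulate_cohort(config: SimConfig) -> tuple[OmicsMatrix, OmicsMatrix, SimTruth]:
    """Generate (expression matrix, methylation matrix, truth) from a config."""
    rng = np.random.default_rng(config.seed)

    shared = _gene_names("G", config.n_shared)
    expr_private = _gene_names("EXPG", config.n_genes_expr - config.n_shared)
    meth_private = _gene_names("METG", config.n_genes_meth - config.n_shared)
    expr_genes = shared + expr_private
    meth_genes = shared + meth_private

    n_diff = config.n_planted + config.n_expr_only + config.n_meth_only
    chosen = rng.choice(config.n_shared, size=n_diff, replace=False) if n_diff else np.array([], int)
    chosen_names = [shared[i] for i in chosen]
    planted = chosen_names[: config.n_planted]
    expr_only = chosen_names[config.n_planted : config.n_planted + config.n_expr_only]
    meth_only = chosen_names[config.n_planted + config.n_expr_only :]

    # signed expression direction for every expression-differential gene;
    # planted genes carry the opposite sign on the methylation side
    expr_diff = planted + expr_only
    expr_sign = {g: float(rng.choice([-1.0, 1.0])) for g in expr_diff}
    meth_sign = {g: -expr_sign[g] for g in planted}
    meth_sign.update({g: float(rng.choice([-1.0, 1.0])) for g in meth_only})

    expr_log2_shift = {g: expr_sign[g] * config.expr_log2_effect for g in expr_diff}
    meth_shift = {g: meth_sign[g] * config.meth_beta_effect for g in meth_sign}

    # ---- expression matrix ------------------------------------------------
    e_ids, e_labels = _sample_ids("ES", config.n_tumor_expr, config.n_normal_expr)
    baseline = rng.uniform(5.0, 10.0, size=len(expr_genes))
    log2v = np.tile(baseline, (len(e_ids), 1))
    tumor_rows = (e_labels == TUMOR).to_numpy()
    gene_pos = {g: j for j, g in enumerate(expr_genes)}
    for g, shift in expr_log2_shift.items():
        log2v[tumor_rows, gene_pos[g]] += shift
    log2v += rng.normal(0.0, config.noise_sd, size=log2v.shape)
    expr = OmicsMatrix(
        "expression",
        pd.DataFrame(np.exp2(log2v), index=e_ids, columns=expr_genes),
        e_labels,
    )

    # ---- methylation matrix ----------------------------------------------
    m_ids, m_labels = _sample_ids("MS", config.n_tumor_meth, config.n_normal_meth)
    base_beta = rng.uniform(0.05, 0.95, size=len(meth_genes))
    m_gene_pos = {g: j for j, g in enumerate(meth_genes)}
    group_mean = np.tile(base_beta, (len(m_ids), 1))
    m_tumor_rows = (m_labels == TUMOR).to_numpy()
    for g, shift in meth_shift.items():
        j = m_gene_pos[g]
        lo, hi = _HYPER_BASELINE if shift > 0 else _HYPO_BASELINE
        b0 = rng.uniform(lo, hi)
        group_mean[:, j] = b0
        group_mean[m_tumor_rows, j] = b0 + shift
    betas = expit(logit(group_mean) + rng.normal(0.0, config.noise_sd, size=group_mean.shape))
    meth = OmicsMatrix(
        "methylation",
        pd.DataFrame(betas, index=m_ids, columns=meth_genes),
        m_labels,
    )

    truth = SimTruth(
        planted_biomarkers=frozenset(planted),
        expr_only_genes=frozenset(expr_only),
        meth_only_genes=frozenset(meth_only),
        expr_log2_shift=expr_log2_shift,
        meth_beta_shift=meth_shift,
    )
    return expr, meth, truth


def benchmark_config(seed: int = 0, **overrides) -> SimConfig:
    """Reduced-scale benchmark cohort used throughout the test battery.

    2,000 genes per modality, 60 tumor + 60 normal samples per modality,
    20 planted biomarkers at 1.5 log2 / 0.15 beta effects — small enough to
    run the full 5-fold pipeline in seconds while keeping the planted
    effects at the strength the selection thresholds are designed for.
    """
    cfg = dict(
        n_genes_expr=2000,
        n_genes_meth=2000,
        shared_gene_fraction=0.8,
        n_tumor_expr=60,
        n_normal_expr=60,
        n_tumor_meth=60,
        n_normal_meth=60,
        n_planted=20,
        n_expr_only=20,
        n_meth_only=20,
        expr_log2_effect=1.5,
        meth_beta_effect=0.15,
        noise_sd=0.4,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Benchmark-scale cohort with zero planted effects (negative control)."""
    return benchmark_config(
        seed=seed,
        n_planted=0,
        n_expr_only=0,
        n_meth_only=0,
        expr_log2_effect=0.0,
        meth_beta_effect=0.0,
        **overrides,
    )
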