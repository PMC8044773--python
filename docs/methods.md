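# Methods

This note records the statistical model behind `gcbmi`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Pipeline model

The pipeline treats biomarker discovery as a per-fold, training-only
selection problem followed by an out-of-fold classification audit. Its
central assumption is *cross-modality concordance*: a gene whose expression
differs between tumor and normal **and** whose promoter methylation differs
in the same cohort contrast is a stronger candidate than a gene supported
by one modality, so the selection unit is the intersection DEG ∩ DMP.

The two cohorts are unpaired — expression and methylation are measured on
different patients — which has two structural consequences:

* cross-validation folds are drawn independently per modality (fold k of
  the combined pipeline is expression-fold-k with methylation-fold-k);
* combined training examples do not exist naturally and are manufactured by
  the Cartesian product of same-label samples. The evaluation unit is the
  *pair*, not the patient: all reported metrics are per-pair. An optional
  majority-vote aggregation back to source samples exists
  (`integration.majority_by_source`) but is off the default path, since the
  mapping from pair predictions to per-patient calls is not part of the
  method's definition.

### Standardization

Per-gene z-scoring with training-set mean and sample standard deviation
(ddof = 1; the denominator is a design choice — cohorts are small, so the
unbiased variant is used). Genes with zero training variance are excluded
and listed rather than floored: the transform is undefined for them and
they carry no class signal. Applying parameters to a gene they were not
fitted on raises, which turns silent leakage into a hard error.

### Mutual-information pre-screen

The MI estimator is deliberately deterministic: quantile binning into
B = 10 bins (duplicate quantile edges merge, so heavily tied columns use
fewer bins; a constant column scores 0) followed by the plug-in discrete
MI in bits. Nearest-neighbor MI estimators were rejected because their
internal randomness would make ranks seed-sensitive and untestable against
a closed-form oracle. Ties in MI break lexicographically on the gene
symbol, making the TopN cut reproducible. N defaults to 3,000; it is a
screening cut, not a significance statement, and is exposed in
`PipelineConfig`.

### Differential calling

* Fold change is computed on the **original positive scale**, never on
  z-scores: standardized group means can be negative, making ratio
  thresholds meaningless. Genes with a non-positive class mean are flagged
  `fc_undefined` and can never be significant.
* Variance gate: Levene's test with mean centering at alpha = 0.05
  (configurable) routes each gene to the pooled t-test (homogeneous) or
  Welch's t-test (heterogeneous). The t-tests run on standardized training
  values; since the z-transform is affine per gene, the t statistic and
  p-value are identical to the raw-scale test.
* FDR: Benjamini–Hochberg step-up (via statsmodels) over exactly the TopN
  survivors of that modality and fold — the set actually tested. Adjusting
  over the full genome instead would mix tested and untested hypotheses.
* Default gates: expression |FC| > 2, methylation |FC| > 1.8, both with
  p < 0.05 and FDR < 0.01. An alternative expression cut of 2.1 is
  reachable through `DiffThresholds` (both values circulate for this kind
  of analysis; 2.0 is the default operating point).
* The batch implementation vectorizes Levene and both t-tests across genes
  and is tested per-gene against the scalar `variance_gated_test` path.

### Classifier

A feed-forward network: input = expression block ‖ methylation block over
the selected genes, six ReLU hidden layers × 100 units with per-unit
biases, inverted dropout after each hidden layer, one sigmoid output;
binary cross-entropy loss (predictions clipped to [1e−7, 1−1e−7]), Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8). The "two-part input" is realized as a
plain concatenated vector with a documented block boundary — the layers
downstream are ordinary dense layers, so a branched architecture would add
nothing. Implemented as a self-contained numpy minibatch trainer (the
model is six small GEMMs); weight init is He-normal, and *all* randomness
(init, shuffling, dropout masks) flows from one integer seed, so training
is bit-reproducible.

Defaults: dropout 0.3, learning rate 1e−3, 30 epochs, batch 128, threshold
0.5. These are conventional values (the architecture is fixed by design;
the optimization hyperparameters are not critical on the benchmark —
the paired datasets are large and strongly separable once selection has
done its job). Note that with fewer training rows than the batch size an
epoch is a single Adam step; small experiments should lower `batch_size`.

### Evaluation

Stratified k-fold splitting (k = 5) with a dedicated `cv_seed`,
per modality. Stratification is a deliberate deviation from plain
order-based splitting: with a 94-sample normal class in the methylation
cohort, unstratified folds can lose a class entirely, which aborts the fold
before any fitting. Metrics are the confusion-derived accuracy, precision,
recall and F1 (zero-denominator cases defined as 0 and logged) plus the
rank-based Mann–Whitney AUC (ties count 1/2). Across-fold summaries are
arithmetic means at the metric level. A fold whose intersection is empty is
reported with status `no_biomarkers` rather than crashing; it is excluded
from the metric means but absorbs the consensus to ∅, which is the honest
reading of "no gene survived every fold".

## Synthetic cohort generator

The generator emulates the regime the pipeline targets: two modality
matrices over disjoint sample ID spaces, a mostly-shared gene universe
(80% by default), ~20 planted true biomarkers differential in both
modalities with opposite signs, and equally many expression-only and
methylation-only decoys that must be removed by the intersection.

* Expression: per-gene baseline uniform on [5, 10] log2 units (the central
  range of microarray intensities); values are `2^(baseline + shift·tumor +
  N(0, σ))` with σ = 0.4 by default — strictly positive, log-normal noise.
  A planted shift of 1.5 log2 units corresponds to an expected fold change
  of 2^1.5 ≈ 2.8, comfortably above the |FC| > 2 gate but close enough
  that the t/FDR gates still do real work at n = 48 + 48 training samples.
* Methylation: logit-normal beta values, `expit(logit(m) + N(0, σ))`,
  strictly inside (0, 1). Non-differential genes draw baselines uniformly
  on [0.05, 0.95]. Differential genes are modeled as *promoter events in
  the low-methylation regime*: hypermethylation starts at β ≈ 0.08–0.15
  and gains 0.15, hypomethylation starts at β ≈ 0.23–0.30 and loses 0.15.
  This mirrors real promoter dynamics (CpG-island promoters are unmethylated
  at baseline, and differential events are proportionally large there) and
  is also the regime where an absolute 0.15 shift is a ratio-detectable
  event — a 0.15 shift on a β = 0.7 probe would be invisible to any
  fold-change criterion, so planting it would break the semantics of
  "true biomarker". For planted genes the methylation direction is opposite
  to the expression direction.
* Default dimensions mirror the real cohorts this method was designed
  around (13,515/14,476 features; 134+134 and 203+94 samples, unpaired);
  the test battery and the acceptance script use `benchmark_config()` —
  2,000 genes and 60+60 samples per modality — which keeps a full 5-fold
  run under a minute while preserving the HDLSS character and the planted
  effect sizes (1.5 log2 / 0.15 beta).

What the generator does **not** emulate: probe-level structure (tests
build probe matrices directly where collapsing is exercised), CpG spatial
correlation, gene–gene correlation, batch effects, or label noise.
Passing recovery tests therefore shows the pipeline's selection logic and
leakage discipline are correct under the stated noise model — not that the
thresholds are optimal for any particular real platform.

## Numerical choices and degenerate inputs

* Probe collapsing: per-sample median over a gene's probes (midpoint for
  even counts); genes with any missing value after collapsing are removed.
* BH q-values are order-preserving and clipped to 1; an empty p-vector
  returns empty.
* MI of a constant column is 0; empty joint cells contribute 0.
* `cartesian_pair` requires identical ordered gene lists on both sides and
  yields deterministic expression-sample-major row order; zero samples of
  a label on either side annihilates that label's pairs.
* Gene symbols are uppercased at every boundary so set operations are
  case-insensitive.
* Seeds: the simulator, the CV splitter and the network each take their
  own integer seed; the acceptance script derives all of them from its
  single `--seed`.

## Known limitations

* Metrics are per-pair; pair-level counts overweight patients from the
  smaller modality side, and no calibration of the network scores is done.
* The MI estimator's binning (10 quantile bins) is a bias/variance
  compromise; very small cohorts (< ~20 samples per class) would warrant
  fewer bins.
* No moderated (empirical-Bayes) test variant; with very few samples per
  group the gene-wise t-tests are noisy, which is partly why the MI screen
  and FDR revision precede them.
* The consensus operation is a hard intersection: one unlucky fold can
  empty it. This is by design (it matches the method's definition) but a
  frequency-threshold consensus would be a natural extension.
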