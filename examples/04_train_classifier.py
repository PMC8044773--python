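"""Train the dense neural network on paired data and compare with baselines.

The classifier is six ReLU hidden layers of 100 units with dropout 0.3, one
sigmoid output, binary cross-entropy loss, Adam. Baselines (KNN with K=5,
RBF-SVM, Gaussian naive Bayes) run through the same fit/score contract.
"""

import gcbmi
from gcbmi import dnn

expr, meth, truth = gcbmi.simulate_cohort(
    gcbmi.benchmark_config(seed=3, n_genes_expr=400, n_genes_meth=400)
)

# select biomarkers on one half, evaluate pairs built from the other half
e_tr = expr.subset_samples(expr.sample_ids[::2])
e_te = expr.subset_samples(expr.sample_ids[1::2])
m_tr = meth.subset_samples(meth.sample_ids[::2])
m_te = meth.subset_samples(meth.sample_ids[1::2])

config = gcbmi.PipelineConfig(dnn=gcbmi.DNNConfig(epochs=10, seed=0))
sel = gcbmi.select_biomarkers(e_tr, m_tr, config)
genes = sel.selected_genes
print(f"selected genes: {len(genes)}")

std = gcbmi.apply_standardizer
train_ds = gcbmi.cartesian_pair(
    std(e_tr, sel.expr_params).subset_genes(genes),
    std(m_tr, sel.meth_params).subset_genes(genes),
)
test_ds = gcbmi.cartesian_pair(
    std(e_te, sel.expr_params).subset_genes(genes),
    std(m_te, sel.meth_params).subset_genes(genes),
)

model = dnn.train(train_ds, config.dnn)
print(f"training loss: epoch 1 = {model.history[0]:.4f} -> "
      f"epoch {len(model.history)} = {model.history[-1]:.4f}")
scores, hard = dnn.predict(model, test_ds)
print(f"DNN held-out pair accuracy = {(hard == test_ds.labels).mean():.4f}, "
      f"AUC = {gcbmi.auc(scores, test_ds.labels):.4f}")

for name in dnn.BASELINE_NAMES:
    clf = dnn.baseline_classifiers(name).fit(train_ds.features, train_ds.labels)
    _, hard = clf.predict(test_ds.features)
    print(f"{name:>3} held-out pair accuracy = {(hard == test_ds.labels).mean():.4f}")
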