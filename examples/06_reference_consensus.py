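"""Consensus over the bundled gastric-cancer per-fold gene lists.

The package ships the per-fold DEG ∩ DMP lists reported by a published
gastric tumor/normal integration study (five cross-validation folds with
17, 19, 17, 24 and 17 genes). Intersecting them yields the eight-gene
biomarker panel.
"""

import gcbmi

folds = gcbmi.load_reference_fold_lists()
for k in folds.fold_indices:
    print(f"fold {k}: {len(folds.genes(k))} genes")

consensus = gcbmi.consensus_across_folds(folds)
print(f"\nconsensus ({len(consensus)} genes): " + ",".join(consensus))
# PGC (pepsinogen C) and PSCA are established gastric biomarkers; the
# consensus set is exactly the genes present in every fold's intersection.
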