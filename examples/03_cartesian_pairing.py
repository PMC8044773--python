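"""Expand unpaired cohorts into combined training examples by Cartesian pairing.

Every same-label (expression sample, methylation sample) pair becomes one
combined example, so a 112/102 tumor/normal expression fold crossed with a
160/77 methylation fold yields 112x160 + 102x77 = 25,774 training rows.
"""

import numpy as np
import pandas as pd

import gcbmi


def make(modality, prefix, n_tumor, n_normal, genes, rng):
    ids = [f"{prefix}T{i}" for i in range(n_tumor)] + [f"{prefix}N{i}" for i in range(n_normal)]
    labels = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=ids)
    values = pd.DataFrame(rng.normal(size=(len(ids), len(genes))), index=ids, columns=genes)
    return gcbmi.OmicsMatrix(modality, values, labels)


rng = np.random.default_rng(0)
genes = ["PGC", "PSCA", "KCNE2"]
expr = make("expression", "E", 112, 102, genes, rng)
meth = make("methylation", "M", 160, 77, genes, rng)

pairs = gcbmi.cartesian_pair(expr, meth)
print(f"tumor pairs:  {pairs.n_tumor}  (= 112 x 160)")
print(f"normal pairs: {pairs.n_normal}   (= 102 x 77)")
print(f"total rows:   {pairs.n_rows}")
print(f"feature vector length: {pairs.features.shape[1]} "
      f"(expression block + methylation block over {len(genes)} genes)")
# Each row records which source samples it came from:
print(pairs.to_frame().iloc[0, :3].to_dict())
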