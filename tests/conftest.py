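import numpy as np
import pandas as pd
import pytest

import gcbmi


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted cohort shared by the recovery-style tests."""
    cfg = gcbmi.benchmark_config(seed=7, n_genes_expr=400, n_genes_meth=400)
    return gcbmi.simulate_cohort(cfg)


@pytest.fixture()
def tiny_expr_matrix():
    """3 genes × 4 samples expression matrix with both labels."""
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0],
                [2.0, 4.0, 3.5],
                [10.0, 1.0, 2.0],
                [12.0, 1.5, 2.5],
            ]
        ),
        index=["S1", "S2", "S3", "S4"],
        columns=["GA", "GB", "GC"],
    )
    labels = pd.Series(
        ["tumor", "tumor", "normal", "normal"], index=values.index, name="label"
    )
    return gcbmi.OmicsMatrix("expression", values, labels)
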