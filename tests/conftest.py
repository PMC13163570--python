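import numpy as np
import pandas as pd
import pytest

from buffatlas import ExpressionMatrix


def make_matrix(values, tissues, stages=None, gene_ids=None, sample_ids=None):
    """Build an ExpressionMatrix from an array and per-sample tissue labels."""
    values = np.asarray(values, float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    stages = stages or [None] * n_samples
    meta = pd.DataFrame(
        {
            "tissue": tissues,
            "stage": [s if s is not None else pd.NA for s in stages],
            "source": "test",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, two tissues with two replicates each."""
    return make_matrix(
        [[4.0, 6.0, 1.0, 3.0], [0.5, 0.7, 0.2, 0.1], [10.0, 12.0, 50.0, 48.0]],
        tissues=["liver", "liver", "muscle", "muscle"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
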