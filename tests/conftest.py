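import numpy as np
import pytest

from dbnexpr.data_model import ExpressionDataset
from dbnexpr.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 samples x 4 genes with simple values and binary labels."""
    X = np.array([
        [1.0, 5.0, 2.0, 0.0],
        [2.0, 5.0, 4.0, 0.0],
        [3.0, 5.0, 9.0, 0.0],
    ])
    return ExpressionDataset(
        expression=X,
        sample_ids=["s1", "s2", "s3"],
        gene_ids=["g1", "g2", "g3", "g4"],
        labels=["a", "a", "b"],
    )


@pytest.fixture(scope="session")
def small_synth():
    """Small separable two-class dataset for classifier tests."""
    spec = SyntheticSpec(n_per_class=(30, 30), n_genes=100, n_differential=15,
                         effect_size=2.0, noise_sd=1.0, seed=7)
    ds, truth = generate(spec)
    return ds, truth
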