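import numpy as np
import pandas as pd
import pytest

from coresig.data_io import CASE, CONTROL, ExpressionDataset


def make_dataset(values, labels, genes=None, samples=None, metadata=None):
    """Build an ExpressionDataset from a 2-D array and a label list."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i:03d}" for i in range(1, n_genes + 1)]
    samples = samples or [f"S{j:03d}" for j in range(1, n_samples + 1)]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    lab = pd.Series(list(labels), index=samples, name="label")
    return ExpressionDataset(expr, lab, metadata or {})


def noise_dataset(n_cases, n_controls, n_genes, seed):
    """Pure-noise balanced-ish dataset: no gene carries class signal."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_cases + n_controls))
    labels = [CASE] * n_cases + [CONTROL] * n_controls
    return make_dataset(values, labels)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, 2 cases / 2 controls, gene 1 separates."""
    values = [[10.0, 8.0, 0.0, 2.0],
              [1.0, 2.0, 1.5, 1.8],
              [5.0, 5.0, 5.0, 5.0]]
    return make_dataset(values, [CASE, CASE, CONTROL, CONTROL])
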