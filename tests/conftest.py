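import numpy as np
import pytest

from cellbrf import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, layer="raw"):
    """ExpressionMatrix with auto-generated ids from a 2-D array."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(g)],
        [f"c{j}" for j in range(c)],
        layer=layer,
    )


@pytest.fixture
def blob_matrix():
    """Log-normalized matrix of three well-separated cell blobs.

    Returns (matrix, true_labels): 60 cells x 20 genes, blobs of 25/20/15
    cells offset along disjoint gene subsets.
    """
    rng = np.random.default_rng(7)
    sizes = [25, 20, 15]
    labels = np.repeat([0, 1, 2], sizes)
    g = 20
    vals = rng.normal(5.0, 0.3, size=(g, 60))
    for cl, block in enumerate(np.split(np.arange(60), np.cumsum(sizes)[:-1])):
        vals[cl * 5 : (cl + 1) * 5, block] += 8.0
    vals = np.clip(vals, 0, None)
    return make_matrix(vals, layer="lognorm"), labels
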