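import numpy as np
import pandas as pd
import pytest

from scase import AllelicDataset


@pytest.fixture
def toy_dataset():
    """2 genes x 3 cells, hand-checkable."""
    ref = np.array([[1, 2, 0], [0, 0, 5]])
    total = np.array([[2, 4, 0], [0, 0, 5]])
    return AllelicDataset(ref, total, pd.Index(["gA", "gB"]), pd.Index(["c1", "c2", "c3"]))


@pytest.fixture
def balanced_dataset():
    """60 genes x 120 cells, exactly balanced (ref = total / 2)."""
    rng = np.random.default_rng(7)
    total = 2 * rng.poisson(10, size=(60, 120))
    ref = total // 2
    return AllelicDataset(
        ref, total,
        pd.Index([f"g{i}" for i in range(60)]),
        pd.Index([f"c{j}" for j in range(120)]),
    )


def make_bb_dataset(n_genes, n_cells, ar, theta, mean_total=20.0, seed=0, groups=None):
    """Beta-binomial dataset with Poisson totals; ar/theta scalar or per-gene."""
    rng = np.random.default_rng(seed)
    total = rng.poisson(mean_total, size=(n_genes, n_cells))
    ar = np.broadcast_to(np.asarray(ar, dtype=float), (n_genes,))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (n_genes,))
    p = rng.beta((ar / theta)[:, None], ((1 - ar) / theta)[:, None], size=(n_genes, n_cells))
    ref = rng.binomial(total, p)
    return AllelicDataset(
        ref, total,
        pd.Index([f"g{i:04d}" for i in range(n_genes)]),
        pd.Index([f"c{j:04d}" for j in range(n_cells)]),
        groups=groups,
    )
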