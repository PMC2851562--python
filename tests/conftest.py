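import numpy as np
import pandas as pd
import pytest

from sparseqtl.datatypes import GenotypePanel, MarkerMap
from sparseqtl.model import Hyperparameters, ScoreWorkspace


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_instance(seed, n=12, p=6, q=2, signal=None, tau_grid_size=25, noise=0.7):
    """Small random inbred-panel regression instance with optional planted
    effects (dict marker -> coefficient, shared across tissues)."""
    r = np.random.default_rng(seed)
    X = r.choice([-0.5, 0.5], size=(n, p))
    B = np.zeros((p, q))
    for j, b in (signal or {}).items():
        B[j] = b
    Y = X @ B + noise * r.standard_normal((n, q))
    hyper = Hyperparameters.from_data(Y, p, tau_grid_size=tau_grid_size)
    return Y, X, hyper


@pytest.fixture
def tiny_workspace():
    Y, X, hyper = make_instance(1, signal={1: 1.4, 4: 0.9})
    return ScoreWorkspace(Y, X, hyper)


def toy_map(chrom_sizes=((1, 5),), spacing=3.0):
    """MarkerMap with the given (chrom, n_markers) layout; physical
    position is 2 Mbp per cM."""
    rows = []
    for c, k in chrom_sizes:
        for m in range(k):
            rows.append((f"c{c}m{m + 1}", str(c), m * spacing, m * spacing * 2.0))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chr", "cm", "mbp"]))
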