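import numpy as np
import pytest

from hldamalo.lda import LabeledDataset


@pytest.fixture
def four_point_data():
    """Two classes of two 2-D points each, worked out by hand:
    class 0 = {(0,0),(0,2)}, class 1 = {(4,0),(4,2)}; the grand mean is
    (2,1), between-class scatter [[16,0],[0,0]], within-class [[0,0],[0,4]]."""
    X = np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]])
    y = np.array([0, 0, 1, 1])
    return LabeledDataset(X=X, y=y)


def make_gaussian_2class(n: int, d: int, gap: float, seed: int) -> LabeledDataset:
    """Balanced two-class Gaussian dataset with mean gap along the first axis."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.normal(size=(n, d))
    y = np.concatenate([np.zeros(half, dtype=int), np.ones(n - half, dtype=int)])
    X[y == 1, 0] += gap
    return LabeledDataset(X=X, y=y)
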