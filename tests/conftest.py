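import numpy as np
import pytest
import scipy.sparse as sp

from scbsp import ExpressionMatrix, SpatialCoordinates


def make_coords(positions, rescaled=False):
    positions = np.asarray(positions, dtype=float)
    ids = np.asarray([f"s{i}" for i in range(len(positions))], dtype=object)
    return SpatialCoordinates(positions=positions, spot_ids=ids, is_rescaled=rescaled)


def make_expr(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if ids is None:
        ids = [f"f{i}" for i in range(rows.shape[0])]
    return ExpressionMatrix(values=sp.csr_matrix(rows), feature_ids=np.asarray(ids, dtype=object))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_instance(rng):
    """A small random dataset: Poisson counts over uniform 2D coordinates."""
    m, n = 80, 20
    coords = make_coords(rng.uniform(0, 10, size=(m, 2)))
    counts = rng.poisson(2.0, size=(n, m)).astype(float)
    return make_expr(counts), coords
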