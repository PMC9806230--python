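import numpy as np
import pytest

from spathet import CellTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_cells(rng):
    """500 cells uniform on a 500x500 µm window with random OD."""
    n = 500
    return CellTable(
        sample_id="uniform",
        x=rng.uniform(0, 500, n),
        y=rng.uniform(0, 500, n),
        od=rng.uniform(0, 40, n),
    )


def make_cells(x, y, od, sample_id="test"):
    return CellTable(
        sample_id=sample_id,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        od=np.asarray(od, dtype=float),
    )
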