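import numpy as np
import pytest

from adiposizer import TissueParams, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """A quick 1500×1500 px slide (60 cells, 0.5 µm/px) with ground truth."""
    params = TissueParams(width=1500, height=1500, pixel_size=0.5, n_cells=60, seed=7)
    return generate_tissue(params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
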