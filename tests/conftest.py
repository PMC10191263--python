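import numpy as np
import pytest

from popencode.frontend import Spectrogram
from popencode.synthetic import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spectrogram(rng):
    """18 x 200 nonnegative random spectrogram split into 4 snippets."""
    values = np.abs(rng.normal(size=(18, 200)))
    return Spectrogram(values, np.geomspace(200, 20000, 18),
                       seg_lens=np.array([50, 50, 50, 50]))


@pytest.fixture(scope="session")
def small_dataset():
    """Small shared-subspace population for plumbing-level tests."""
    return make_dataset(N=12, subspace_dim=4, sites=2, n_est_snippets=16,
                        n_val_snippets=4, n_val_repeats=8, seed=99)
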