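import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from fidelitylink import rsa, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return synthdata.make_trial_table(
        n_blocks=1, trials_per_block=16, n_stimuli=4, memory_rate=0.7, seed=7
    )


@pytest.fixture
def identity_cov():
    def make(n_vox):
        return rsa.ShrunkCovariance(sigma=np.eye(n_vox), lam=0.0, source_df=100)

    return make
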