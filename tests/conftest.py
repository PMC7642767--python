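import numpy as np
import pytest

from cvalkit import synth


@pytest.fixture(scope="session")
def interior_lambda_dataset():
    """A fixed small tree + BM trait whose lambda optimum is interior to
    (0, 1), shared by the grid-search and external oracle tests."""
    tree = synth.simulate_yule_tree(synth.TreeSimConfig(n_tips=8, seed=302))
    traits = synth.simulate_bm_trait(
        tree, synth.BmParams(sigma2=1.0, lambda_true=0.6, seed=402))
    return tree, traits


@pytest.fixture(scope="session")
def yule16():
    return synth.simulate_yule_tree(synth.TreeSimConfig(n_tips=16, seed=108))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
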