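import numpy as np
import pytest

from wingcomp import read_newick, synthetic


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def study_dataset():
    """One fixed study-like dataset (23 tips, 32 count traits)."""
    return synthetic.generate_study_like_dataset(seed=7)


@pytest.fixture(scope="session")
def fixed_tree_23():
    """A fixed 23-tip tree reused by calibration tests."""
    tree, _ = synthetic.generate_study_like_dataset(seed=11)
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
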