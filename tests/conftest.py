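import numpy as np
import pytest

from npcmf import AssociationMatrix, EntityIndex, synthetic


@pytest.fixture()
def small_index():
    return EntityIndex(("mA", "mB", "mC"), ("dX", "dY"))


@pytest.fixture()
def small_assoc(small_index):
    return AssociationMatrix(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]), small_index)


@pytest.fixture(scope="session")
def default_synthetic():
    """Default planted dataset, generated once per session."""
    return synthetic.generate(synthetic.SyntheticSpec())


def random_binary(rng, n, m, density=0.3):
    return (rng.random((n, m)) < density).astype(float)
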