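import numpy as np
import pytest

from cgardp import SynthConfig, generate, generate_worked_example
from cgardp.estimator import CGARDPClassifier
from cgardp.trainer import sample_training_pairs


@pytest.fixture(scope="session")
def worked_example():
    """The fixed 6-drug / 5-disease network with four r1-to-d3 paths."""
    return generate_worked_example()


@pytest.fixture(scope="session")
def tiny_net():
    """A small planted-block network (12 drugs, 9 diseases, 3 blocks)."""
    return generate(
        SynthConfig(
            n_drugs=12,
            n_diseases=9,
            n_blocks=3,
            assoc_density_matched=0.5,
            assoc_density_unmatched=0.05,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def tiny_model():
    """A deliberately small architecture for fast gradient/shape tests."""
    return dict(
        hidden_dim=3,
        attention_dim=3,
        fc_out_dim=4,
        n_filters=(2, 3),
        dropout_rate=0.0,
        random_state=0,
    )


@pytest.fixture(scope="session")
def fitted_tiny(tiny_net):
    """A short fit on the tiny network, shared by inference-side tests."""
    pos = np.argwhere(tiny_net.A == 1)
    pairs, labels = sample_training_pairs(tiny_net, pos, neg_ratio=1.0, seed=5)
    clf = CGARDPClassifier(epochs=8, batch_size=16, random_state=3)
    clf.fit(pairs, labels, network=tiny_net)
    return clf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
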