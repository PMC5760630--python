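import numpy as np
import pytest

from prcnet import DirectedNetwork, PerturbationDesign, generate_scale_free_network
from prcnet import datagen


@pytest.fixture
def single_edge():
    return DirectedNetwork(nodes=[1, 2], edges={(1, 2)})


@pytest.fixture
def chain():
    return DirectedNetwork(nodes=[1, 2, 3], edges={(1, 2), (2, 3)})


@pytest.fixture
def fully_inferable_triangle():
    # two perturbed nodes feeding an unperturbed one
    return DirectedNetwork(nodes=[1, 2, 3], edges={(1, 2), (1, 3), (2, 3)})


@pytest.fixture
def out_hub():
    return DirectedNetwork(nodes=[0, 1, 2, 3], edges={(0, 1), (0, 2), (0, 3)})


@pytest.fixture
def chain_screens():
    """Noise-free and mildly noisy screens on the chain 1->2->3 with
    planted weights, nodes 1 and 2 perturbed."""
    net = datagen.three_node_chain(0.8, 1.3)
    rng = np.random.default_rng(42)
    strengths = rng.standard_normal(2000)
    design = PerturbationDesign(
        n_nodes=3,
        experiments=[(1 if k % 2 == 0 else 2, k, float(strengths[k])) for k in range(2000)],
        knockout=False,
    )
    out = {}
    for sd in (0.0, 0.3):
        out[sd] = datagen.simulate_linear_knockouts(
            net, design, sigma=sd, noise_mode="additive",
            seed=np.random.default_rng(7), n_wt_replicates=8,
        )
    return net, out


def random_weighted_net(n, seed, mean_degree=2.0):
    rng = np.random.default_rng(seed)
    net = generate_scale_free_network(n, 2.5, mean_degree, "outgoing", rng)
    return datagen.assign_random_weights(net, rng), rng
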