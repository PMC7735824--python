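import pytest

from pmdne import BipartiteNetwork, Hyperparams, embed_network, make_synthetic


@pytest.fixture()
def tiny_bn() -> BipartiteNetwork:
    """Two miRNAs, two diseases, three associations (all weight 1)."""
    return BipartiteNetwork(
        u_nodes=["m1", "m2"],
        v_nodes=["d1", "d2"],
        edges={("m1", "d1"): 1.0, ("m1", "d2"): 1.0, ("m2", "d2"): 1.0},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """20+20-node planted-block dataset used across training tests."""
    return make_synthetic(
        n_u=20, n_v=20, n_blocks=2, p_in=0.4, p_out=0.05,
        sim_signal=0.6, sim_noise_sd=0.1, seed=5,
    )


@pytest.fixture(scope="session")
def small_hp() -> Hyperparams:
    return Hyperparams(d=16, epochs=10, seed=5, walks_per_node=5)


@pytest.fixture(scope="session")
def small_model(small_dataset, small_hp):
    data = small_dataset
    return embed_network(data.network, data.sim_u, data.sim_v, small_hp)
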