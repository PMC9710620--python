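import numpy as np
import networkx as nx
import pytest

from mundo import (PPINetwork, SynthSpec, VoteConfig, converged_diffusion_state,
                   diffusion_state, dsd_matrix, generate_dataset)


@pytest.fixture
def path_net() -> PPINetwork:
    """The 3-node path a-b-c."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def k4_net() -> PPINetwork:
    nodes = ["a", "b", "c", "d"]
    return PPINetwork.from_edges(
        [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    )


def random_connected_net(n: int, seed: int, p: float = 0.25) -> PPINetwork:
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    return PPINetwork.from_edges([(f"n{u:03d}", f"n{v:03d}") for u, v in g.edges()])


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic species pair shared across tests."""
    spec = SynthSpec(n_model=80, n_target=80, n_orthologs=40, n_terms=8,
                     dag_depth=3, label_density=0.8, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_embeddings(small_dataset):
    from mundo import select_rbh_landmarks
    from mundo.pipeline import embed_pair

    ds = small_dataset
    lm = select_rbh_landmarks(ds.fwd_hits, ds.rev_hits, 90, 85)
    target_dsd, ce = embed_pair(ds.model_net, ds.target_net, lm)
    return lm, target_dsd, ce


@pytest.fixture
def vote_cfg() -> VoteConfig:
    return VoteConfig(d=5, c=3, alpha=1.5, top_r=3)
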