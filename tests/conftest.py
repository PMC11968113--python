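"""Shared fixtures: synthetic datasets are generated at test time.

The heavy session fixtures (the default simulated slice and one fully
trained model on it) are shared across test modules so the end-to-end
properties are checked on a single training run.
"""

import numpy as np
import pytest

import stmask
from stmask.train import TrainConfig, cluster, embed, train


@pytest.fixture(scope="session")
def smoke_data():
    """Default simulated slice (30x30 grid, 4 band domains, 200 genes),
    preprocessed, with its KNN graph and the clean log-mean signal."""
    ds, clean = stmask.simulate_slice(stmask.smoke_config())
    pre = stmask.preprocess(ds)
    graph = stmask.build_knn_graph(pre.coords, k=6)
    return {"raw": ds, "pre": pre, "graph": graph, "clean": clean}


@pytest.fixture(scope="session")
def smoke_trained(smoke_data):
    """Full dual-masking model trained 300 epochs on the default slice,
    with its domain labels and the raw-feature k-means baseline."""
    pre, graph = smoke_data["pre"], smoke_data["graph"]
    cfg = TrainConfig(
        epochs=300, lam=0.7, node_mask_rate=0.3, edge_mask_rate=0.4, seed=0
    )
    state, trace = train(pre, graph, cfg)
    H = embed(pre, graph, state)
    labels = cluster(H, 4, seed=0).labels
    baseline = cluster(pre.features, 4, seed=0).labels
    return {
        "state": state,
        "trace": trace,
        "embedding": H,
        "labels": labels,
        "ari": stmask.ari(labels, pre.truth),
        "baseline_ari": stmask.ari(baseline, pre.truth),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_graph(n: int, k: int, seed: int = 0) -> stmask.SpatialGraph:
    g_rng = np.random.default_rng(seed)
    return stmask.build_knn_graph(g_rng.normal(size=(n, 2)), k=k)


@pytest.fixture
def tiny_graph():
    """6-node KNN graph on random coordinates."""
    return random_graph(6, 2, seed=1)
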