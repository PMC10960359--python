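"""Shared fixtures: tiny hand-built networks and a session-scoped benchmark."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netprop import (
    BenchmarkConfig,
    ForestConfig,
    GeneNetwork,
    GeneSet,
    LabelSpec,
    build_feature_matrix,
    cross_validate,
    generate_benchmark,
)


@pytest.fixture
def two_node_net() -> GeneNetwork:
    return GeneNetwork(nx.Graph([("A", "B")]))


@pytest.fixture
def path3_net() -> GeneNetwork:
    return GeneNetwork(nx.Graph([("A", "B"), ("B", "C")]))


def random_connected_graph(n: int, rng: np.random.Generator,
                           p: float | None = None) -> GeneNetwork:
    """Erdos-Renyi graph conditioned on connectivity (resample until connected)."""
    if p is None:
        p = min(1.0, 3.0 * np.log(n) / n)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    return GeneNetwork(nx.relabel_nodes(g, {i: f"g{i:04d}" for i in g.nodes()}))


def heavy_tailed_graph(n: int, seed: int, gamma: float = 2.5) -> GeneNetwork:
    """Configuration-model graph with a power-law-ish degree sequence,
    simplified (no self-loops/multi-edges) and reduced to its main component."""
    rng = np.random.default_rng(seed)
    deg = np.clip(rng.zipf(gamma, size=n), 1, n // 10)
    if deg.sum() % 2:
        deg[0] += 1
    g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    comp = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    g = g.subgraph(comp).copy()
    return GeneNetwork(nx.relabel_nodes(g, {i: f"g{i:04d}" for i in g.nodes()}))


@pytest.fixture(scope="session")
def default_benchmark():
    """The planted-module benchmark at its default study conditions, seed 7."""
    return generate_benchmark(BenchmarkConfig(rng_seed=7))


@pytest.fixture(scope="session")
def default_features(default_benchmark):
    return build_feature_matrix(
        default_benchmark.network, default_benchmark.seed_sets
    )


@pytest.fixture(scope="session")
def default_cv(default_benchmark, default_features):
    spec = LabelSpec(
        positives=default_benchmark.positives,
        exclusion=default_benchmark.exclusion,
        rng_seed=7,
    )
    return cross_validate(default_features, spec, ForestConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down benchmark for fast pipeline smoke tests."""
    return BenchmarkConfig(
        n_nodes=400, module_size=40, n_seed_lists=5, seed_list_size=20,
        n_positives=20, rng_seed=3,
    )
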