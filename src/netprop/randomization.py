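"""Degree-preserving network randomization (the propagation negative control).

Repeated double-edge swaps — (a,b),(c,d) -> (a,c),(b,d), rejecting self-loops
and duplicate edges — shuffle topology while conserving every node's degree
exactly. The conventional burn-in of 10 successful swaps per edge gives an
approximately uniform sample from the fixed-degree-sequence ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .network_io import GeneNetwork

logger = logging.getLogger(__name__)


class RandomizationError(RuntimeError):
    """Swap budget exhausted without reaching the target swap count."""


@dataclass(frozen=True)
class RandomizationConfig:
    swaps_per_edge: float = 10.0
    rng_seed: int = 0
    max_tries_factor: int = 100

    def __post_init__(self) -> None:
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be positive")
        if self.max_tries_factor < 1:
            raise ValueError("max_tries_factor must be >= 1")


def degree_preserving_randomize(
    net: GeneNetwork, cfg: RandomizationConfig = RandomizationConfig()
) -> GeneNetwork:
    """Randomize edges by double-edge swaps, preserving the degree sequence.

    Performs ``swaps_per_edge * |E|`` successful swaps (networkx
    ``double_edge_swap``); deterministic for a fixed ``rng_seed``. Graphs on
    fewer than four nodes admit no legal swap and are returned unchanged.
    Edge weights are not preserved (the null is topological); the output may
    be disconnected — re-extract the main component before propagation.
    """
    if net.n_edges < 2:
        raise ValueError("randomization needs at least 2 edges")
    if net.n_nodes < 4:
        logger.info("fewer than 4 nodes: no legal double-edge swap, copying input")
        return GeneNetwork(net.graph.copy())
    n_swaps = max(1, round(cfg.swaps_per_edge * net.n_edges))
    shuffled = nx.Graph()
    shuffled.add_nodes_from(net.nodes)
    shuffled.add_edges_from(net.edges())
    try:
        nx.double_edge_swap(
            shuffled,
            nswap=n_swaps,
            max_tries=cfg.max_tries_factor * n_swaps,
            seed=cfg.rng_seed,
        )
    except nx.NetworkXAlgorithmError as exc:
        raise RandomizationError(
            f"could not complete {n_swaps} swaps within "
            f"{cfg.max_tries_factor * n_swaps} attempts: {exc}"
        ) from exc
    out = GeneNetwork(shuffled)
    if not out.is_connected():
        logger.info("randomized network is disconnected; extract main component")
    return out
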