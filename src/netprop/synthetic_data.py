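"""Synthetic benchmark with a planted disease module.

Generates a connected preferential-attachment network (heavy-tailed degrees,
like real protein-interaction networks), plants a "disease module" — a random
node set — and derives everything the pipeline needs from it: K seed lists
that mix module and background genes, a positive-label set drawn from the
module, and an exclusion list (the whole module) emulating a curated disease
database. Signal strength is controlled by ``seed_overlap_frac``, the
fraction of each seed list drawn from the module; at 0 the benchmark carries
no recoverable signal and classification should sit at chance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .network_io import GeneNetwork, GeneSet, write_edge_list, write_gene_sets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Sizes and rates of the planted-module benchmark.

    Defaults emulate the scale of the emulated study design at desk size:
    ten seed lists of ~60 genes over a 2000-node network, half of each list
    from a 100-gene module, 50 positives. ``densify_p`` optionally adds
    module-internal edges with the given probability to strengthen the
    topological signal beyond pure seed overlap.
    """

    n_nodes: int = 2000
    attachment_edges: int = 3
    module_size: int = 100
    n_seed_lists: int = 10
    seed_list_size: int = 60
    seed_overlap_frac: float = 0.5
    n_positives: int = 50
    densify_p: float = 0.0
    exclude_positives_from_seeds: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.module_size < self.n_nodes:
            raise ValueError("module_size must be in (0, n_nodes)")
        if not 0.0 <= self.seed_overlap_frac <= 1.0:
            raise ValueError("seed_overlap_frac must be in [0, 1]")
        if self.n_positives > self.module_size:
            raise ValueError("n_positives cannot exceed module_size")
        n_from_module = round(self.seed_overlap_frac * self.seed_list_size)
        module_pool = self.module_size - (
            self.n_positives if self.exclude_positives_from_seeds else 0
        )
        if n_from_module > module_pool:
            raise ValueError(
                "seed_overlap_frac x seed_list_size exceeds the module pool "
                "available to seed lists"
            )
        if self.seed_list_size - n_from_module > self.n_nodes - self.module_size:
            raise ValueError("seed lists larger than the background pool")
        if not 0.0 <= self.densify_p <= 1.0:
            raise ValueError("densify_p must be in [0, 1]")


@dataclass(frozen=True)
class Benchmark:
    network: GeneNetwork
    seed_sets: tuple[GeneSet, ...]
    positives: GeneSet
    exclusion: GeneSet
    module: GeneSet
    config: BenchmarkConfig


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_benchmark(cfg: BenchmarkConfig = BenchmarkConfig()) -> Benchmark:
    """Build the planted-module benchmark, fully reproducible from rng_seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    graph_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment_edges,
                                 seed=graph_seed)
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes()})
    genes = np.array(sorted(g.nodes()))

    module = rng.choice(genes, size=cfg.module_size, replace=False)
    module_set = set(module)
    background = np.array([x for x in genes if x not in module_set])
    positives = rng.choice(module, size=cfg.n_positives, replace=False)

    if cfg.densify_p > 0:
        for i in range(cfg.module_size):
            for j in range(i + 1, cfg.module_size):
                if rng.random() < cfg.densify_p:
                    g.add_edge(module[i], module[j])

    if cfg.exclude_positives_from_seeds:
        positive_set = set(positives)
        module_pool = np.array([x for x in module if x not in positive_set])
    else:
        module_pool = module
    n_from_module = round(cfg.seed_overlap_frac * cfg.seed_list_size)
    n_from_background = cfg.seed_list_size - n_from_module
    seed_sets = []
    for k in range(cfg.n_seed_lists):
        members: list[str] = []
        if n_from_module:
            members += list(
                rng.choice(module_pool, size=n_from_module, replace=False)
            )
        if n_from_background:
            members += list(
                rng.choice(background, size=n_from_background, replace=False)
            )
        seed_sets.append(
            GeneSet(name=f"seedlist_{k + 1:02d}", genes=tuple(members))
        )
    return Benchmark(
        network=GeneNetwork(g),
        seed_sets=tuple(seed_sets),
        positives=GeneSet(name="positives", genes=tuple(positives)),
        exclusion=GeneSet(name="exclusion", genes=tuple(module)),
        module=GeneSet(name="module", genes=tuple(module)),
        config=cfg,
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> dict[str, str]:
    """Write network, seed lists, labels and a config manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": str(outdir / "network.tsv"),
        "seed_sets": str(outdir / "seed_lists.gmt"),
        "positives": str(outdir / "positives.txt"),
        "exclusion": str(outdir / "exclusion.txt"),
        "manifest": str(outdir / "benchmark.json"),
    }
    write_edge_list(bench.network, paths["network"])
    write_gene_sets(bench.seed_sets, paths["seed_sets"])
    Path(paths["positives"]).write_text("\n".join(bench.positives.genes) + "\n")
    Path(paths["exclusion"]).write_text("\n".join(bench.exclusion.genes) + "\n")
    manifest = {
        "config": dataclasses.asdict(bench.config),
        "module": list(bench.module.genes),
        "files": {k: v for k, v in paths.items() if k != "manifest"},
    }
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
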