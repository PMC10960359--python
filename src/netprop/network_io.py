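"""Reading, validation and canonicalization of interaction networks and gene sets.

Gene identifiers are opaque, case-sensitive strings; no symbol/ID mapping is
attempted. Networks are undirected, simple (no self-loops, no multi-edges)
and optionally weighted; the main connected component is extracted before
propagation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input file (bad row, wrong column count, empty file)."""


class GeneSetError(ValueError):
    """An invalid gene-set collection (empty set, duplicate names)."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise GeneSetError(f"gene set {self.name!r} contains duplicates")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneNetwork:
    """An undirected gene-gene interaction network.

    Wraps a :class:`networkx.Graph` with a fixed node order (file/insertion
    order) and a cached sparse adjacency. Edge weights default to 1.0; the
    network is treated as weighted only if some weight differs from 1.
    """

    def __init__(self, graph: nx.Graph):
        for u, v in graph.edges():
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
        self._graph = graph
        self._nodes: tuple[str, ...] = tuple(graph.nodes())
        self._index = {g: i for i, g in enumerate(self._nodes)}
        self._adjacency: sp.csr_matrix | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edges(self) -> Iterable[tuple[str, str]]:
        return self._graph.edges()

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency in node order (weights default 1.0)."""
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self._graph, nodelist=self._nodes, weight="weight", format="csr"
            ).astype(float)
        return self._adjacency

    def degrees(self) -> np.ndarray:
        """Weighted degree of every node, in node order."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def is_weighted(self) -> bool:
        return any(
            d.get("weight", 1.0) != 1.0 for _, _, d in self._graph.edges(data=True)
        )

    def is_connected(self) -> bool:
        return nx.is_connected(self._graph)

    def fingerprint(self) -> dict:
        """Node/edge counts plus a content hash, for provenance headers."""
        h = hashlib.sha256()
        for u, v, d in sorted(
            (min(u, v), max(u, v), d.get("weight", 1.0))
            for u, v, d in self._graph.edges(data=True)
        ):
            h.update(f"{u}\t{v}\t{d!r}\n".encode())
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "hash": h.hexdigest()[:16],
        }


def read_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    has_header: bool = False,
) -> GeneNetwork:
    """Read a TSV edge list (source, target[, weight]) into a GeneNetwork.

    '#'-prefixed comment lines and blank lines are skipped. Duplicate rows and
    reversed duplicates collapse to a single edge (first weight wins);
    self-loop rows are dropped with a warning.
    """
    path = Path(path)
    graph = nx.Graph()
    n_data_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if has_header and n_data_rows == 0 and not graph.number_of_nodes():
                has_header = False  # consume exactly one header line
                continue
            parts = line.split(delimiter)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            weight = 1.0
            if len(parts) >= 3 and parts[2].strip():
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
            n_data_rows += 1
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                continue
            if not graph.has_edge(u, v):
                graph.add_edge(u, v, weight=weight)
    if n_data_rows == 0:
        raise ParseError(f"{path}: no edges found")
    return GeneNetwork(graph)


def write_edge_list(net: GeneNetwork, path: str | Path, delimiter: str = "\t") -> None:
    """Write the canonical edge list: one row per edge, weight column only if weighted."""
    path = Path(path)
    weighted = net.is_weighted
    with path.open("w") as fh:
        for u, v, d in net.graph.edges(data=True):
            if weighted:
                fh.write(f"{u}{delimiter}{v}{delimiter}{d.get('weight', 1.0):g}\n")
            else:
                fh.write(f"{u}{delimiter}{v}\n")


def main_component(net: GeneNetwork) -> GeneNetwork:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the component containing the lexicographically
    smallest node, so the result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    best_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == best_size]
    best = min(tied, key=lambda c: c[0])
    keep = set(best)
    ordered = [g for g in net.nodes if g in keep]
    sub = nx.Graph()
    sub.add_nodes_from(ordered)
    for u, v, d in net.graph.edges(data=True):
        if u in keep and v in keep:
            sub.add_edge(u, v, **d)
    if len(best) < net.n_nodes:
        logger.info(
            "main component retains %d/%d nodes (%.1f%%)",
            len(best), net.n_nodes, 100 * len(best) / net.n_nodes,
        )
    return GeneNetwork(sub)


def _dedup(genes: Sequence[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(genes))


def read_gene_sets(path: str | Path, format: str = "plain") -> list[GeneSet]:
    """Read gene sets from a plain list (one gene per line) or a GMT file.

    Plain files yield a single set named after the file stem. GMT rows are
    ``name<TAB>description<TAB>member...``. Members are deduplicated
    preserving order; an empty set or a duplicate set name is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    if format == "plain":
        genes = _dedup(
            [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        )
        if not genes:
            raise GeneSetError(f"{path}: empty gene set")
        sets.append(GeneSet(name=path.stem, genes=genes))
    elif format == "gmt":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT rows need name, description, members"
                )
            name = parts[0]
            genes = _dedup([g.strip() for g in parts[2:] if g.strip()])
            if not genes:
                raise GeneSetError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, genes=genes))
        if not sets:
            raise GeneSetError(f"{path}: no gene sets found")
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise GeneSetError(f"{path}: duplicate gene-set names {dupes}")
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write a collection of gene sets as GMT."""
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, ""] + list(s.genes)) + "\n")
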