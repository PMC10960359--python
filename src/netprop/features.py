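"""Assembly of the genes x seed-sets matrix of normalized propagation scores.

Each seed list contributes one feature column: the normalized propagation
score of every network gene under that list's 1/s seed vector. The uniform-
seed baseline is computed once per network/config and shared across columns.
The classifier's universe is the network's main component; genes outside the
network get no feature row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network_io import GeneNetwork, GeneSet
from .propagation import (
    PropagationConfig,
    build_seed_vector,
    normalize_scores,
    propagate,
    uniform_baseline,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    """Genes x seed-sets matrix of normalized propagation scores."""

    genes: tuple[str, ...]
    set_names: tuple[str, ...]
    values: np.ndarray  # shape (len(genes), len(set_names))
    provenance: dict

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.set_names)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.genes)} genes x {len(self.set_names)} sets"
            )
        if not np.isfinite(v).all():
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes),
                            columns=list(self.set_names))

    def rows_for(self, genes: Sequence[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from feature matrix: {missing[:10]}")
        return self.values[[index[g] for g in genes]]


def build_feature_matrix(
    net: GeneNetwork,
    seed_sets: Sequence[GeneSet],
    cfg: PropagationConfig = PropagationConfig(),
) -> FeatureMatrix:
    """One normalized-propagation column per seed set, in input order."""
    names = [s.name for s in seed_sets]
    if len(set(names)) != len(names):
        raise ValueError("seed-set names must be unique")
    if not seed_sets:
        raise ValueError("at least one seed set is required")
    baseline = uniform_baseline(net, cfg)
    columns = []
    for s in seed_sets:
        seed = build_seed_vector(net, s)  # raises if fully absent
        raw = propagate(net, seed, cfg)
        columns.append(normalize_scores(raw, net, cfg, baseline=baseline).values)
    provenance = {
        "alpha": cfg.alpha,
        "tol": cfg.tol,
        "max_iter": cfg.max_iter,
        "operator_norm": cfg.operator_norm,
        **net.fingerprint(),
    }
    return FeatureMatrix(
        genes=net.nodes,
        set_names=tuple(names),
        values=np.column_stack(columns),
        provenance=provenance,
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """TSV with '#key=value' provenance header lines, 15 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in fm.provenance.items():
            fh.write(f"# {key}={value}\n")
        fh.write("gene\t" + "\t".join(fm.set_names) + "\n")
        for i, gene in enumerate(fm.genes):
            fh.write(
                gene + "\t" + "\t".join(f"{x:.15g}" for x in fm.values[i]) + "\n"
            )


def read_feature_matrix(
    path: str | Path, net: GeneNetwork | None = None
) -> FeatureMatrix:
    """Read a feature-matrix TSV; warn if provenance mismatches ``net``."""
    path = Path(path)
    provenance: dict = {}
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                provenance[key] = value if key == "hash" else _coerce(value)
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header) + 1} columns, "
                    f"got {len(parts)}"
                )
            genes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if header is None or not rows:
        raise ValueError(f"{path}: no feature rows found")
    if net is not None:
        fp = net.fingerprint()
        if any(provenance.get(k) != fp[k] for k in ("n_nodes", "n_edges", "hash")):
            logger.warning(
                "%s: provenance does not match the supplied network "
                "(stored %s, network %s)",
                path,
                {k: provenance.get(k) for k in ("n_nodes", "n_edges", "hash")},
                fp,
            )
    return FeatureMatrix(
        genes=tuple(genes),
        set_names=tuple(header),
        values=np.array(rows),
        provenance=provenance,
    )


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value
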