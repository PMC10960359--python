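"""Random-walk-with-restart propagation and degree-bias normalization.

The diffusion iterates ``F <- alpha * W @ F + (1 - alpha) * Y`` from ``F = Y``
until the maximum absolute change drops below ``tol``. ``W`` is the
symmetrically normalized adjacency ``D^{-1/2} A D^{-1/2}`` by default (its
spectral radius is <= 1, so the map is an alpha-contraction and the fixed
point equals the direct solve ``(1 - alpha) (I - alpha W)^{-1} Y``); a
row-stochastic operator ``D^{-1} A`` is available as an alternative.

Raw scores are biased toward hubs. The normalization divides each raw score
by the score the same node receives under a uniform seed (mass 1/n on every
node), a centrality-like baseline: a node scores above 1 only when it is
closer to the seed set than its connectivity alone predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .network_io import GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

OperatorNorm = Literal["symmetric", "row_stochastic"]

_DENSE_SOLVE_GUARD = 5000


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance within max_iter."""


@dataclass(frozen=True)
class PropagationConfig:
    """Parameters of the propagation operator.

    alpha is the weight of the network-diffusion term; 1 - alpha is the
    restart (seed) weight. The default 0.8 puts most mass on diffusion.
    """

    alpha: float = 0.8
    tol: float = 1e-8
    max_iter: int = 1000
    operator_norm: OperatorNorm = "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.operator_norm not in ("symmetric", "row_stochastic"):
            raise ValueError(f"unknown operator_norm {self.operator_norm!r}")


@dataclass(frozen=True)
class SeedVector:
    """Per-node nonnegative initial mass, aligned to a network's node order."""

    genes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("seed mass must be nonnegative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ScoreVector:
    """Per-node scores aligned to a network's node order.

    kind is 'raw' (propagation fixed point), 'normalized' (raw divided by the
    uniform-seed baseline) or 'classifier' (forest vote fraction).
    """

    genes: tuple[str, ...]
    values: np.ndarray
    kind: Literal["raw", "normalized", "classifier"] = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("scores must be finite")
        object.__setattr__(self, "values", v)

    def __getitem__(self, gene: str) -> float:
        return float(self.values[self.genes.index(gene)])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.genes, map(float, self.values)))

    def write_tsv(self, path: str | Path) -> None:
        """Two-column TSV (gene, score), sorted by descending score."""
        order = np.argsort(-self.values, kind="stable")
        with Path(path).open("w") as fh:
            fh.write(f"# kind={self.kind}\n")
            for i in order:
                fh.write(f"{self.genes[i]}\t{self.values[i]:.12g}\n")


def build_seed_vector(net: GeneNetwork, seeds: GeneSet) -> SeedVector:
    """Uniform mass 1/s on the s seed genes present in the network.

    Seed genes absent from the network are dropped with a warning and do not
    count toward s, so the retained mass always sums to 1.
    """
    present = [g for g in seeds.genes if g in net]
    absent = [g for g in seeds.genes if g not in net]
    if not present:
        raise ValueError(f"no gene of seed set {seeds.name!r} is in the network")
    if absent:
        logger.warning(
            "seed set %r: %d/%d genes absent from network (e.g. %s)",
            seeds.name, len(absent), len(seeds), ", ".join(absent[:5]),
        )
    values = np.zeros(net.n_nodes)
    values[[net.index_of(g) for g in present]] = 1.0 / len(present)
    return SeedVector(genes=net.nodes, values=values)


def normalize_adjacency(
    net: GeneNetwork, mode: OperatorNorm = "symmetric"
) -> sp.csr_matrix:
    """Degree-normalized adjacency operator.

    symmetric: D^{-1/2} A D^{-1/2}; row_stochastic: D^{-1} A.
    """
    deg = net.degrees()
    if (deg == 0).any():
        zero = [g for g, d in zip(net.nodes, deg) if d == 0]
        raise ValueError(f"zero-degree nodes cannot be normalized: {zero[:5]}")
    A = net.adjacency
    if mode == "symmetric":
        d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
        return (d_inv_sqrt @ A @ d_inv_sqrt).tocsr()
    if mode == "row_stochastic":
        return (sp.diags(1.0 / deg) @ A).tocsr()
    raise ValueError(f"unknown operator norm {mode!r}")


def _check_alignment(net: GeneNetwork, genes: tuple[str, ...]) -> None:
    if genes != net.nodes:
        raise ValueError("node order mismatch between vector and network")


def propagate(
    net: GeneNetwork,
    seed: SeedVector,
    cfg: PropagationConfig = PropagationConfig(),
    return_residuals: bool = False,
) -> ScoreVector | tuple[ScoreVector, list[float]]:
    """Iterate F <- alpha*W*F + (1-alpha)*Y to its fixed point.

    Starts from F = Y and stops when the max absolute change is below
    cfg.tol; raises ConvergenceError (with the last residual) if cfg.max_iter
    is reached first.
    """
    _check_alignment(net, seed.genes)
    W = normalize_adjacency(net, cfg.operator_norm)
    y = seed.values
    f = y.copy()
    residuals: list[float] = []
    for _ in range(cfg.max_iter):
        f_next = cfg.alpha * (W @ f) + (1.0 - cfg.alpha) * y
        residual = float(np.max(np.abs(f_next - f)))
        residuals.append(residual)
        f = f_next
        if residual < cfg.tol:
            result = ScoreVector(genes=net.nodes, values=f, kind="raw")
            return (result, residuals) if return_residuals else result
    raise ConvergenceError(
        f"no convergence after {cfg.max_iter} iterations "
        f"(last residual {residuals[-1]:.3e}, tol {cfg.tol:.3e})"
    )


def propagate_direct(
    net: GeneNetwork,
    seed: SeedVector,
    cfg: PropagationConfig = PropagationConfig(),
) -> ScoreVector:
    """Exact fixed point by direct linear solve of (I - alpha W) F = (1-alpha) Y.

    Dense solve, guarded to networks of at most 5000 nodes; intended as the
    oracle against which the iterative solver is verified.
    """
    _check_alignment(net, seed.genes)
    n = net.n_nodes
    if n > _DENSE_SOLVE_GUARD:
        raise ValueError(
            f"direct solve limited to {_DENSE_SOLVE_GUARD} nodes, got {n}"
        )
    W = normalize_adjacency(net, cfg.operator_norm).toarray()
    lhs = np.eye(n) - cfg.alpha * W
    f = np.linalg.solve(lhs, (1.0 - cfg.alpha) * seed.values)
    return ScoreVector(genes=net.nodes, values=f, kind="raw")


def uniform_baseline(
    net: GeneNetwork, cfg: PropagationConfig = PropagationConfig()
) -> ScoreVector:
    """Propagation of the uniform seed (1/n everywhere): the centrality baseline.

    On a connected network the baseline is strictly positive, converging (as
    alpha -> 1) to the operator's dominant eigenvector, i.e. an eigenvector-
    centrality-like profile of pure degree signal.
    """
    uniform = SeedVector(
        genes=net.nodes, values=np.full(net.n_nodes, 1.0 / net.n_nodes)
    )
    return propagate(net, uniform, cfg)


def normalize_scores(
    raw: ScoreVector,
    net: GeneNetwork,
    cfg: PropagationConfig = PropagationConfig(),
    baseline: ScoreVector | None = None,
) -> ScoreVector:
    """Divide raw scores by the uniform-seed baseline to remove degree bias.

    A precomputed baseline (from :func:`uniform_baseline` with the same net
    and cfg) may be passed to amortize the cost across many seed sets.
    """
    _check_alignment(net, raw.genes)
    if baseline is None:
        baseline = uniform_baseline(net, cfg)
    _check_alignment(net, baseline.genes)
    if (baseline.values <= 0).any():
        raise ValueError("baseline not strictly positive; network connected?")
    return ScoreVector(
        genes=net.nodes, values=raw.values / baseline.values, kind="normalized"
    )
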