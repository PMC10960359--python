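"""Operating-point selection and group-vs-random rank validation.

Cutoffs are chosen by exhaustive search over observed score values under the
inclusive decision rule ``predict positive iff score >= cutoff``; criteria are
specificity x sensitivity (classification operating point) or precision +
recall (candidate-list selection). Gene groups are validated by comparing
their classifier scores against an equally sized random draw from the scored
universe with a Wilcoxon-family test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .propagation import ScoreVector

logger = logging.getLogger(__name__)

Criterion = Literal["spec_times_sens", "prec_plus_rec"]


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    criterion: Criterion
    achieved: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def confusion(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass(frozen=True)
class RankTestResult:
    p_value: float
    direction: Literal["higher", "lower", "equal"]
    group_median: float
    control_median: float
    control_scores: np.ndarray
    test: str


def _criterion_value(
    criterion: Criterion, tp: int, fp: int, tn: int, fn: int
) -> float:
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    if criterion == "spec_times_sens":
        return spec * sens
    if criterion == "prec_plus_rec":
        prec = tp / (tp + fp) if tp + fp else 0.0
        return prec + sens
    raise ValueError(f"unknown criterion {criterion!r}")


def optimal_cutoff(
    scores: Sequence[float] | ScoreVector,
    labels: Sequence[int],
    criterion: Criterion = "spec_times_sens",
) -> CutoffResult:
    """Exhaustively choose the score cutoff maximizing the criterion.

    Candidates are every distinct observed score (each realizes a distinct
    confusion table under ``score >= cutoff``) plus +inf for the all-negative
    rule; ties are broken toward the smallest cutoff (most inclusive).
    """
    s = np.asarray(
        scores.values if isinstance(scores, ScoreVector) else scores, dtype=float
    )
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to choose a cutoff")
    best: CutoffResult | None = None
    for cut in [*np.unique(s), np.inf]:
        pred = s >= cut
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = int(np.sum(~pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        value = _criterion_value(criterion, tp, fp, tn, fn)
        if best is None or value > best.achieved:
            best = CutoffResult(
                cutoff=float(cut), criterion=criterion, achieved=value,
                tp=tp, fp=fp, tn=tn, fn=fn,
            )
    assert best is not None
    return best


def group_rank_test(
    scores_for_group: Sequence[float] | Mapping[str, float],
    universe_scores: ScoreVector | Mapping[str, float],
    rng_seed: int = 0,
    test: Literal["rank_sum", "signed_rank"] = "rank_sum",
    group_genes: Sequence[str] | None = None,
    degrees: Mapping[str, float] | None = None,
    n_degree_bins: int = 10,
) -> RankTestResult:
    """Two-sided Wilcoxon test of a gene group against random control genes.

    Samples ``len(group)`` control genes from the universe excluding the
    group (by gene name when group scores are a mapping or ``group_genes``
    is given). ``rank_sum`` (default) treats the samples as independent;
    ``signed_rank`` pairs group and control by sampled index. When
    ``degrees`` is provided, controls are matched to the group's degree
    distribution via quantile bins.
    """
    if isinstance(scores_for_group, Mapping):
        group_genes = list(scores_for_group.keys())
        group = np.asarray(list(scores_for_group.values()), dtype=float)
    else:
        group = np.asarray(scores_for_group, dtype=float)
    if group.size == 0:
        raise ValueError("group is empty")
    uni = (
        universe_scores.to_dict()
        if isinstance(universe_scores, ScoreVector)
        else dict(universe_scores)
    )
    excluded = set(group_genes or [])
    pool_genes = [g for g in uni if g not in excluded]
    if len(pool_genes) < group.size:
        raise ValueError(
            f"control pool ({len(pool_genes)}) smaller than group ({group.size})"
        )
    rng = np.random.default_rng(rng_seed)
    if degrees is not None and group_genes is not None:
        controls = _degree_matched_controls(
            group_genes, pool_genes, degrees, n_degree_bins, rng
        )
    else:
        controls = list(rng.choice(pool_genes, size=group.size, replace=False))
    control = np.asarray([uni[g] for g in controls], dtype=float)
    if test == "rank_sum":
        res = stats.mannwhitneyu(group, control, alternative="two-sided")
    elif test == "signed_rank":
        diff = group - control
        if np.all(diff == 0):
            return RankTestResult(
                p_value=1.0, direction="equal",
                group_median=float(np.median(group)),
                control_median=float(np.median(control)),
                control_scores=control, test=test,
            )
        res = stats.wilcoxon(group, control, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    gm, cm = float(np.median(group)), float(np.median(control))
    direction = "higher" if gm > cm else ("lower" if gm < cm else "equal")
    return RankTestResult(
        p_value=float(res.pvalue), direction=direction,
        group_median=gm, control_median=cm,
        control_scores=control, test=test,
    )


def _degree_matched_controls(
    group_genes: Sequence[str],
    pool_genes: Sequence[str],
    degrees: Mapping[str, float],
    n_bins: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample one control per group gene from the same degree-quantile bin."""
    pool_deg = np.asarray([degrees[g] for g in pool_genes], dtype=float)
    edges = np.quantile(pool_deg, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.inf
    pool_bins = np.searchsorted(edges, pool_deg, side="right") - 1
    by_bin: dict[int, list[str]] = {}
    for g, b in zip(pool_genes, pool_bins):
        by_bin.setdefault(int(b), []).append(g)
    controls: list[str] = []
    taken: set[str] = set()
    for g in group_genes:
        b = int(np.searchsorted(edges, float(degrees[g]), side="right") - 1)
        candidates = [c for c in by_bin.get(b, []) if c not in taken]
        if not candidates:  # fall back to the whole remaining pool
            candidates = [c for c in pool_genes if c not in taken]
        if not candidates:
            raise ValueError("control pool exhausted during degree matching")
        pick = candidates[int(rng.integers(len(candidates)))]
        controls.append(pick)
        taken.add(pick)
    return controls
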