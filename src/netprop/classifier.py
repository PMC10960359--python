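"""Random-forest classification on propagation features.

Curated positives plus uniformly sampled negatives (drawn once per
experiment from network genes outside an exclusion list) train a random
forest whose positive-class vote fraction is the per-gene association score.
Performance is estimated by stratified k-fold cross-validation: per-fold
AUROC/AUPRC, their arithmetic means, vertically averaged curves on a common
grid, and pooled out-of-fold scores for cutoff selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix
from .network_io import GeneNetwork, GeneSet
from .propagation import ScoreVector

logger = logging.getLogger(__name__)

_CURVE_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class LabelSpec:
    """Positive labels, the exclusion pool, and the negative sampling ratio.

    ``exclusion`` lists genes ineligible as negatives (it must contain all
    positives — e.g. every gene with any curated evidence). One negative is
    drawn per positive at the default ratio 1.0.
    """

    positives: GeneSet
    exclusion: GeneSet
    negative_ratio: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.positives.genes) - set(self.exclusion.genes)
        if missing:
            raise ValueError(
                f"positives not covered by exclusion list: {sorted(missing)[:10]}"
            )
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (scikit-learn defaults)."""

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def make_estimator(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            random_state=self.rng_seed,
        )


@dataclass(frozen=True)
class FoldResult:
    auroc: float
    auprc: float
    roc_points: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr_points: tuple[np.ndarray, np.ndarray]  # (recall, precision)


@dataclass(frozen=True)
class CVResult:
    """Per-fold and mean cross-validation summaries plus out-of-fold scores."""

    per_fold: tuple[FoldResult, ...]
    mean_auroc: float
    mean_auprc: float
    oof_scores: dict[str, float]  # labeled gene -> out-of-fold score
    oof_labels: dict[str, int]
    mean_roc: tuple[np.ndarray, np.ndarray]  # grid fpr, mean tpr
    mean_pr: tuple[np.ndarray, np.ndarray]  # grid recall, mean precision


@dataclass
class TrainedModel:
    """A fitted forest bound to the feature-column order it was trained on."""

    estimator: RandomForestClassifier
    set_names: tuple[str, ...]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(Path(path))
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def sample_negatives(net: GeneNetwork, spec: LabelSpec) -> GeneSet:
    """Uniform sample (without replacement) of negatives from the eligible pool.

    The pool is the network's genes minus the exclusion list; the sample size
    is round(negative_ratio x number of positives present in the network).
    """
    excluded = set(spec.exclusion.genes)
    pool = [g for g in net.nodes if g not in excluded]
    n_pos = sum(1 for g in spec.positives.genes if g in net)
    if n_pos == 0:
        raise ValueError("no positive gene is present in the network")
    n_neg = round(spec.negative_ratio * n_pos)
    if len(pool) < n_neg:
        raise ValueError(
            f"negative pool too small: need {n_neg}, have {len(pool)} "
            f"({net.n_nodes} network genes, {len(excluded)} excluded)"
        )
    rng = np.random.default_rng(spec.rng_seed)
    chosen = rng.choice(len(pool), size=n_neg, replace=False)
    return GeneSet(name="negatives", genes=tuple(pool[i] for i in sorted(chosen)))


def _labeled_arrays(
    features: FeatureMatrix, positives: Sequence[str], negatives: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    genes = list(positives) + list(negatives)
    X = features.rows_for(genes)  # raises listing missing genes
    y = np.array([1] * len(positives) + [0] * len(negatives))
    return genes, X, y


def _interp_roc(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    return np.interp(_CURVE_GRID, fpr, tpr)


def _interp_pr(recall: np.ndarray, precision: np.ndarray) -> np.ndarray:
    # precision_recall_curve returns recall descending; flip for interp
    return np.interp(_CURVE_GRID, recall[::-1], precision[::-1])


def cross_validate(
    features: FeatureMatrix,
    labels: LabelSpec,
    forest: ForestConfig = ForestConfig(),
    folds: int = 5,
    negatives: GeneSet | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the forest on labeled genes.

    Negatives are sampled once for the whole experiment (pass ``negatives``
    to reuse an existing sample). Each fold trains on the rest and scores its
    held-out genes with the positive-class vote fraction; out-of-fold scores
    are retained so operating cutoffs can be chosen without leakage.
    """
    present = frozenset(features.genes)
    positives = [g for g in labels.positives.genes if g in present]
    dropped = len(labels.positives) - len(positives)
    if dropped:
        logger.warning(
            "%d/%d positives absent from the feature matrix; dropped",
            dropped, len(labels.positives),
        )
    if not positives:
        raise ValueError("no positive gene is present in the feature matrix")
    if negatives is None:
        universe = _as_network_like(features)
        negatives = sample_negatives(universe, labels)
    genes, X, y = _labeled_arrays(features, positives, negatives.genes)
    if min(np.bincount(y)) < folds:
        raise ValueError(
            f"need >= {folds} genes per class, have {np.bincount(y).tolist()}"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=forest.rng_seed)
    per_fold: list[FoldResult] = []
    oof_scores: dict[str, float] = {}
    roc_interp, pr_interp = [], []
    for train_idx, test_idx in splitter.split(X, y):
        est = forest.make_estimator()
        est.fit(X[train_idx], y[train_idx])
        prob = est.predict_proba(X[test_idx])[:, list(est.classes_).index(1)]
        fpr, tpr, _ = roc_curve(y[test_idx], prob)
        precision, recall_arr, _ = precision_recall_curve(y[test_idx], prob)
        per_fold.append(
            FoldResult(
                auroc=float(roc_auc_score(y[test_idx], prob)),
                auprc=float(average_precision_score(y[test_idx], prob)),
                roc_points=(fpr, tpr),
                pr_points=(recall_arr, precision),
            )
        )
        roc_interp.append(_interp_roc(fpr, tpr))
        pr_interp.append(_interp_pr(recall_arr, precision))
        for i, p in zip(test_idx, prob):
            oof_scores[genes[i]] = float(p)
    return CVResult(
        per_fold=tuple(per_fold),
        mean_auroc=float(np.mean([f.auroc for f in per_fold])),
        mean_auprc=float(np.mean([f.auprc for f in per_fold])),
        oof_scores=oof_scores,
        oof_labels={g: int(lab) for g, lab in zip(genes, y)},
        mean_roc=(_CURVE_GRID.copy(), np.mean(roc_interp, axis=0)),
        mean_pr=(_CURVE_GRID.copy(), np.mean(pr_interp, axis=0)),
    )


def _as_network_like(features: FeatureMatrix):
    """Adapter so sample_negatives can draw from a feature matrix's gene universe."""

    class _Universe:
        nodes = features.genes
        n_nodes = len(features.genes)
        _members = frozenset(features.genes)

        def __contains__(self, gene: str) -> bool:
            return gene in self._members

    return _Universe()


def train_full(
    features: FeatureMatrix,
    labels: LabelSpec,
    forest: ForestConfig = ForestConfig(),
    negatives: GeneSet | None = None,
) -> TrainedModel:
    """Train the forest on all labeled genes (no held-out fold)."""
    positives = [g for g in labels.positives.genes if g in features.genes]
    if not positives:
        raise ValueError("no positive gene is present in the feature matrix")
    if negatives is None:
        negatives = sample_negatives(_as_network_like(features), labels)
    _, X, y = _labeled_arrays(features, positives, negatives.genes)
    est = forest.make_estimator()
    est.fit(X, y)
    return TrainedModel(estimator=est, set_names=features.set_names)


def predict_scores(model: TrainedModel, features: FeatureMatrix) -> ScoreVector:
    """Positive-class vote fraction for every gene in the feature matrix."""
    if features.set_names != model.set_names:
        raise ValueError(
            f"feature columns {features.set_names} do not match the "
            f"model's training columns {model.set_names}"
        )
    prob = model.estimator.predict_proba(features.values)
    pos_col = list(model.estimator.classes_).index(1)
    return ScoreVector(
        genes=features.genes, values=prob[:, pos_col], kind="classifier"
    )
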