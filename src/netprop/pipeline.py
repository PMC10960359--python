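"""End-to-end pipeline: network -> propagation features -> forest -> scores.

Stages: main-component extraction; per-seed-list propagation and
normalization; feature-matrix assembly; stratified cross-validation; full
training; genome-wide scoring; operating-cutoff selection; optional
degree-preserving network null. A manifest (config, seeds, network
fingerprint, package version) is written so reruns are bit-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classifier import (
    CVResult,
    ForestConfig,
    LabelSpec,
    cross_validate,
    predict_scores,
    sample_negatives,
    train_full,
)
from .evaluation import optimal_cutoff
from .features import build_feature_matrix, write_feature_matrix
from .network_io import (
    GeneSet,
    main_component,
    read_edge_list,
    read_gene_sets,
)
from .propagation import PropagationConfig
from .randomization import RandomizationConfig, degree_preserving_randomize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    network_path: str
    seed_sets_path: str
    seed_sets_format: str  # 'gmt' or 'plain'
    positives_path: str
    exclusion_path: str
    output_dir: str
    propagation: PropagationConfig = PropagationConfig()
    forest: ForestConfig = ForestConfig()
    randomization: RandomizationConfig = RandomizationConfig()
    negative_ratio: float = 1.0
    folds: int = 5
    network_null: bool = False
    rng_seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key, cls in (
            ("propagation", PropagationConfig),
            ("forest", ForestConfig),
            ("randomization", RandomizationConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = cls(**raw[key])
        return RunConfig(**raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written as JSON)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load network"
    try:
        net = main_component(read_edge_list(cfg.network_path))
        if cfg.network_null:
            rnd_cfg = dataclasses.replace(
                cfg.randomization, rng_seed=cfg.rng_seed
            )
            net = main_component(degree_preserving_randomize(net, rnd_cfg))
            logger.info("degree-preserving null network in effect")

        stage = "load gene sets"
        seed_sets = read_gene_sets(cfg.seed_sets_path, cfg.seed_sets_format)
        positives = read_gene_sets(cfg.positives_path, "plain")[0]
        exclusion = read_gene_sets(cfg.exclusion_path, "plain")[0]
        labels = LabelSpec(
            positives=GeneSet("positives", positives.genes),
            exclusion=GeneSet(
                "exclusion", tuple(dict.fromkeys(exclusion.genes + positives.genes))
            ),
            negative_ratio=cfg.negative_ratio,
            rng_seed=cfg.rng_seed,
        )

        stage = "build features"
        features = build_feature_matrix(net, seed_sets, cfg.propagation)
        write_feature_matrix(features, out / "features.tsv")

        stage = "sample negatives"
        negatives = sample_negatives(net, labels)

        stage = "cross-validate"
        forest = dataclasses.replace(cfg.forest, rng_seed=cfg.rng_seed)
        cv = cross_validate(features, labels, forest, folds=cfg.folds,
                            negatives=negatives)
        _write_cv(cv, out)

        stage = "train full model"
        model = train_full(features, labels, forest, negatives=negatives)
        model.save(out / "model.joblib")

        stage = "predict"
        scores = predict_scores(model, features)
        _write_scores(scores, labels, negatives, out / "scores.tsv")

        stage = "select cutoffs"
        oof_genes = list(cv.oof_scores)
        oof_s = [cv.oof_scores[g] for g in oof_genes]
        oof_y = [cv.oof_labels[g] for g in oof_genes]
        cut_ss = optimal_cutoff(oof_s, oof_y, "spec_times_sens")
        cut_pr = optimal_cutoff(oof_s, oof_y, "prec_plus_rec")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "network": net.fingerprint(),
        "network_null": cfg.network_null,
        "n_seed_sets": len(seed_sets),
        "n_positives_in_network": sum(1 for g in positives.genes if g in net),
        "n_negatives": len(negatives),
        "cv": {
            "folds": cfg.folds,
            "mean_auroc": cv.mean_auroc,
            "mean_auprc": cv.mean_auprc,
            "per_fold_auroc": [f.auroc for f in cv.per_fold],
            "per_fold_auprc": [f.auprc for f in cv.per_fold],
        },
        "cutoffs": {
            "spec_times_sens": {
                "cutoff": cut_ss.cutoff,
                "achieved": cut_ss.achieved,
                "confusion": cut_ss.confusion,
            },
            "prec_plus_rec": {
                "cutoff": cut_pr.cutoff,
                "achieved": cut_pr.achieved,
                "confusion": cut_pr.confusion,
            },
        },
        "outputs": {
            "features": "features.tsv",
            "scores": "scores.tsv",
            "model": "model.joblib",
            "cv_metrics": "cv_metrics.tsv",
            "mean_roc": "mean_roc.tsv",
            "mean_pr": "mean_pr.tsv",
        },
    }
    (out / "manifest.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def _write_cv(cv: CVResult, out: Path) -> None:
    with (out / "cv_metrics.tsv").open("w") as fh:
        fh.write("fold\tauroc\tauprc\n")
        for i, f in enumerate(cv.per_fold, start=1):
            fh.write(f"{i}\t{f.auroc:.6f}\t{f.auprc:.6f}\n")
        fh.write(f"mean\t{cv.mean_auroc:.6f}\t{cv.mean_auprc:.6f}\n")
    for name, (grid, mean_vals), cols in (
        ("mean_roc", cv.mean_roc, ("fpr", "tpr")),
        ("mean_pr", cv.mean_pr, ("recall", "precision")),
    ):
        with (out / f"{name}.tsv").open("w") as fh:
            fh.write(f"{cols[0]}\t{cols[1]}\n")
            for x, yv in zip(grid, mean_vals):
                fh.write(f"{x:.4f}\t{yv:.6f}\n")


def _write_scores(scores, labels: LabelSpec, negatives, path: Path) -> None:
    pos = set(labels.positives.genes)
    neg = set(negatives.genes)
    import numpy as np

    order = np.argsort(-scores.values, kind="stable")
    with path.open("w") as fh:
        fh.write("gene\tscore\tlabel\n")
        for i in order:
            g = scores.genes[i]
            lab = "positive" if g in pos else ("negative" if g in neg else "")
            fh.write(f"{g}\t{scores.values[i]:.6f}\t{lab}\n")
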