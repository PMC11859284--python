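"""End-to-end pipeline: data -> contrastive pretraining -> probe -> audit.

Every artifact written carries the configuration hash, and a rerun with the
same config and seed reproduces the metrics file byte-identically (no
timestamps enter any artifact).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .config import RunConfig, config_hash
from .contrastive import PretrainResult, pretrain
from .encoder import save_checkpoint
from .landmarks import FeatureMatrix, save_labels_csv, save_matrix_csv
from .outliers import outlier_experiment
from .probe import cross_validate, evaluate, train_probe
from .synth import (
    SyntheticDatasetConfig,
    generate_dataset,
    motion_class,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _synth_stage(config: RunConfig) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Generate the unlabeled pretraining set and an independent labeled set."""
    classes = [
        motion_class(n, config.synth.noise_sd, config.synth.dropout_rate)
        for n in config.synth.class_names
    ]
    pretrain_data = generate_dataset(
        SyntheticDatasetConfig(
            classes=classes, frames_per_class=config.synth.frames_per_class, seed=config.seed
        )
    )
    labeled = generate_dataset(
        SyntheticDatasetConfig(
            classes=classes,
            frames_per_class=config.synth.frames_per_class,
            seed=config.seed + 1_000_003,
        )
    )
    return pretrain_data, labeled


def _split(labeled: FeatureMatrix, test_fraction: float, seed: int):
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    n = len(labeled)
    order = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return labeled.subset(order[n_test:]), labeled.subset(order[:n_test])


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run synth -> pretrain -> finetune -> evaluate [-> outliers].

    Returns the metrics dictionary; artifacts (landmark CSVs, encoder
    checkpoint, loss history, metrics JSON, optional outlier report) are
    written under ``output_dir``.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    timings: dict[str, float] = {}

    tic = time.perf_counter()
    pretrain_data, labeled = _synth_stage(config)
    timings["synth"] = time.perf_counter() - tic
    save_matrix_csv(pretrain_data, outdir / "pretrain_landmarks.csv")
    save_matrix_csv(labeled, outdir / "labeled_landmarks.csv")
    save_labels_csv(labeled, outdir / "labels.csv")

    tic = time.perf_counter()
    pretrain_cfg = config.pretrain
    if pretrain_cfg.seed != config.seed:
        pretrain_cfg = type(pretrain_cfg)(
            epochs=pretrain_cfg.epochs,
            batch_size=pretrain_cfg.batch_size,
            learning_rate=pretrain_cfg.learning_rate,
            weight_decay=pretrain_cfg.weight_decay,
            seed=config.seed,
        )
    result: PretrainResult = pretrain(
        pretrain_data,
        config.encoder,
        config.projector,
        config.ntxent,
        pretrain_cfg,
        config.augment,
    )
    timings["pretrain"] = time.perf_counter() - tic
    save_checkpoint(
        result.encoder, config.encoder, outdir / "encoder.npz", extra={"config_hash": chash}
    )
    loss_csv = "\n".join(
        ["epoch,mean_loss"]
        + [f"{i},{v:.10f}" for i, v in enumerate(result.loss_history)]
    )
    (outdir / "pretrain_loss.csv").write_text(loss_csv + "\n")

    probe_cfg = config.probe
    if probe_cfg.seed != config.seed:
        probe_cfg = type(probe_cfg)(
            epochs=probe_cfg.epochs,
            learning_rate=probe_cfg.learning_rate,
            milestones=probe_cfg.milestones,
            gamma=probe_cfg.gamma,
            folds=probe_cfg.folds,
            seed=config.seed,
        )
    train_set, test_set = _split(labeled, config.pipeline.test_fraction, config.seed)

    tic = time.perf_counter()
    fold_metrics, cv_mean = cross_validate(result.encoder, train_set, probe_cfg)
    head, _ = train_probe(result.encoder, train_set, probe_cfg)
    test_metrics = evaluate(head, result.encoder, test_set)
    timings["finetune_evaluate"] = time.perf_counter() - tic

    metrics = {
        "config_hash": chash,
        "seed": config.seed,
        "final_pretrain_loss": float(result.loss_history[-1]),
        "cv_folds": [f.to_dict() for f in fold_metrics],
        "cv_mean": cv_mean.to_dict(),
        "test": test_metrics.to_dict(),
    }

    if config.outlier.enabled:
        tic = time.perf_counter()
        rows = outlier_experiment(
            train_set,
            list(config.outlier.counts),
            motion_class(
                config.outlier.outlier_motion,
                config.synth.noise_sd,
                config.synth.dropout_rate,
            ),
            config.encoder,
            config.projector,
            config.ntxent,
            pretrain_cfg,
            probe_cfg,
            config.augment,
            seed=config.seed,
        )
        timings["outliers"] = time.perf_counter() - tic
        metrics["outlier_experiment"] = [r.to_dict() for r in rows]

    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    for stage, seconds in timings.items():
        logger.info("stage %-18s %.2f s", stage, seconds)
    return metrics
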