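"""End-to-end experiment orchestration: cross-validated training, metric
aggregation, explainability reports, and multi-model statistical comparison.

A run directory contains, per fold, a checkpoint and training history, plus
fold metrics CSV, aggregated metrics (mean +/- sd), the aggregated confusion
matrix, optional heatmap/IoU reports, and a manifest recording the full
configuration and seed so a persisted run re-executes identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import autodiff as ad
from .cam import explain as cam_explain
from .cam import localization_iou, save_heatmap_png
from .data import (
    LABELS,
    generate_phantoms,
    patient_kfold,
    preprocess,
    read_mias,
    read_phantom_set,
    splits_to_json,
)
from .errors import InputError
from .network import (
    BackboneConfig,
    TrainConfig,
    build_model,
    history_to_csv,
    predict_proba,
    save_checkpoint,
    train,
)
from .stats import (
    METRIC_COLUMNS,
    Q_ALPHA_REPORTED,
    aggregate_folds,
    auc_macro,
    cd_diagram,
    classification_metrics,
    confusion,
    rank_summary,
    read_fold_table,
)

logger = logging.getLogger(__name__)

RUNCONFIG_SCHEMA = 1

PRESETS = {
    "full": lambda: BackboneConfig(),
    "tiny": BackboneConfig.tiny,
    # minimal structure for smoke runs and tests
    "micro": lambda: BackboneConfig(
        stage_channels=(8, 16, 16, 16, 32), input_size=32, blocks=(1, 1, 1, 1)
    ),
}


@dataclass
class RunConfig:
    """Fully serializable description of one experiment run."""

    out_dir: str = "runs/experiment"
    # data: either a phantom specification or MIAS paths
    data_kind: str = "phantom"  # "phantom" | "mias" | "manifest"
    phantom_n: int = 120
    phantom_size: int = 64
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    mias_image_dir: str | None = None
    mias_info_file: str | None = None
    manifest_path: str | None = None
    # model / training
    variant: str = "hmc"
    preset: str = "tiny"
    folds: int = 5
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    augment: bool = True
    val_fraction: float = 0.1
    seed: int = 0
    # explainability
    xai_method: str | None = None  # "gradcam" | "gradcampp" | "scorecam"
    iou_threshold: float = 0.5
    save_heatmaps: bool = False
    schema: int = RUNCONFIG_SCHEMA

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if payload.get("schema", RUNCONFIG_SCHEMA) != RUNCONFIG_SCHEMA:
            raise InputError(f"unsupported run-config schema {payload.get('schema')}")
        payload["class_mix"] = tuple(payload.get("class_mix", (1 / 3, 1 / 3, 1 / 3)))
        return cls(**payload)


def _setup_logging(run_dir: Path):
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hmcnet")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def _load_samples(config: RunConfig):
    if config.data_kind == "phantom":
        logger.info(
            "generating %d phantoms (size %d, seed %d)",
            config.phantom_n, config.phantom_size, config.seed,
        )
        return generate_phantoms(
            config.phantom_n, config.class_mix, config.phantom_size, config.seed
        )
    if config.data_kind == "manifest":
        if not config.manifest_path:
            raise InputError("data_kind 'manifest' requires manifest_path")
        return read_phantom_set(config.manifest_path)
    if config.data_kind == "mias":
        if not (config.mias_image_dir and config.mias_info_file):
            raise InputError("data_kind 'mias' requires mias_image_dir and mias_info_file")
        records = read_mias(config.mias_image_dir, config.mias_info_file)
        logger.info("loaded %d MIAS records", len(records))
        return records
    raise InputError(f"unknown data_kind {config.data_kind!r}")


def _evaluate_fold(model, samples, test_idx, input_size):
    X = np.stack([preprocess(samples[i].image, input_size) for i in test_idx])
    y = np.array([samples[i].label_index for i in test_idx])
    probs = predict_proba(model, X)
    pred = probs.argmax(axis=1)
    cm = confusion(y, pred, len(LABELS))
    metrics = classification_metrics(cm)
    row = {
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.macro["sensitivity"],
        "specificity": metrics.macro["specificity"],
        "precision": metrics.macro["precision"],
        "f1": metrics.macro["f1"],
    }
    try:
        row["auc"] = auc_macro(y, probs)
    except InputError:
        row["auc"] = float("nan")
    return row, cm, probs


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline described by ``config``; idempotent for a
    fixed seed, resumable per fold (existing fold outputs are reused)."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(run_dir)
    t_start = time.time()
    try:
        config.to_yaml(run_dir / "config.yaml")
        samples = _load_samples(config)
        logger.info(
            "defaults in effect: variant=%s preset=%s lr=%g batch=%d epochs=%d "
            "augment(jitter20%%/flip50%%/rotate15deg, order jitter-flip-rotate)=%s "
            "val_fraction=%.2f patient-level folds=%d",
            config.variant, config.preset, config.learning_rate, config.batch_size,
            config.epochs, config.augment, config.val_fraction, config.folds,
        )
        splits = patient_kfold(samples, config.folds, config.seed)
        (run_dir / "splits.json").write_text(json.dumps(splits_to_json(samples, splits), indent=2))
        backbone = PRESETS[config.preset]()
        fold_rows = []
        agg_cm = None
        for fold, (train_idx, test_idx) in enumerate(splits):
            fold_dir = run_dir / f"fold{fold}"
            fold_dir.mkdir(exist_ok=True)
            metrics_path = fold_dir / "metrics.json"
            ckpt_path = fold_dir / "checkpoint.npz"
            if metrics_path.exists():
                logger.info("fold %d: reusing existing metrics (resume)", fold)
                payload = json.loads(metrics_path.read_text())
                row = payload["metrics"]
                cm_counts = np.array(payload["confusion"])
            else:
                logger.info("fold %d: training on %d samples, testing on %d",
                            fold, len(train_idx), len(test_idx))
                model = build_model(config.variant, backbone, seed=config.seed + fold)
                tcfg = TrainConfig(
                    learning_rate=config.learning_rate, batch_size=config.batch_size,
                    epochs=config.epochs, seed=config.seed + fold,
                    val_fraction=config.val_fraction, augment=config.augment,
                )
                history = train(model, [samples[i] for i in train_idx], tcfg)
                history_to_csv(history, fold_dir / "history.csv")
                save_checkpoint(model, ckpt_path)
                row, cm, _ = _evaluate_fold(model, samples, test_idx, backbone.input_size)
                cm_counts = cm.counts
                metrics_path.write_text(json.dumps(
                    {"metrics": row, "confusion": cm_counts.tolist()}, indent=2))
            fold_rows.append({"fold": fold, **row})
            agg_cm = cm_counts if agg_cm is None else agg_cm + cm_counts
        fold_table = pd.DataFrame(fold_rows)
        fold_table.to_csv(run_dir / "fold_metrics.csv", index=False)
        aggregate_folds(fold_table, decimals=4).to_csv(run_dir / "aggregate_metrics.csv")
        np.savetxt(run_dir / "aggregated_confusion.csv", agg_cm, fmt="%d", delimiter=",")

        if config.xai_method:
            _explain_run(config, run_dir, samples, splits, backbone)

        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "started_unix": round(t_start, 3),
            "finished_unix": round(time.time(), 3),
            "n_samples": len(samples),
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("run complete in %.1fs", time.time() - t_start)
        return run_dir
    finally:
        logging.getLogger("hmcnet").removeHandler(handler)
        handler.close()


def _explain_run(config, run_dir, samples, splits, backbone):
    from .network import load_checkpoint

    rows = []
    heat_dir = run_dir / "heatmaps"
    heat_dir.mkdir(exist_ok=True)
    for fold, (_, test_idx) in enumerate(splits):
        ckpt = run_dir / f"fold{fold}" / "checkpoint.npz"
        if not ckpt.exists():
            logger.warning("fold %d: no checkpoint, skipping explanations", fold)
            continue
        model = load_checkpoint(ckpt)
        for i in test_idx:
            s = samples[i]
            mask = getattr(s, "mask", None)
            if mask is None or not mask.any():
                continue
            x = preprocess(s.image, backbone.input_size)
            hm = cam_explain(model, x, s.label_index, config.xai_method)
            iou = localization_iou(hm, mask, config.iou_threshold)
            sid = getattr(s, "sample_id", str(i)) or str(i)
            rows.append({"sample_id": sid, "method": config.xai_method,
                         "threshold": config.iou_threshold, "iou": iou})
            if config.save_heatmaps:
                save_heatmap_png(hm, x, heat_dir / f"{sid}_{config.xai_method}")
    if rows:
        df = pd.DataFrame(rows)
        df.to_csv(run_dir / "iou_report.csv", index=False)
        logger.info("mean IoU (%s, thr %.2f): %.3f over %d lesions",
                    config.xai_method, config.iou_threshold, df["iou"].mean(), len(df))


def run_compare(
    tables: dict[str, object],
    metric: str = "accuracy",
    q_alpha: float = Q_ALPHA_REPORTED,
    out_dir=None,
):
    """Friedman/Nemenyi comparison of per-fold metric tables.

    ``tables`` maps model name -> fold-table CSV path (or DataFrame).  All
    tables must share the fold count; returns (RankSummary, CDDiagram) and,
    when ``out_dir`` is given, writes rank_summary.json / cd_diagram.json.
    """
    if len(tables) < 2:
        raise InputError("need at least two models to compare")
    frames = {}
    for name, src in tables.items():
        df = src if isinstance(src, pd.DataFrame) else read_fold_table(src)
        if metric not in df.columns:
            raise InputError(f"table for {name!r} lacks metric column {metric!r}")
        frames[name] = df.sort_values("fold")[metric].to_numpy()
    lengths = {name: len(v) for name, v in frames.items()}
    if len(set(lengths.values())) != 1:
        raise InputError(f"fold-count mismatch across tables: {lengths}")
    matrix = np.column_stack(list(frames.values()))  # (N folds, k models)
    summary = rank_summary(matrix, list(frames.keys()), q_alpha)
    diagram = cd_diagram(summary.average_ranks, summary.cd, summary.models)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "rank_summary.json").write_text(summary.to_json())
        (out_dir / "cd_diagram.json").write_text(diagram.to_json())
    return summary, diagram
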