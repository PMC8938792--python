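"""End-to-end orchestration: phantoms → split → training → self-training
→ segmentation of the test pool → volumetry/scores → evaluation.

The pipeline runs fully in memory and writes its artifacts (cohort
table, split manifest, training curves, checkpoint, per-subject scores,
metrics, ROC summaries) into an output directory, finishing with a
manifest that lists every produced file with a SHA-256 hash.  One
top-level seed deterministically derives every stage seed, so a rerun
with the same configuration and seed reproduces the score table
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstats, phantom, segnet, semisup, volumetrics
from .grids import LabelMap
from .phantom import CohortModel
from .regions import N_CLASSES
from .segnet import SegConfig, TrainConfig

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config",
           "build_dataset", "segment_subject"]

log = logging.getLogger("sinusvol")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with scaled-down defaults."""

    n_labeled: int = 10
    n_unlabeled: int = 20
    labeled_ratio: float = 0.8
    selftrain_fraction: float = 0.2
    seed: int = 0
    slice_step: int = 2

    cohort: CohortModel = field(default_factory=CohortModel)
    seg: SegConfig = field(default_factory=lambda: SegConfig(
        in_channels=4, n_classes=N_CLASSES, base_width=8, depth=3,
        atrous_rates=(1, 2, 4), se_reduction=4))
    warmup: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=12, batch_size=16, lr=3e-3, dice_weight=0.5))
    rounds: int = 2
    round_epochs: int = 3
    tau: float = 0.9
    lambda_entropy: float = 0.0

    hu_threshold: float = volumetrics.HU_AIR_THRESHOLD
    tlms_partial_low: float = 0.05
    tlms_complete_high: float = 0.95

    out_dir: str = "pipeline_out"

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


_NESTED = {"cohort": CohortModel, "seg": SegConfig, "warmup": TrainConfig}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus overrides.

    Unknown keys or wrongly-typed values raise ValueError before any
    computation starts.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
    raw.update(overrides or {})
    kwargs = {}
    valid = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in valid:
            raise ValueError(f"unknown config key {key!r}")
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            sub_valid = {f.name for f in dataclasses.fields(_NESTED[key])}
            bad = set(value) - sub_valid
            if bad:
                raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
            if "atrous_rates" in value:
                value["atrous_rates"] = tuple(value["atrous_rates"])
            kwargs[key] = _NESTED[key](**value)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    for name, typ in (("n_labeled", int), ("n_unlabeled", int),
                      ("rounds", int), ("seed", int)):
        if not isinstance(getattr(cfg, name), int):
            raise ValueError(f"{name} must be an integer")
    for name in ("labeled_ratio", "selftrain_fraction", "tau", "hu_threshold",
                 "lambda_entropy"):
        v = getattr(cfg, name)
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ValueError(f"{name} must be a number, got {type(v).__name__}")
    return cfg


def build_dataset(cfg: PipelineConfig):
    """Generate the cohort and all phantom data arrays.

    Returns ``(records, specs, data, truth)`` where ``data`` maps
    subject id to (X, Y) slice arrays and ``truth`` to the ground-truth
    region reports and full-resolution grids.
    """
    cohort = phantom.generate_cohort(
        cfg.n_labeled + cfg.n_unlabeled, cfg.cohort,
        seed=cfg.stage_seed("cohort"))
    records = {r.subject_id: r for r, _ in cohort}
    specs = {r.subject_id: s for r, s in cohort}
    data, truth = {}, {}
    for sid, spec in specs.items():
        vol, lm, gt = phantom.generate_phantom(spec)
        x, y = phantom.slices_to_arrays(vol, lm, slice_step=cfg.slice_step)
        data[sid] = (x, y)
        truth[sid] = {"volume": vol, "labelmap": lm, "reports": gt}
    return records, specs, data, truth


def segment_subject(model, volume, hu_threshold=volumetrics.HU_AIR_THRESHOLD,
                    partial_low=0.05, complete_high=0.95):
    """Segment every coronal slice of a volume, stack to 3D, and score."""
    x, _ = phantom.slices_to_arrays(volume, None, slice_step=1)
    was_training = model.training
    model.eval()
    preds = []
    for i in range(0, len(x), 32):
        preds.append(model.forward(x[i:i + 32]).argmax(axis=1))
    model.train(was_training)
    labels = np.concatenate(preds)
    pred_map = volumetrics.stack_segmentations(
        list(labels), volume.spacing_mm, volume.orientation)
    score = volumetrics.score_subject(
        pred_map, volume, hu_threshold, partial_low, complete_high)
    return pred_map, score


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure raises :class:`PipelineError` naming the stage,
    after persisting a partial manifest of the files written so far.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"seed": cfg.seed, "stages": [], "files": {}}

    def flush(stage: str | None = None):
        if stage:
            manifest["stages"].append(stage)
        manifest["files"] = {str(p.relative_to(out)): _sha256(p)
                             for p in written if p.exists()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def emit(path: Path):
        written.append(path)

    stage = "config"
    try:
        cfg_path = out / "config.json"
        cfg_dict = dataclasses.asdict(cfg)
        cfg_path.write_text(json.dumps(cfg_dict, indent=2, default=list))
        emit(cfg_path)
        flush(stage)

        stage = "phantom"
        log.info("generating %d phantoms", cfg.n_labeled + cfg.n_unlabeled)
        records, specs, data, truth = build_dataset(cfg)
        ids = list(records)
        labeled_ids = ids[:cfg.n_labeled]
        unlabeled_ids = ids[cfg.n_labeled:]
        cohort_path = out / "cohort.csv"
        phantom.cohort_to_frame(list(records.values())).to_csv(
            cohort_path, index=False)
        emit(cohort_path)
        flush(stage)

        stage = "split"
        split = semisup.make_split(
            labeled_ids, unlabeled_ids, cfg.labeled_ratio,
            cfg.selftrain_fraction, seed=cfg.stage_seed("split"))
        split_path = out / "split.json"
        split_path.write_text(json.dumps({
            "seed": cfg.stage_seed("split"),
            "labeled_ratio": cfg.labeled_ratio,
            "selftrain_fraction": cfg.selftrain_fraction,
            **{k: list(v) for k, v in dataclasses.asdict(split).items()},
        }, indent=2))
        emit(split_path)
        flush(stage)

        stage = "train"
        log.info("supervised warm-up on %d subjects", len(split.labeled_train))
        model = segnet.build_model(cfg.seg, seed=cfg.stage_seed("init"))
        x_tr = np.concatenate([data[i][0] for i in split.labeled_train])
        y_tr = np.concatenate([data[i][1] for i in split.labeled_train])
        x_va = np.concatenate([data[i][0] for i in split.labeled_val])
        y_va = np.concatenate([data[i][1] for i in split.labeled_val])
        curves_path = out / "train_curves.csv"
        warm_cfg = replace(cfg.warmup, seed=cfg.stage_seed("warmup"),
                           log_csv=str(curves_path))
        segnet.train_supervised(model, x_tr, y_tr, warm_cfg, val=(x_va, y_va))
        emit(curves_path)
        flush(stage)

        stage = "selftrain"
        if cfg.rounds > 0 and split.unlabeled_selftrain:
            log.info("self-training: %d rounds on %d unlabeled subjects",
                     cfg.rounds, len(split.unlabeled_selftrain))
            round_cfg = replace(cfg.warmup, epochs=cfg.round_epochs,
                                seed=cfg.stage_seed("rounds"))
            state = semisup.self_train(
                model, split, data, rounds=cfg.rounds, tau=cfg.tau,
                lambda_entropy=cfg.lambda_entropy, round_cfg=round_cfg)
            hist_path = out / "selftrain_history.csv"
            pd.DataFrame(state.history).to_csv(hist_path, index=False)
            emit(hist_path)
        ckpt_path = out / "model.npz"
        segnet.save_checkpoint(model, ckpt_path)
        emit(ckpt_path)
        emit(ckpt_path.with_suffix(".json"))
        flush(stage)

        stage = "segment"
        test_ids = list(split.unlabeled_test)
        log.info("segmenting %d test subjects", len(test_ids))
        scores, seg_rows, pred_reports, ref_reports = {}, [], {}, {}
        for sid in test_ids:
            vol = truth[sid]["volume"]
            ref_lm: LabelMap = truth[sid]["labelmap"]
            pred_map, score = segment_subject(
                model, vol, cfg.hu_threshold,
                cfg.tlms_partial_low, cfg.tlms_complete_high)
            scores[sid] = score
            pred_reports[sid] = list(score.reports)
            ref_reports[sid] = truth[sid]["reports"]
            m = evalstats.seg_metrics(pred_map.data, ref_lm.data, N_CLASSES)
            truth_score = volumetrics.vmlms(truth[sid]["reports"])
            seg_rows.append({
                "subject_id": sid, "mean_dice": m.mean_dice, "miou": m.miou,
                "pixel_accuracy": m.pixel_accuracy,
                "vmlms_pred": score.vmlms_total,
                "vmlms_truth": truth_score.vmlms_total,
                "tlms_pred": score.tlms_total,
                "tlms_truth": truth_score.tlms_total,
            })
        scores_path = out / "scores.csv"
        volumetrics.scores_to_frame(scores).to_csv(scores_path, index=False)
        emit(scores_path)
        metrics_path = out / "metrics.csv"
        pd.DataFrame(seg_rows).to_csv(metrics_path, index=False)
        emit(metrics_path)
        flush(stage)

        stage = "evaluate"
        mdf = pd.DataFrame(seg_rows)
        summary = {
            "n_test": len(test_ids),
            "mean_dice": float(mdf.mean_dice.mean()),
            "miou": float(mdf.miou.mean()),
            "pixel_accuracy": float(mdf.pixel_accuracy.mean()),
            "vmlms_mae": float((mdf.vmlms_pred - mdf.vmlms_truth).abs().mean()),
            "tlms_mae": float((mdf.tlms_pred - mdf.tlms_truth).abs().mean()),
        }
        surgery = np.array([records[s].surgery for s in test_ids])
        if 0 < surgery.sum() < len(surgery):
            for name, col in (("vmlms", "vmlms_pred"), ("tlms", "tlms_pred")):
                rr = evalstats.roc(mdf[col].to_numpy(), surgery.astype(int))
                summary[f"{name}_surgery_auc"] = rr.auc
                summary[f"{name}_surgery_cutpoint"] = rr.youden_cutpoint
                roc_path = out / f"roc_{name}.csv"
                pd.DataFrame({"threshold": rr.thresholds, "fpr": rr.fpr,
                              "tpr": rr.tpr}).to_csv(roc_path, index=False)
                emit(roc_path)
        agreement = evalstats.region_agreement(pred_reports, ref_reports,
                                               tolerance=0.1)
        agree_path = out / "region_agreement.csv"
        agreement.to_csv(agree_path)
        emit(agree_path)
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        emit(summary_path)
        flush(stage)
        manifest["summary"] = summary
        flush()
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        flush()
        raise PipelineError(stage, exc) from exc
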