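"""End-to-end orchestration: simulate -> standardize -> crop -> blank filter
-> train on group A -> predict group B -> image-level evaluation.

A single :class:`PipelineConfig` (YAML round-trippable) and one global seed
determine every stage; re-running with the same configuration reproduces
the cohort, manifests and report exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blankfilter, classifier, evaluate, phantom, preprocess
from .errors import DegenerateChannelError, InvalidConfigError

__all__ = ["PipelineConfig", "run_simulate", "run_full"]

log = logging.getLogger("mpmbreast")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run (flat, for lossless config files)."""

    # cohort layout
    n_patients: int = 12
    images_per_patient: int = 8
    cancer_fraction: float = 0.5
    no_finding_fraction: float = 0.10
    # acquisition geometry
    width_px: int = 1024
    height_px: int = 1024
    n_planes: int = 1
    # phantom rendering
    noise_sd: float = 12.0
    background_level: float = 40.0
    signal_scale: float = 2500.0
    tissue_coverage: float = 0.80
    tile_cancer_fraction: float = 0.05
    # blank rule
    snr_threshold: float = 20.0
    brightness_threshold: float = 0.10
    median_window: int = 3
    snr_mode: str = "db"
    # training
    architecture: str = "small_cnn"
    epochs: int = 40
    learning_rate: float = 0.005
    batch_size: int = 128
    val_fraction: float = 0.20
    # evaluation
    verdict_threshold: float = 0.0625
    coverage_threshold: float = 0.90
    # reproducibility
    seed: int = 0

    def geometry(self) -> phantom.StackGeometry:
        return phantom.StackGeometry(
            width_px=self.width_px, height_px=self.height_px, n_planes=self.n_planes
        )

    def blank_rule(self) -> blankfilter.BlankRule:
        return blankfilter.BlankRule(
            snr_threshold=self.snr_threshold,
            brightness_threshold=self.brightness_threshold,
            median_window=self.median_window,
            snr_mode=self.snr_mode,
        )

    def train_config(self) -> classifier.TrainConfig:
        return classifier.TrainConfig(
            architecture=self.architecture,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def verdict_config(self) -> evaluate.VerdictConfig:
        return evaluate.VerdictConfig(threshold=self.verdict_threshold)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _generate(config: PipelineConfig):
    return phantom.generate_cohort(
        n_patients=config.n_patients,
        images_per_patient=config.images_per_patient,
        cancer_fraction=config.cancer_fraction,
        seed=config.seed,
        geometry=config.geometry(),
        no_finding_fraction=config.no_finding_fraction,
        noise_sd=config.noise_sd,
        background_level=config.background_level,
        signal_scale=config.signal_scale,
        tissue_coverage=config.tissue_coverage,
        tile_cancer_fraction=config.tile_cancer_fraction,
    )


def run_simulate(config: PipelineConfig, outdir: str | Path) -> Path:
    """Generate the cohort and write TIFF stacks, truth and manifest."""
    if config.n_patients < 2:
        raise InvalidConfigError("cannot form patient-disjoint groups from one patient")
    cohort = _generate(config)
    outdir = Path(outdir)
    manifest = phantom.save_cohort(cohort, outdir)
    config.to_yaml(outdir / "config.yaml")
    log.info("simulated %d stacks -> %s", len(cohort), outdir)
    return manifest


def _tile_records(config: PipelineConfig, cohort) -> list[dict]:
    """Crop, blank-flag and pool every retained plane of every stack.

    The standardized image is summarized into 4x4 block mean + standard
    deviation planes before cropping (equivalent to per-tile
    classifier.tile_features) so classifier inputs stay small in memory;
    the blank rule always reads the raw 12-bit tile.
    """
    rule = config.blank_rule()
    side = 128
    pooled_side = 32
    factor = side // pooled_side
    records: list[dict] = []
    for stack, truth in cohort:
        if stack.voxels.shape[0] > 1:
            planes = preprocess.calibrate_z(stack, config.coverage_threshold)
        else:
            planes = [0]
        for z in planes:
            raw = stack.voxels[z].astype(np.float64)
            image_id = stack.image_id if len(planes) == 1 else f"{stack.image_id}_z{z}"
            try:
                std = preprocess.standardize(raw)
                degenerate = False
            except DegenerateChannelError:
                std, degenerate = None, True
            if not degenerate:
                c, h, w = std.shape
                blocks = std.reshape(c, h // factor, factor, w // factor, factor)
                mean = blocks.mean(axis=(2, 4))
                var = (blocks**2).mean(axis=(2, 4)) - mean**2
                # block mean + std feature planes, matching classifier.tile_features
                pooled = np.concatenate([mean, np.sqrt(np.clip(var, 0.0, None))])
            rows, cols = raw.shape[1] // side, raw.shape[2] // side
            for r in range(rows):
                for cc in range(cols):
                    raw_tile = raw[:, r * side : (r + 1) * side, cc * side : (cc + 1) * side]
                    blank = degenerate or blankfilter.is_blank(raw_tile, rule)
                    x = (
                        None
                        if degenerate
                        else pooled[
                            :,
                            r * pooled_side : (r + 1) * pooled_side,
                            cc * pooled_side : (cc + 1) * pooled_side,
                        ].astype(np.float32)
                    )
                    records.append(
                        {
                            "image_id": image_id,
                            "patient_id": stack.patient_id,
                            "group": stack.group,
                            "grid_row": r,
                            "grid_col": cc,
                            "is_blank": bool(blank),
                            "truth_label": "cancer" if truth.tile_labels[r, cc] else "no_cancer",
                            "score": None,
                            "split": None,
                            "x": x,
                        }
                    )
    return records


def run_full(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the whole pipeline and return the evaluation report."""
    cohort = _generate(config)
    log.info("cohort: %d stacks", len(cohort))
    records = _tile_records(config, cohort)
    del cohort

    a_tiles = [t for t in records if t["group"] == "A"]
    b_tiles = [t for t in records if t["group"] == "B"]
    if not a_tiles or not b_tiles:
        raise InvalidConfigError("both groups A and B must contain images")

    # tile-level 20% validation split inside group A, then blank exclusion
    a_train, a_val = preprocess.split_train_validation(
        a_tiles, config.val_fraction, seed=config.seed
    )
    for t in a_train:
        t["split"] = "train"
    for t in a_val:
        t["split"] = "validation"
    tr = [t for t in a_train if not t["is_blank"]]
    va = [t for t in a_val if not t["is_blank"]]

    model = classifier.train(
        np.stack([t["x"] for t in tr]),
        [t["truth_label"] for t in tr],
        np.stack([t["x"] for t in va]),
        [t["truth_label"] for t in va],
        config.train_config(),
    )
    log.info(
        "trained %s: val acc %.3f (epoch %d)",
        model.architecture,
        model.metadata["validation_accuracy"],
        model.metadata["best_epoch"],
    )

    b_nonblank = [t for t in b_tiles if not t["is_blank"]]
    if b_nonblank:
        scores = classifier.predict_batch(model, np.stack([t["x"] for t in b_nonblank]))
        for t, s in zip(b_nonblank, scores):
            t["score"] = float(s)

    cm = evaluate.tile_outcomes(b_tiles)
    accuracy, precision, recall, f_measure = evaluate.matrix_metrics(cm)

    n_tiles_per_image = (config.height_px // 128) * (config.width_px // 128)
    verdict_cfg = config.verdict_config()
    by_image: dict[str, list[dict]] = {}
    for t in b_tiles:
        by_image.setdefault(t["image_id"], []).append(t)
    verdicts = []
    for image_id, tiles in sorted(by_image.items()):
        mp = evaluate.malignant_probability(tiles, expected_tiles=n_tiles_per_image)
        truth_class = (
            "cancerous" if any(t["truth_label"] == "cancer" for t in tiles) else "normal"
        )
        verdicts.append(
            evaluate.ImageVerdict(
                image_id=image_id,
                malignant_probability=mp,
                predicted_class="malignant" if verdict_cfg.is_malignant(mp) else "nonmalignant",
                truth_class=truth_class,
            )
        )
    sensitivity, specificity = evaluate.image_level_rates(verdicts)
    roc_points, auc = evaluate.roc_curve(verdicts, n_tiles=n_tiles_per_image)
    mp_cancer = [v.malignant_probability for v in verdicts if v.truth_class == "cancerous"]
    mp_normal = [v.malignant_probability for v in verdicts if v.truth_class == "normal"]
    if mp_cancer and mp_normal:
        u_stat, p_value = evaluate.mann_whitney_u(mp_cancer, mp_normal)
    else:
        u_stat, p_value = evaluate.UNDEFINED, evaluate.UNDEFINED

    report = {
        "config": asdict(config),
        "counts": {
            "images_total": len(by_image) + len({t["image_id"] for t in a_tiles}),
            "images_group_a": len({t["image_id"] for t in a_tiles}),
            "images_group_b": len(by_image),
            "tiles_total": len(records),
            "tiles_group_a": len(a_tiles),
            "tiles_group_b": len(b_tiles),
            "blank_group_a": sum(t["is_blank"] for t in a_tiles),
            "blank_group_b": sum(t["is_blank"] for t in b_tiles),
            "training_tiles": len(tr),
            "validation_tiles": len(va),
        },
        "training": {
            "validation_accuracy": model.metadata["validation_accuracy"],
            "best_epoch": model.metadata["best_epoch"],
        },
        "tile_confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "tile_metrics": {
            "accuracy": accuracy,
            "precision": precision,
            "recall": recall,
            "f_measure": f_measure,
        },
        "image_metrics": {
            "sensitivity": sensitivity,
            "specificity": specificity,
            "auc": auc,
            "mann_whitney_u": u_stat,
            "mann_whitney_p": p_value,
            "verdict_threshold": config.verdict_threshold,
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        tile_frame = pd.DataFrame(
            [{k: v for k, v in t.items() if k != "x"} for t in records]
        )
        tile_frame.to_csv(outdir / "tiles.csv", index=False)
        pd.DataFrame([dataclasses.asdict(v) for v in verdicts]).to_csv(
            outdir / "image_verdicts.csv", index=False
        )
        if not np.isnan(auc):
            evaluate.save_roc_plot(roc_points, auc, outdir / "roc.svg")
        config.to_yaml(outdir / "config.yaml")
        log.info("report written to %s", outdir)

    report["_verdicts"] = verdicts  # in-memory convenience, not serialized above
    return report
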