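"""End-to-end orchestration: simulate -> enhance -> segment -> features ->
train -> report.

Every stage writes its artifacts under the run directory (images/,
enhanced/, masks/, features.csv, segmentation_scores.csv, report.json)
so each stage can be inspected or replayed in isolation.  A single
master seed deterministically derives all stage seeds (stable CRC-32
mixing), and re-running the same configuration reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import FoldPlan, FuzzyKnnClassifier, cross_validate, make_classifier
from .enhance import ClaheParams, enhance_rgb
from .featurebank import FEATURE_NAMES, extract_all
from .imageio import load_mask, load_rgb, save_mask, save_rgb
from .segeval import score_segmentation
from .segment import fcm_segment, kmeans_segment, select_roi
from .synthgen import generate_dataset

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "cancerous"


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, human-editable run configuration with documented defaults."""

    n_per_class: int = 20          # synthetic images per class
    seed: int = 0                  # master seed; all stage seeds derive from it
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip_limit: float = 0.01
    clahe_bins: int = 256
    seg_method: str = "kmeans"     # kmeans | ckmeans (L*a*b*) | fcm
    seg_k: int = 3                 # clusters, per the framework's protocol
    roi_rule: str = "most_blue"
    classifier: str = "knn"        # knn | fknn | svm | rf
    knn_k: int = 5                 # neighbors
    fuzzifier: float = 2.0
    k_folds: int = 10

    def validate(self) -> list[str]:
        errors = []
        if self.n_per_class < 1:
            errors.append("n_per_class must be >= 1")
        if self.seg_k < 1:
            errors.append("seg_k must be >= 1")
        if self.seg_method not in ("kmeans", "ckmeans", "fcm"):
            errors.append(f"unknown seg_method {self.seg_method!r}")
        if self.roi_rule not in ("most_blue", "darkest"):
            errors.append(f"unknown roi_rule {self.roi_rule!r}")
        if self.classifier not in ("knn", "fknn", "svm", "rf"):
            errors.append(f"unknown classifier {self.classifier!r}")
        if self.knn_k < 1:
            errors.append("knn_k must be >= 1")
        if not self.fuzzifier > 1:
            errors.append("fuzzifier must be > 1")
        if self.k_folds < 2:
            errors.append("k_folds must be >= 2")
        if self.clahe_tiles[0] < 1 or self.clahe_tiles[1] < 1:
            errors.append("clahe_tiles entries must be >= 1")
        if not self.clahe_clip_limit > 0:
            errors.append("clahe_clip_limit must be > 0")
        return errors


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Load and schema-validate a YAML config; every violation is reported
    at once.  Unknown keys are rejected."""
    if data is None:
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    errors = [f"unknown key {k!r}" for k in data if k not in known]
    clean = {k: v for k, v in data.items() if k in known}
    for key in ("clahe_tiles",):
        if key in clean and isinstance(clean[key], list):
            clean[key] = tuple(clean[key])
    cfg = PipelineConfig(**clean)
    errors += cfg.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["clahe_tiles"] = list(d["clahe_tiles"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()


def segment_image(img: np.ndarray, cfg: PipelineConfig, seed: int) -> np.ndarray:
    if cfg.seg_method == "kmeans":
        mask = kmeans_segment(img, k=cfg.seg_k, seed=seed, color_space="rgb")
    elif cfg.seg_method == "ckmeans":
        mask = kmeans_segment(img, k=cfg.seg_k, seed=seed, color_space="lab")
    else:
        mask = fcm_segment(img, k=max(cfg.seg_k, 2), m=cfg.fuzzifier,
                           seed=seed).mask
    return select_roi(mask, img, rule=cfg.roi_rule)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clahe_params = ClaheParams(tile_grid=cfg.clahe_tiles,
                               clip_limit=cfg.clahe_clip_limit,
                               n_bins=cfg.clahe_bins)

    logger.info("stage simulate: %d images/class", cfg.n_per_class)
    img_dir = out / "images"
    records = generate_dataset(cfg.n_per_class, stage_seed(cfg.seed, "simulate"),
                               img_dir)

    enhanced_dir = out / "enhanced"
    mask_dir = out / "masks"
    enhanced_dir.mkdir(exist_ok=True)
    mask_dir.mkdir(exist_ok=True)
    seg_rows = []
    for i, rec in enumerate(records):
        rgb = load_rgb(img_dir / rec.filename)
        enhanced = enhance_rgb(rgb, clahe_params)
        save_rgb(enhanced, enhanced_dir / rec.filename)
        roi = segment_image(enhanced, cfg,
                            stage_seed(cfg.seed, f"segment/{rec.filename}"))
        save_mask(roi, mask_dir / rec.mask)
        gt = load_mask(img_dir / rec.mask)
        s = score_segmentation(roi, gt)
        seg_rows.append({
            "filename": rec.filename, "label": rec.label,
            "accuracy": s.accuracy, "sensitivity": s.sensitivity,
            "specificity": s.specificity, "fpr": s.fpr,
            "pri": s.pri, "gce": s.gce, "voi": s.voi,
        })
    seg_df = pd.DataFrame(seg_rows)
    seg_df.to_csv(out / "segmentation_scores.csv", index=False)

    logger.info("stage features")
    # ROI masks come from the segmentation stage, not the ground truth.
    rows = []
    for rec in records:
        rgb = load_rgb(enhanced_dir / rec.filename)
        roi = load_mask(mask_dir / rec.mask)
        rows.append(extract_all(rgb, roi))
    features = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    features["label"] = [r.label for r in records]
    features.to_csv(out / "features.csv", index=False)

    logger.info("stage train: %s with %d-fold CV", cfg.classifier, cfg.k_folds)
    x = features[list(FEATURE_NAMES)].to_numpy()
    y = (features["label"] == POSITIVE_CLASS).astype(int).to_numpy()
    plan = FoldPlan.stratified(y, k_folds=cfg.k_folds,
                               seed=stage_seed(cfg.seed, "folds"))
    clf = make_classifier(cfg.classifier, k=cfg.knn_k, m=cfg.fuzzifier,
                          seed=stage_seed(cfg.seed, "classifier"))
    cv = cross_validate(x, y, clf, plan, positive=1)

    report = {
        "version": __version__,
        "config": {**asdict(cfg), "clahe_tiles": list(cfg.clahe_tiles)},
        "config_hash": config_hash(cfg),
        "n_images": len(records),
        "segmentation_mean": {
            k: float(seg_df[k].mean())
            for k in ("accuracy", "sensitivity", "specificity", "fpr",
                      "pri", "gce", "voi")
        },
        "classification": cv.as_dict(),
    }
    if isinstance(clf, FuzzyKnnClassifier) and clf.memberships_ is not None:
        report["fuzzy_membership_row_sums_ok"] = bool(
            np.allclose(clf.memberships_.sum(axis=1), 1.0))
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    save_config(cfg, out / "config.yaml")
    return report
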