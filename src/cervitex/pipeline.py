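"""End-to-end pipeline: enhance -> transform -> extract -> classify -> segment.

Ties the library stages together over an on-disk dataset (PNG images, optional
``mask_<id>.png`` ground truths, optional ``labels.csv``) and writes a
reproducible result set: ``features.csv``, ``model.json``, ``metrics.json``
and one mask PNG per abnormal call.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import classify, segmentation
from .config import PipelineConfig
from .enhancement import enhance_image, to_grayscale
from .ridgelet import largest_prime_leq
from .texture import assemble_features

__all__ = ["PipelineError", "load_dataset", "save_dataset", "extract_feature_table", "run_pipeline"]

log = logging.getLogger("cervitex")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def save_dataset(
    out_dir: str | Path,
    images: np.ndarray,
    masks: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> None:
    """Write a dataset as PNG images + mask PNGs + labels.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [f"img_{i:04d}" for i in range(len(images))]
    for i, img_id in enumerate(ids):
        iio.imwrite(out / f"{img_id}.png", images[i])
        if masks is not None:
            iio.imwrite(out / f"mask_{img_id}.png", (masks[i] * 255).astype(np.uint8))
    if labels is not None:
        pd.DataFrame({"image": ids, "label": labels}).to_csv(
            out / "labels.csv", index=False
        )


def load_dataset(
    in_dir: str | Path,
) -> tuple[list[str], list[np.ndarray], dict[str, np.ndarray], dict[str, int]]:
    """Read images, ground-truth masks and labels from a directory.

    Returns (ids, images, masks-by-id, labels-by-id); masks and labels may be
    empty when not present on disk.
    """
    in_dir = Path(in_dir)
    paths = sorted(
        p
        for p in list(in_dir.glob("*.png")) + list(in_dir.glob("*.jpg")) + list(in_dir.glob("*.tif"))
        if not p.name.startswith("mask_")
    )
    if not paths:
        raise PipelineError("input", f"no images found in {in_dir}")
    ids, images, masks = [], [], {}
    for p in paths:
        img_id = p.stem
        ids.append(img_id)
        images.append(np.asarray(iio.imread(p)))
        mask_path = in_dir / f"mask_{p.name}"
        if mask_path.exists():
            masks[img_id] = (np.asarray(iio.imread(mask_path)) > 0).astype(np.uint8)
    labels: dict[str, int] = {}
    labels_path = in_dir / "labels.csv"
    if labels_path.exists():
        df = pd.read_csv(labels_path)
        labels = {str(r.image): int(r.label) for r in df.itertuples()}
    return ids, images, masks, labels


def extract_feature_table(
    ids: list[str],
    images: list[np.ndarray],
    config: PipelineConfig,
    labels: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Enhance every image and assemble its feature vector.

    The ridgelet grid size is resolved once from the smallest image dimension
    so every vector has the same length; a config-hash mismatch across the
    table is impossible by construction and asserted anyway.

    Returns (feature table, grayscale-by-id, enhanced-by-id).
    """
    feat_cfg = config.features
    if "frt" in feat_cfg.blocks and feat_cfg.frt_prime is None:
        min_side = min(min(img.shape[:2]) for img in images)
        feat_cfg = dataclasses.replace(feat_cfg, frt_prime=largest_prime_leq(min_side))
        log.info("resolved ridgelet grid size p=%d", feat_cfg.frt_prime)
    grays: dict[str, np.ndarray] = {}
    enhanced: dict[str, np.ndarray] = {}
    rows = []
    names: list[str] | None = None
    vec_hash: str | None = None
    for img_id, img in zip(ids, images):
        grays[img_id] = to_grayscale(img)
        enhanced[img_id] = enhance_image(
            img, config.enhancement.window, config.enhancement.fusion, config.enhancement.levels
        )
        fv = assemble_features(enhanced[img_id], feat_cfg)
        if names is None:
            names, vec_hash = fv.names, fv.config_hash
        elif fv.names != names or fv.config_hash != vec_hash:
            raise PipelineError("extract", f"inconsistent feature configuration at {img_id}")
        rows.append(fv.values)
    table = pd.DataFrame(np.vstack(rows), columns=names)
    table.insert(0, "image", ids)
    if labels:
        table["label"] = [labels.get(i, -1) for i in ids]
    return table, grays, enhanced


def _json_safe(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, input_dir: str | Path, output_dir: str | Path) -> dict:
    """Run the full detection pipeline over a dataset directory.

    Requires ``labels.csv`` in the input directory (training needs truth
    labels).  On any stage failure, partially written outputs are removed and
    a stage-tagged :class:`PipelineError` is raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cfg_hash = config.config_hash()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        log.info("pipeline start (config %s)", cfg_hash)
        ids, images, truth_masks, labels = load_dataset(input_dir)
        if not labels:
            raise PipelineError("input", "labels.csv required to train/evaluate")

        log.info("[enhance+extract] %d images (config %s)", len(ids), cfg_hash)
        try:
            table, grays, enhanced = extract_feature_table(ids, images, config, labels)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage
            raise PipelineError("extract", str(exc)) from exc

        features_path = out / "features.csv"
        table.to_csv(features_path, index=False, float_format="%.12g")
        created.append(features_path)

        feat_cols = [c for c in table.columns if c not in ("image", "label")]
        X = table[feat_cols].to_numpy()
        y = table["label"].to_numpy()
        log.info("[classify] k=%d cross-validation (config %s)", config.classifier.k, cfg_hash)
        try:
            train_cfg = config.classifier.train
            if train_cfg.seed == 0 and config.seed != 0:
                train_cfg = dataclasses.replace(train_cfg, seed=config.seed)
            metrics = classify.kfold_cv(X, y, config.classifier.k, config.seed, train_cfg)
            model = classify.train(X, y, train_cfg, feature_names=feat_cols)
            calls, scores = model.predict(X)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("classify", str(exc)) from exc
        model_path = out / "model.json"
        model.save(model_path)
        created.append(model_path)

        log.info("[segment] abnormal calls (config %s)", cfg_hash)
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        per_image = []
        se = config.segmentation.element()
        for img_id, call, score in zip(ids, calls.tolist(), scores.tolist()):
            entry = {
                "image": img_id,
                "label": int(labels.get(img_id, -1)),
                "call": int(call),
                "score": round(float(score), 12),
            }
            if call == 1 or config.segmentation.force:
                source = grays[img_id] if config.segmentation.source == "gray" else enhanced[img_id]
                try:
                    result = segmentation.segment(
                        source,
                        se,
                        config.segmentation.min_area,
                        config.segmentation.method,
                        truth=truth_masks.get(img_id),
                        operation=config.segmentation.operation,
                    )
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError("segment", f"{img_id}: {exc}") from exc
                mask_path = mask_dir / f"mask_{img_id}.png"
                iio.imwrite(mask_path, (result.mask * 255).astype(np.uint8))
                created.append(mask_path)
                entry["n_regions"] = len(result.regions)
                if result.dice_vs_truth is not None:
                    entry["dice"] = round(result.dice_vs_truth, 12)
            per_image.append(entry)

        dices = [e["dice"] for e in per_image if "dice" in e and e["label"] == 1]
        report = {
            "config_hash": cfg_hash,
            "n_images": len(ids),
            "metrics": _json_safe(metrics.to_dict()),
            "mean_dice_true_abnormal": (round(float(np.mean(dices)), 12) if dices else None),
            "per_image": per_image,
        }
        report_path = out / "metrics.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        created.append(report_path)
        log.info("pipeline done: mu=%.4f accuracy=%.4f", metrics.cv_error, metrics.accuracy)
        return report
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise
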