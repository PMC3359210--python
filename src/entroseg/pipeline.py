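"""Batch orchestration and pixel-based evaluation.

``run_pipeline`` chains the three stages of the quantification system —
colour deconvolution, entropy-based segmentation, cell-based scoring —
over a list of images, logging the chosen cut-offs per image and
recording (rather than raising on) per-image failures so one corrupt
file cannot abort a batch.

Two modes:

``live-cell``
    fluor-blue deconvolution, single-stage maximum-entropy threshold on
    the blue channel, pixel-mean score.
``ihc``
    H/E/D deconvolution, multistage 8-layer entropy segmentation of the
    Haematoxylin channel, radius-3 mode filter, pixel-mean score.

``evaluate_mask`` compares a predicted mask against ground truth with
the foreground (mask value 0) as the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import entropy, imgio, quantify, stains

__all__ = ["EvalResult", "PipelineConfig", "evaluate_mask", "segment_image", "run_pipeline"]

logger = logging.getLogger(__name__)

MODES = ("live-cell", "ihc")


@dataclass(frozen=True)
class EvalResult:
    """Pixel-based contingency counts of a predicted vs true mask.

    ``precision`` / ``recall`` are ``nan`` when their denominator is
    zero (``undefined_precision`` / ``undefined_recall`` flag that).
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float

    @property
    def undefined_precision(self) -> bool:
        return self.true_positives + self.false_positives == 0

    @property
    def undefined_recall(self) -> bool:
        return self.true_positives + self.false_negatives == 0


def evaluate_mask(predicted: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Pixelwise precision/recall of a predicted mask (foreground = 0)."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    for name, arr in (("predicted", pred), ("truth", true)):
        if not np.all(np.isin(np.unique(arr), (0, 255))):
            raise ValueError(f"{name} mask must be binary with values {{0, 255}}")
    p_fg = pred == 0
    t_fg = true == 0
    tp = int(np.sum(p_fg & t_fg))
    fp = int(np.sum(p_fg & ~t_fg))
    fn = int(np.sum(~p_fg & t_fg))
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return EvalResult(tp, fp, fn, precision, recall)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    ``stain_channel`` defaults to the first stain of the system
    (``blue`` for fluor-blue, ``haematoxylin`` for ihc-hed).
    """

    mode: str = "live-cell"
    stain_system: str = "fluor-blue"
    stain_channel: str | None = None
    criterion: str = "kapur"
    mode_filter_radius: int = 3  # applied in ihc mode; set 0 to disable
    quant_mode: str = "pixel"  # "pixel" | "cell"
    measure: str = "magnitude"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.quant_mode not in ("pixel", "cell"):
            raise ValueError("quant_mode must be 'pixel' or 'cell'")
        if self.mode_filter_radius < 0:
            raise ValueError("mode_filter_radius must be >= 0")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "PipelineConfig":
        defaults = {"live-cell": {"stain_system": "fluor-blue"},
                    "ihc": {"stain_system": "ihc-hed"}}[mode]
        return cls(mode=mode, **{**defaults, **overrides})

    def to_dict(self) -> dict:
        return asdict(self)


def segment_image(
    image: np.ndarray, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Deconvolve and segment one RGB image.

    Returns ``(stain_channel, mask, info)`` where ``info`` records the
    cut-offs and degeneracy flags of the entropy stage.
    """
    system = stains.get_stain_system(config.stain_system)
    channel_name = config.stain_channel or system.names[0]
    channels = stains.deconvolve(image, system)
    channel = channels[channel_name]
    info: dict = {"stain_channel": channel_name}
    if config.mode == "live-cell":
        result = entropy.max_entropy_threshold(
            entropy.histogram(channel), variant=config.criterion
        )
        mask = entropy.binarize(channel, result.cutoff)
        info.update(cutoff=result.cutoff, degenerate=result.degenerate)
        if result.degenerate:
            mask = np.full(channel.shape, 255, dtype=np.uint8)
    else:
        result = entropy.multistage_segment(channel, variant=config.criterion)
        mask = result.mask
        info.update(
            boundaries=result.boundaries,
            stage_cutoffs=result.stage_cutoffs,
            layer_cutoff=result.layer_cutoff,
            degenerate=result.degenerate,
        )
        if config.mode_filter_radius > 0 and not result.degenerate:
            mask = entropy.mode_filter(mask, radius=config.mode_filter_radius)
    return channel, mask, info


def _score(channel: np.ndarray, mask: np.ndarray, config: PipelineConfig):
    if config.quant_mode == "pixel":
        return quantify.quant_score(channel, mask, measure=config.measure)
    return quantify.cell_mean_score(channel, mask, measure=config.measure)


def run_pipeline(
    images: Sequence,
    config: PipelineConfig,
    image_ids: Sequence[str] | None = None,
    group_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Score a batch of images (arrays or file paths).

    Returns a score table (one row per input, with an ``error`` column
    for unreadable files) and a dict of masks keyed by image id.
    """
    if image_ids is None:
        image_ids = [
            str(img) if isinstance(img, (str, Path)) else f"image_{i}"
            for i, img in enumerate(images)
        ]
    if len(image_ids) != len(images):
        raise ValueError("one image id per image is required")
    if group_labels is not None and len(group_labels) != len(images):
        raise ValueError("one group label per image is required")

    rows: list[dict] = []
    masks: dict[str, np.ndarray] = {}
    for i, (img, image_id) in enumerate(zip(images, image_ids)):
        row: dict = {"image_id": image_id, "mode": config.quant_mode}
        if group_labels is not None:
            row["group"] = group_labels[i]
        try:
            arr = imgio.read_rgb(img) if isinstance(img, (str, Path)) else np.asarray(img)
            channel, mask, info = segment_image(arr, config)
            res = _score(channel, mask, config)
            masks[image_id] = mask
            row.update(
                score=res.score,
                foreground_pixels=res.foreground_pixels,
                n_cells=res.n_cells,
                degenerate=bool(info.get("degenerate", False)) or res.empty,
                error="",
            )
            logger.info("%s: cutoff=%s score=%s", image_id, info.get("cutoff"), res.score)
        except Exception as exc:  # noqa: BLE001 - per-file robustness contract
            logger.warning("%s: failed (%s)", image_id, exc)
            row.update(
                score=float("nan"), foreground_pixels=0, n_cells=0,
                degenerate=True, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows), masks
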