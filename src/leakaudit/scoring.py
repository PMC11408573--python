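"""Interpretability scoring of heat maps against ground-truth nodule masks.

Two families of scores per image:

* nodule locality — the maximum and the mean of the heat-map values inside
  the nodule mask ("is the attention on the nodule at all?");
* shape correlation — Pearson and Spearman correlation between the heat map
  and the binary mask over the whole image grid ("does the attention pattern
  match the nodule shape?").

A degenerate (constant) heat map carries no spatial information; its four
scores are set to 0 by convention and flagged, so score tables stay total.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .heatmap import CamConfig, HeatMap, compute_cam
from .phantom import AnnotatedImage

__all__ = ["InterpretabilityScores", "nodule_locality", "shape_correlation",
           "score_table"]

SCORE_COLUMNS = ["image_id", "patient_id", "model_tag", "cam_variant",
                 "nodule_max", "nodule_mean", "pearson", "spearman",
                 "degenerate"]


class ScoringError(ValueError):
    """Scores are undefined for this input (empty or constant mask...)."""


def _values(heatmap: HeatMap | np.ndarray) -> tuple[np.ndarray, bool]:
    if isinstance(heatmap, HeatMap):
        return heatmap.values, heatmap.degenerate
    arr = np.asarray(heatmap, dtype=np.float64)
    return arr, bool(arr.max() - arr.min() <= 0.0)


@dataclass(frozen=True)
class InterpretabilityScores:
    """All four scores for one image under one CAM variant."""

    image_id: str
    nodule_max: float
    nodule_mean: float
    pearson: float
    spearman: float
    degenerate: bool
    cam_variant: str
    patient_id: str = ""
    model_tag: str = ""


def nodule_locality(heatmap: HeatMap | np.ndarray,
                    mask: np.ndarray) -> tuple[float, float]:
    """(max, mean) of heat-map values restricted to mask==1 pixels."""
    values, _ = _values(heatmap)
    mask = np.asarray(mask)
    if values.shape != mask.shape:
        raise ScoringError(f"heat map shape {values.shape} != mask shape "
                           f"{mask.shape}")
    inside = values[mask > 0]
    if inside.size == 0:
        raise ScoringError("empty nodule mask: locality scores undefined")
    return float(inside.max()), float(inside.mean())


def shape_correlation(heatmap: HeatMap | np.ndarray,
                      mask: np.ndarray) -> tuple[float, float]:
    """(Pearson, Spearman) correlation of heat map vs. binary mask.

    Both arrays are flattened in the same (row-major) pixel order; Spearman
    uses average ranks for ties.  A zero-variance heat map returns (0, 0) —
    the degenerate convention — while a constant mask is an error since no
    correlation against a constant reference is defined.
    """
    values, degenerate = _values(heatmap)
    mask = np.asarray(mask)
    if values.shape != mask.shape:
        raise ScoringError(f"heat map shape {values.shape} != mask shape "
                           f"{mask.shape}")
    flat_mask = (mask > 0).astype(np.float64).ravel()
    if flat_mask.min() == flat_mask.max():
        raise ScoringError("mask is constant (all zero or all one): "
                           "shape correlation undefined")
    if degenerate:
        return 0.0, 0.0
    flat = values.ravel()
    pearson = float(stats.pearsonr(flat, flat_mask).statistic)
    spearman = float(stats.spearmanr(flat, flat_mask).statistic)
    return pearson, spearman


def score_image(heatmap: HeatMap, image: AnnotatedImage,
                model_tag: str = "") -> InterpretabilityScores:
    """Scores for one already-computed heat map."""
    if heatmap.degenerate:
        return InterpretabilityScores(
            image_id=image.image_id, nodule_max=0.0, nodule_mean=0.0,
            pearson=0.0, spearman=0.0, degenerate=True,
            cam_variant=heatmap.variant, patient_id=image.patient_id,
            model_tag=model_tag)
    n_max, n_mean = nodule_locality(heatmap, image.mask)
    pearson, spearman = shape_correlation(heatmap, image.mask)
    return InterpretabilityScores(
        image_id=image.image_id, nodule_max=n_max, nodule_mean=n_mean,
        pearson=pearson, spearman=spearman, degenerate=False,
        cam_variant=heatmap.variant, patient_id=image.patient_id,
        model_tag=model_tag)


def score_table(images: Sequence[AnnotatedImage], model,
                cam_config: CamConfig = CamConfig(),
                model_tag: str = "",
                target_class: int | None = None) -> pd.DataFrame:
    """One score row per image per CAM variant.

    ``target_class`` selects whose evidence the heat map shows.  The default
    (``None``) targets the model's predicted class — the decision being
    explained.  Passing a fixed class index (typically the malignant class)
    renders every heat map in the same units, "where the model sees evidence
    for that class", which is how nodule heat maps are usually compared
    across images.  Returns a DataFrame with the :data:`SCORE_COLUMNS`
    layout.
    """
    rows = []
    for image in images:
        if image.mask.max() == 0:
            raise ScoringError(f"image {image.image_id} has an empty mask")
        if target_class is None:
            target = int(np.argmax(model.forward(image.pixels)))
        else:
            target = int(target_class)
        for heatmap in compute_cam(model, image.pixels, target,
                                   cam_config).values():
            rows.append(asdict(score_image(heatmap, image, model_tag)))
    table = pd.DataFrame(rows)
    return table[SCORE_COLUMNS] if len(table) else \
        pd.DataFrame(columns=SCORE_COLUMNS)
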