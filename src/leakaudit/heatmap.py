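"""Class activation heat maps (Grad-CAM style) and image overlays.

The map is built from the model's last convolutional activations ``A_k`` and
the gradient of the target class's pre-softmax score with respect to them:
each channel's neuron weight ``w_k`` is the spatial average of its gradient,
the per-pixel channel contributions ``w_k * A_k`` are combined across
channels by an average and/or a maximum, negative values are (optionally)
rectified away, and the result is min-max normalized to [0, 1] and
bilinearly upsampled to the image resolution.  A constant pre-normalization
map has no spatial information; it is flagged ``degenerate`` and rendered as
all zeros.

Any object exposing ``last_conv_activations(image)`` and
``class_score_gradient(image, target_class)`` (see
:class:`leakaudit._net.SmallConvNet`) can be mapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize as _sk_resize

from ._net import ContractViolation

__all__ = ["CamConfig", "HeatMap", "compute_cam", "overlay",
           "write_heatmap", "read_heatmap", "CAM_VARIANTS"]

CAM_VARIANTS = ("weighted_average", "weighted_maximum")


@dataclass(frozen=True)
class CamConfig:
    """How channel contributions are reduced and post-processed."""

    channel_combination: str = "both"   # weighted_average|weighted_maximum|both
    rectify_negative: bool = True
    upsampling: str = "bilinear"
    colormap_name: str = "jet"

    def __post_init__(self) -> None:
        allowed = CAM_VARIANTS + ("both",)
        if self.channel_combination not in allowed:
            raise ValueError(f"channel_combination must be one of {allowed}")
        if self.upsampling != "bilinear":
            raise ValueError("only bilinear upsampling is supported")

    @property
    def variants(self) -> tuple[str, ...]:
        if self.channel_combination == "both":
            return CAM_VARIANTS
        return (self.channel_combination,)


@dataclass
class HeatMap:
    """Per-image attention map on the image grid, min-max scaled to [0, 1]."""

    values: np.ndarray                      # (H, W) in [0, 1]
    degenerate: bool
    native_resolution: tuple[int, int]      # conv-grid shape before upsampling
    normalization_bounds: tuple[float, float]
    variant: str = "weighted_average"


def _normalize(values: np.ndarray) -> tuple[np.ndarray, bool,
                                            tuple[float, float]]:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0.0:
        return np.zeros_like(values), True, (lo, hi)
    return (values - lo) / (hi - lo), False, (lo, hi)


def compute_cam(model, image: np.ndarray, target_class: int,
                config: CamConfig = CamConfig()) -> dict[str, HeatMap]:
    """Heat map(s) for one image, keyed by channel-combination variant.

    With ``channel_combination="both"`` (the default) the returned dict has
    the ``weighted_average`` and ``weighted_maximum`` entries; otherwise a
    single entry.
    """
    image = np.asarray(image, dtype=np.float64)
    activations = np.asarray(model.last_conv_activations(image),
                             dtype=np.float64)
    gradients = np.asarray(
        model.class_score_gradient(image, int(target_class)),
        dtype=np.float64)
    if gradients.shape != activations.shape:
        raise ContractViolation(
            f"gradient shape {gradients.shape} does not match activation "
            f"shape {activations.shape}")
    weights = gradients.mean(axis=(1, 2))            # neuron weights w_k
    contrib = weights[:, None, None] * activations   # (C, h, w)
    out: dict[str, HeatMap] = {}
    for variant in config.variants:
        if variant == "weighted_average":
            raw = contrib.mean(axis=0)
        else:
            raw = contrib.max(axis=0)
        if config.rectify_negative:
            raw = np.maximum(raw, 0.0)
        native = raw.shape
        if raw.shape != image.shape:
            up = _sk_resize(raw, image.shape, order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
        else:
            up = raw
        values, degenerate, bounds = _normalize(up)
        out[variant] = HeatMap(values=values, degenerate=degenerate,
                               native_resolution=native,
                               normalization_bounds=bounds, variant=variant)
    return out


def overlay(image: np.ndarray, heatmap: HeatMap | np.ndarray,
            colormap_name: str = "jet", alpha: float = 0.35) -> np.ndarray:
    """Alpha-blend the color-mapped heat map onto the grayscale image.

    Returns an (H, W, 3) float RGB array in [0, 1]; ``alpha=0`` reproduces
    the grayscale image, ``alpha=1`` the pure color-mapped map.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    values = heatmap.values if isinstance(heatmap, HeatMap) else \
        np.asarray(heatmap, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if values.shape != image.shape:
        raise ValueError(f"heat map shape {values.shape} does not match "
                         f"image shape {image.shape}")
    cmap = colormaps[colormap_name]
    colored = cmap(values)[..., :3]
    gray = np.repeat(image[..., None], 3, axis=2)
    return (1.0 - alpha) * gray + alpha * colored


def write_heatmap(heatmap: HeatMap, path: str | Path) -> None:
    """Persist as 16-bit grayscale PNG plus a JSON sidecar."""
    path = Path(path)
    arr = np.round(heatmap.values * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)  # uint16 -> 16-bit grayscale PNG
    sidecar = {
        "degenerate": heatmap.degenerate,
        "native_resolution": list(heatmap.native_resolution),
        "normalization_bounds": list(heatmap.normalization_bounds),
        "variant": heatmap.variant,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_heatmap(path: str | Path) -> HeatMap:
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return HeatMap(values=arr, degenerate=meta["degenerate"],
                   native_resolution=tuple(meta["native_resolution"]),
                   normalization_bounds=tuple(meta["normalization_bounds"]),
                   variant=meta["variant"])
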