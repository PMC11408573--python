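"""Nodule labelling from radiologist scores, and small-angle rotation
augmentation.

A nodule is labelled from the malignancy scores (integers 1-5) of its raters:
it needs at least three raters to count at all; the exact rational average is
then thresholded at <= 1.5 (benign) and >= 3.5 (malignant), everything in
between is excluded.  Averages are kept as exact fractions so the 1.5/3.5
boundaries are decided without float round-off.

Augmentation replicates each image at small rotations (default +/-2 and
+/-4 degrees) about the image centre, which multiplies the dataset size by
five at the default angles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .phantom import AnnotatedImage

__all__ = ["NoduleLabel", "label_from_scores", "augment_rotations",
           "DEFAULT_ANGLES"]

DEFAULT_ANGLES: tuple[float, ...] = (2.0, -2.0, 4.0, -4.0)

MIN_RATERS = 3
BENIGN_MAX_AVG = Fraction(3, 2)      # average <= 1.5  -> benign
MALIGNANT_MIN_AVG = Fraction(7, 2)   # average >= 3.5  -> malignant


@dataclass(frozen=True)
class NoduleLabel:
    """Label derived from rater scores: benign / malignant / excluded."""

    value: str                      # "benign" | "malignant" | "excluded"
    average_score: Fraction | None  # exact rational average; None if no scores


def label_from_scores(scores: Sequence[int]) -> NoduleLabel:
    """Apply the labelling rule to a list of radiologist scores.

    Fewer than three raters excludes the nodule regardless of the scores.
    The average is computed as an exact rational, so e.g. [1, 1, 2] with
    average 4/3 is benign and [2, 3, 2] with average 7/3 is excluded.
    """
    scores = list(scores)
    for s in scores:
        if not isinstance(s, (int, np.integer)) or not 1 <= int(s) <= 5:
            raise ValueError(f"radiologist scores must be integers in 1..5, "
                             f"got {s!r}")
    avg = Fraction(sum(int(s) for s in scores), len(scores)) if scores else None
    if len(scores) < MIN_RATERS:
        return NoduleLabel("excluded", avg)
    if avg <= BENIGN_MAX_AVG:
        return NoduleLabel("benign", avg)
    if avg >= MALIGNANT_MIN_AVG:
        return NoduleLabel("malignant", avg)
    return NoduleLabel("excluded", avg)


def _rotate_pair(pixels: np.ndarray, mask: np.ndarray, angle: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    if angle == 0.0:
        return pixels.copy(), mask.copy()
    background = float(pixels[mask == 0].mean()) if (mask == 0).any() \
        else float(pixels.mean())
    rot_pixels = _sk_rotate(pixels, angle, order=1, mode="constant",
                            cval=background, preserve_range=True)
    rot_mask = _sk_rotate(mask.astype(float), angle, order=1, mode="constant",
                          cval=0.0, preserve_range=True)
    return np.clip(rot_pixels, 0.0, 1.0), (rot_mask >= 0.5).astype(np.uint8)


def augment_rotations(image: AnnotatedImage,
                      angles: Sequence[float] = DEFAULT_ANGLES
                      ) -> list[AnnotatedImage]:
    """Return the original image plus one rotated copy per angle.

    Pixels are rotated with bilinear interpolation about the image centre;
    regions rotated in from outside the frame are filled with the image's
    background (non-nodule) mean.  The mask is rotated with the same
    transform and re-binarized at 0.5, keeping it aligned with the nodule for
    downstream interpretability scoring.  ``augmentation_angle`` and
    ``source_image_id`` record the provenance of each copy.
    """
    out = [image]
    for angle in angles:
        pixels, mask = _rotate_pair(image.pixels, image.mask, float(angle))
        sign = "+" if angle >= 0 else "-"
        suffix = f"r{sign}{abs(float(angle)):g}"
        out.append(replace(
            image,
            image_id=f"{image.image_id}_{suffix}",
            pixels=pixels,
            mask=mask,
            radiologist_scores=list(image.radiologist_scores),
            augmentation_angle=float(angle),
            source_image_id=image.image_id,
        ))
    return out
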