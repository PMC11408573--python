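"""Synthetic phantom-CT cohort with a planted patient-identity leakage channel.

Each patient owns a small stack of 2-D grayscale "slices" showing two
elliptical lung fields (shared anatomy) and exactly one nodule per slice.
Benign nodules are smooth disks; malignant nodules are larger and spiculated
(disk plus radial spikes).  On top of this class signal every patient carries
a private *identity signature*: a low-amplitude sinusoidal texture inside a
smooth patch at a patient-specific location, with patient-specific spatial
frequencies and phases, never touching the nodule mask.  Because all slices
of a patient share the signature, an image-wise (patient-leaking) train/test
split lets a classifier recognise the patient instead of the nodule — the
leakage channel this package audits.

Two further controls shape the study: a fixed number of slices per patient
are *ambiguous* — their nodule is a plain disk whose radius falls in the gap
between the benign and malignant ranges, so the image itself carries no
class information while the label (the patient's class) remains valid.  No
image-based classifier can beat chance on ambiguous slices of unseen
patients, which caps honest accuracy; a model that has memorised patient
identities can simply look the class up, which is exactly the advantage an
image-wise split hands out.  An optional per-slice clutter texture (off by
default) adds patient-independent structure.

All generation is a pure function of :class:`PhantomSpec`; identical specs
(including the seed) produce byte-identical cohorts.  Pixel intensities are
quantized to the 8-bit grid at generation time so that writing to PNG and
reading back is an exact round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomSpec",
    "PatientPhantom",
    "AnnotatedImage",
    "generate_cohort",
    "assign_radiologist_scores",
    "write_cohort",
    "read_cohort",
    "cohort_manifest",
]

# Base tissue intensities (fraction of full scale).
_AIR = 0.05
_BODY = 0.50
_LUNG = 0.18
_NODULE_CONTRAST = 0.35

# Lung-field ellipse geometry as fractions of the image side.  Anatomy is
# shared by all patients: the sinusoidal signature must be the only
# patient-identity channel, so that signature_strength=0 is a true
# no-leakage ablation.
_LUNG_SEMI_ROW = 0.33
_LUNG_SEMI_COL = 0.22
_LUNG_CENTER_ROW = 0.52
_LUNG_CENTER_COLS = (0.30, 0.70)
_ANATOMY_JITTER = 0.0

# Per-patient signature spatial frequencies (cycles/pixel).  Periods of
# ~7-20 px keep the texture coarse enough to survive the small-angle
# rotation augmentation (a memorised patient signature still matches the
# rotated copies of that patient's slices, which is what an image-wise split
# leaks) while fine enough that a patch a few periods wide is distinctive:
# two patients' patches rarely look alike.
_SIGNATURE_FREQ_RANGE = (0.05, 0.15)

# The signature lives inside a Gaussian window ("patch") whose centre is
# patient-specific, drawn uniformly on an annulus around the body centre.
# sigma and the annulus radii are fractions of the image side.  A +/-4
# degree rotation moves the patch centre by well under sigma, so the patch
# survives augmentation; spreading centres over the annulus keeps different
# patients' patches from piling onto the same pixels.
_SIGNATURE_PATCH_SIGMA = 0.12
_SIGNATURE_PATCH_RING = (0.16, 0.38)

# Malignant spiculation: radius modulated up to this factor of the base radius.
_SPIKE_FACTOR = 1.2
_NODULE_MARGIN = 2.0  # pixels kept between nodule rim and lung-field boundary

MANIFEST_COLUMNS = [
    "image_id", "patient_id", "nodule_id", "class", "radiologist_scores",
    "augmentation_angle", "source_image_id", "ambiguous", "split",
]


class CohortValidationError(ValueError):
    """A PhantomSpec field violates the generator's invariants."""


class CohortIOError(IOError):
    """A cohort directory is inconsistent (e.g. a manifest row without files)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cohort.

    Radii are in pixels.  ``signature_strength`` is the amplitude of the
    per-patient sinusoidal identity texture as a fraction of full intensity
    scale; ``noise_sd`` is the standard deviation of i.i.d. Gaussian pixel
    noise and ``clutter_strength`` the amplitude of an optional per-slice
    (patient-independent) texture on the same scale.
    ``malignant_radius_range[0]`` must be at least ``benign_radius_range[1]``
    so the classes are separable by size by construction.
    ``ambiguous_per_patient`` slices per patient (an even number) are
    rendered with a plain disk whose radius falls in the gap between the two
    class ranges — half at a low (benign-leaning) and half at a high
    (malignant-leaning) gap radius, identically for both classes.  The image
    is class-uninformative, and because any size-based decision threshold
    inside the gap gets exactly half of each patient's ambiguous slices
    right, accuracy on unseen patients is capped at
    ``1 - ambiguous/(2*slices)`` with essentially no per-patient variance.
    A patient-memorizing (leaking) model can instead recover those labels
    from the identity signature.

    The defaults are the desk-scale study conditions used by
    :func:`leakaudit.experiment.desk_spec`.
    """

    n_patients_benign: int = 12
    n_patients_malignant: int = 12
    slices_per_patient: int = 8
    image_size: int = 64
    benign_radius_range: tuple[float, float] = (3.0, 4.5)
    malignant_radius_range: tuple[float, float] = (8.0, 9.5)
    signature_strength: float = 0.30
    noise_sd: float = 0.05
    clutter_strength: float = 0.0
    ambiguous_per_patient: int = 4
    seed: int = 0
    n_raters: int = 4
    score_jitter: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_patients_benign", "n_patients_malignant",
                     "slices_per_patient"):
            if getattr(self, name) < 1:
                raise CohortValidationError(f"{name} must be >= 1, got "
                                            f"{getattr(self, name)}")
        if self.image_size < 32:
            raise CohortValidationError("image_size must be >= 32")
        for name in ("benign_radius_range", "malignant_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise CohortValidationError(
                    f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        if self.malignant_radius_range[0] < self.benign_radius_range[1]:
            raise CohortValidationError(
                "malignant_radius_range low must be >= benign_radius_range "
                "high (classes must be size-separable)")
        # The largest spiculated nodule (plus margin) must fit inside the
        # narrowest lung-field ellipse a patient can draw.
        semi_col = (1.0 - _ANATOMY_JITTER) * _LUNG_SEMI_COL * self.image_size
        max_reach = self.malignant_radius_range[1] * _SPIKE_FACTOR
        if max_reach + _NODULE_MARGIN > semi_col:
            raise CohortValidationError(
                f"malignant_radius_range high ({self.malignant_radius_range[1]}"
                f") does not fit inside the lung field at image_size "
                f"{self.image_size} (max reach {max_reach:.1f}px, lung "
                f"semi-axis {semi_col:.1f}px)")
        if not 0.0 <= self.signature_strength <= 1.0:
            raise CohortValidationError("signature_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise CohortValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.clutter_strength <= 1.0:
            raise CohortValidationError("clutter_strength must be in [0, 1]")
        if not 0 <= self.ambiguous_per_patient <= self.slices_per_patient:
            raise CohortValidationError(
                f"ambiguous_per_patient must be in [0, slices_per_patient], "
                f"got {self.ambiguous_per_patient} with slices_per_patient "
                f"{self.slices_per_patient}")
        if self.ambiguous_per_patient % 2 != 0:
            raise CohortValidationError(
                "ambiguous_per_patient must be even (half low-gap, half "
                f"high-gap radii), got {self.ambiguous_per_patient}")
        if self.n_raters < 1:
            raise CohortValidationError("n_raters must be >= 1")
        if self.score_jitter < 0:
            raise CohortValidationError("score_jitter must be >= 0")


@dataclass
class AnnotatedImage:
    """One slice: grayscale pixels in [0, 1], binary nodule mask, metadata."""

    image_id: str
    patient_id: str
    nodule_id: str
    pixels: np.ndarray          # float64 in [0,1], quantized to the 8-bit grid
    mask: np.ndarray            # uint8 in {0,1}, same shape
    radiologist_scores: list[int]
    class_label: str            # ground-truth patient class: benign|malignant
    augmentation_angle: float = 0.0
    source_image_id: str = ""
    ambiguous: bool = False     # nodule rendered class-uninformative

    def __post_init__(self) -> None:
        if not self.source_image_id:
            self.source_image_id = self.image_id
        if self.pixels.shape != self.mask.shape:
            raise CohortValidationError(
                f"pixels/mask shape mismatch for {self.image_id}")


@dataclass
class PatientPhantom:
    """One synthetic patient: identity signature, anatomy, slice stack."""

    patient_id: str
    class_label: str
    signature_params: dict      # freq_row, freq_col (cycles/px), phase, amplitude
    anatomy_params: dict        # two lung-field ellipses (center/semi-axes, px)
    slices: list[AnnotatedImage] = field(default_factory=list)


def _lung_ellipses(image_size: int, rng: np.random.Generator) -> dict:
    """Two lung-field ellipses (shared geometry; see _ANATOMY_JITTER note)."""
    n = image_size
    ellipses = []
    for c_col in _LUNG_CENTER_COLS:
        j = (lambda: 1.0 + rng.uniform(-_ANATOMY_JITTER, _ANATOMY_JITTER)) \
            if _ANATOMY_JITTER > 0 else (lambda: 1.0)
        ellipses.append({
            "center_row": _LUNG_CENTER_ROW * n * j(),
            "center_col": c_col * n * j(),
            "semi_row": _LUNG_SEMI_ROW * n * j(),
            "semi_col": _LUNG_SEMI_COL * n * j(),
        })
    return {"ellipses": ellipses}


def _ellipse_interior(shape: tuple[int, int], e: dict,
                      shrink: float = 0.0) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    sr = max(e["semi_row"] - shrink, 1.0)
    sc = max(e["semi_col"] - shrink, 1.0)
    return (((rows - e["center_row"]) / sr) ** 2
            + ((cols - e["center_col"]) / sc) ** 2) <= 1.0


def _nodule_shape(shape: tuple[int, int], center: tuple[float, float],
                  radius: float, malignant: bool,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask and anti-aliased intensity bump for one nodule.

    Malignant nodules get radial spikes: r(theta) = r * (1 + a*cos(m*theta+p)^8)
    with m lobes; benign nodules are plain disks.
    """
    rows, cols = np.indices(shape)
    dr = rows - center[0]
    dc = cols - center[1]
    dist = np.hypot(dr, dc)
    if malignant:
        m = int(rng.integers(5, 10))
        phase = rng.uniform(0, 2 * np.pi)
        theta = np.arctan2(dr, dc)
        r_theta = radius * (1.0 + (_SPIKE_FACTOR - 1.0)
                            * np.cos(m * theta + phase) ** 8)
    else:
        r_theta = np.full(shape, radius)
    mask = (dist <= r_theta).astype(np.uint8)
    bump = np.clip(r_theta - dist, 0.0, 1.0)  # 1-px anti-aliased rim
    return mask, bump


def _render_slice(spec: PhantomSpec, anatomy: dict, signature: dict,
                  malignant: bool, rng: np.random.Generator,
                  ambiguous: str = "") -> tuple[np.ndarray, np.ndarray]:
    n = spec.image_size
    shape = (n, n)
    pixels = np.full(shape, _AIR)

    # Body: one large ellipse behind both lungs.
    body = {"center_row": n * 0.52, "center_col": n * 0.5,
            "semi_row": n * 0.42, "semi_col": n * 0.46}
    pixels[_ellipse_interior(shape, body)] = _BODY
    for e in anatomy["ellipses"]:
        pixels[_ellipse_interior(shape, e)] = _LUNG

    # Place the nodule fully inside one lung field.  An ambiguous slice gets
    # a plain disk with one of two fixed radii at the thirds of the gap
    # between the class ranges, regardless of the patient's class: identical
    # for both classes, hence carrying no class information.
    if ambiguous:
        b_hi = spec.benign_radius_range[1]
        m_lo = spec.malignant_radius_range[0]
        third = (m_lo - b_hi) / 3.0
        radius = b_hi + (third if ambiguous == "low" else 2.0 * third)
        malignant = False  # plain disk, no spiculation
    else:
        lo, hi = (spec.malignant_radius_range if malignant
                  else spec.benign_radius_range)
        radius = rng.uniform(lo, hi)
    reach = radius * (_SPIKE_FACTOR if malignant else 1.0) + _NODULE_MARGIN
    e = anatomy["ellipses"][int(rng.integers(0, 2))]
    allowed = _ellipse_interior(shape, e, shrink=reach)
    if not allowed.any():  # pragma: no cover - excluded by spec validation
        raise CohortValidationError("nodule does not fit inside the lung field")
    flat = np.flatnonzero(allowed)
    idx = flat[int(rng.integers(0, flat.size))]
    center = (idx // n, idx % n)
    mask, bump = _nodule_shape(shape, center, radius, malignant, rng)
    pixels = pixels + _NODULE_CONTRAST * bump

    # Patient-identity signature, outside the nodule only: a sinusoidal
    # texture inside a smooth patient-specific patch (a Gaussian window at a
    # patient-specific location).  Localizing the signature keeps it
    # spatially disjoint from the nodule and makes a memorised signature
    # detector respond only where *that* patient's patch lives, so unseen
    # patients barely excite it.
    if signature["amplitude"] > 0:
        rows, cols = np.indices(shape)
        wave = (np.sin(2 * np.pi * signature["freq_row"] * rows
                       + signature["phase"])
                * np.sin(2 * np.pi * signature["freq_col"] * cols
                         + signature["phase2"]))
        d2 = ((rows - signature["center_row"]) ** 2
              + (cols - signature["center_col"]) ** 2)
        sigma = _SIGNATURE_PATCH_SIGMA * n
        window = np.exp(-d2 / (2.0 * sigma * sigma))
        # Demean over the applied weights: the signature is a zero-net-DC
        # texture, so it never shifts a slice's mean intensity (a quantity
        # that carries class information through nodule area).
        region = (1.0 - mask) * window
        wave = wave - (wave * region).sum() / region.sum()
        pixels = pixels + signature["amplitude"] * wave * region

    # Per-slice clutter texture: random nodule-scale blobs, independent of
    # the patient, emulating slice-specific acquisition texture.  It bounds
    # how well any classifier can size the nodule on an unseen image, without
    # carrying patient identity.
    if spec.clutter_strength > 0:
        rows, cols = np.indices(shape)
        cf1, cf2 = rng.uniform(0.06, 0.15, 2)
        cp1, cp2 = rng.uniform(0, 2 * np.pi, 2)
        clutter = (np.sin(2 * np.pi * cf1 * rows + cp1)
                   * np.sin(2 * np.pi * cf2 * cols + cp2))
        pixels = pixels + spec.clutter_strength * clutter

    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, shape)

    pixels = np.clip(pixels, 0.0, 1.0)
    pixels = np.round(pixels * 255.0) / 255.0  # 8-bit grid: PNG round trip
    return pixels, mask


def assign_radiologist_scores(patient: PatientPhantom, n_raters: int,
                              score_jitter: float, seed: int
                              ) -> dict[str, list[int]]:
    """Draw per-nodule malignancy scores (1-5) from ``n_raters`` raters.

    Scores are centred on the patient's class (1 for benign, 5 for
    malignant); each rater's score is the centre plus Gaussian jitter,
    rounded and clamped to [1, 5].  With ``score_jitter=0`` benign nodules
    average exactly 1.0 and malignant exactly 5.0.  The raters act on the
    patient record, so ambiguous slices are scored like the rest of the
    patient even though their image carries no class information.  Scores
    are written back onto the patient's slices and also returned as a
    mapping nodule_id -> scores.
    """
    if n_raters < 1:
        raise CohortValidationError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    center = 1.0 if patient.class_label == "benign" else 5.0
    out: dict[str, list[int]] = {}
    for img in patient.slices:
        raw = center + rng.normal(0.0, score_jitter, n_raters)
        scores = np.clip(np.round(raw), 1, 5).astype(int).tolist()
        img.radiologist_scores = scores
        out[img.nodule_id] = scores
    return out


def generate_cohort(spec: PhantomSpec) -> list[PatientPhantom]:
    """Generate the full cohort described by ``spec``.

    Returns ``n_patients_benign + n_patients_malignant`` patients, each with
    ``slices_per_patient`` original (unaugmented) slices carrying the
    patient's identity signature and one nodule of the patient's class.
    """
    root = np.random.SeedSequence(spec.seed)
    classes = (["benign"] * spec.n_patients_benign
               + ["malignant"] * spec.n_patients_malignant)
    patient_seeds = root.spawn(len(classes))
    cohort: list[PatientPhantom] = []
    for p_idx, (label, pseed) in enumerate(zip(classes, patient_seeds)):
        rng = np.random.default_rng(pseed)
        patient_id = f"P{p_idx:03d}"
        theta = rng.uniform(0, 2 * np.pi)
        lo2, hi2 = (r * spec.image_size for r in _SIGNATURE_PATCH_RING)
        ring = float(np.sqrt(rng.uniform(lo2 ** 2, hi2 ** 2)))  # area-uniform
        signature = {
            "freq_row": rng.uniform(*_SIGNATURE_FREQ_RANGE),
            "freq_col": rng.uniform(*_SIGNATURE_FREQ_RANGE),
            "phase": rng.uniform(0, 2 * np.pi),
            "phase2": rng.uniform(0, 2 * np.pi),
            "amplitude": spec.signature_strength,
            "center_row": float(0.52 * spec.image_size + ring * np.sin(theta)),
            "center_col": float(0.50 * spec.image_size + ring * np.cos(theta)),
        }
        anatomy = _lung_ellipses(spec.image_size, rng)
        patient = PatientPhantom(patient_id=patient_id, class_label=label,
                                 signature_params=signature,
                                 anatomy_params=anatomy)
        if spec.ambiguous_per_patient:
            chosen = rng.choice(spec.slices_per_patient,
                                size=spec.ambiguous_per_patient,
                                replace=False).tolist()
            half = spec.ambiguous_per_patient // 2
            ambiguous_kind = {idx: ("low" if i < half else "high")
                              for i, idx in enumerate(chosen)}
        else:
            ambiguous_kind = {}
        for s_idx in range(spec.slices_per_patient):
            pixels, mask = _render_slice(spec, anatomy, signature,
                                         label == "malignant", rng,
                                         ambiguous=ambiguous_kind.get(s_idx,
                                                                      ""))
            img = AnnotatedImage(
                image_id=f"{patient_id}_s{s_idx:02d}",
                patient_id=patient_id,
                nodule_id=f"{patient_id}_n{s_idx:02d}",
                pixels=pixels, mask=mask,
                radiologist_scores=[], class_label=label,
                ambiguous=bool(ambiguous_kind.get(s_idx)),
            )
            patient.slices.append(img)
        score_seed = int(np.random.default_rng(pseed).integers(0, 2 ** 31))
        assign_radiologist_scores(patient, spec.n_raters, spec.score_jitter,
                                  score_seed)
        cohort.append(patient)
    return cohort


def cohort_images(cohort: Sequence[PatientPhantom]) -> list[AnnotatedImage]:
    """All slices of all patients, in cohort order."""
    return [img for patient in cohort for img in patient.slices]


def cohort_manifest(images: Sequence[AnnotatedImage],
                    split: dict[str, str] | None = None) -> pd.DataFrame:
    """Manifest DataFrame (one row per image) for a set of annotated images."""
    rows = []
    for img in images:
        rows.append({
            "image_id": img.image_id,
            "patient_id": img.patient_id,
            "nodule_id": img.nodule_id,
            "class": img.class_label,
            "radiologist_scores": ";".join(map(str, img.radiologist_scores)),
            "augmentation_angle": img.augmentation_angle,
            "source_image_id": img.source_image_id,
            "ambiguous": int(img.ambiguous),
            "split": (split or {}).get(img.image_id, ""),
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def _write_png(path: Path, array_u8: np.ndarray) -> None:
    Image.fromarray(array_u8, mode="L").save(path)


def write_cohort(cohort: Sequence[PatientPhantom], directory: str | Path,
                 split: dict[str, str] | None = None) -> Path:
    """Write a cohort to ``directory`` (images/, masks/, manifest.csv).

    Images are stored as 8-bit grayscale PNGs, masks as {0, 255} PNGs.
    Per-patient signature/anatomy parameters go to patients.json so that
    :func:`read_cohort` can rebuild the full :class:`PatientPhantom` objects.
    Returns the manifest path.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    images = cohort_images(cohort)
    for img in images:
        _write_png(directory / "images" / f"{img.image_id}.png",
                   np.round(img.pixels * 255.0).astype(np.uint8))
        _write_png(directory / "masks" / f"{img.image_id}.png",
                   (img.mask * 255).astype(np.uint8))
    manifest = cohort_manifest(images, split)
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    meta = {
        p.patient_id: {
            "class_label": p.class_label,
            "signature_params": p.signature_params,
            "anatomy_params": p.anatomy_params,
        } for p in cohort
    }
    (directory / "patients.json").write_text(json.dumps(meta, indent=1))
    return manifest_path


def read_cohort(directory: str | Path) -> list[PatientPhantom]:
    """Read a cohort written by :func:`write_cohort` (exact round trip)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", dtype=str,
                           keep_default_na=False)
    meta = json.loads((directory / "patients.json").read_text())
    patients: dict[str, PatientPhantom] = {}
    for pid, m in meta.items():
        patients[pid] = PatientPhantom(
            patient_id=pid, class_label=m["class_label"],
            signature_params=m["signature_params"],
            anatomy_params=m["anatomy_params"])
    for _, row in manifest.iterrows():
        img_path = directory / "images" / f"{row.image_id}.png"
        mask_path = directory / "masks" / f"{row.image_id}.png"
        for path in (img_path, mask_path):
            if not path.exists():
                raise CohortIOError(
                    f"manifest row for image_id={row.image_id!r} refers to a "
                    f"missing file: {path}")
        pixels = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
        mask = (np.asarray(Image.open(mask_path)) >= 128).astype(np.uint8)
        scores = ([int(s) for s in row.radiologist_scores.split(";")]
                  if row.radiologist_scores else [])
        pid = row.patient_id
        if pid not in patients:
            raise CohortIOError(f"patient {pid!r} missing from patients.json")
        patients[pid].slices.append(AnnotatedImage(
            image_id=row.image_id, patient_id=pid, nodule_id=row.nodule_id,
            pixels=pixels, mask=mask, radiologist_scores=scores,
            class_label=row["class"],
            augmentation_angle=float(row.augmentation_angle),
            source_image_id=row.source_image_id,
            ambiguous=bool(int(row.ambiguous)),
        ))
    return list(patients.values())
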