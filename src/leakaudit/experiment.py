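"""Paired fair/unfair study on a phantom cohort.

One experiment generates a cohort, labels and augments it, carves out a
challenge set of whole patients, then trains two classifiers from the same
pool with identical configuration and seeds — one under a patient-wise
("fair") split with per-epoch MCCV validation, one under an image-wise
("unfair") split — and reports test accuracy, challenge accuracy, and CAM
interpretability scores for both arms.  The only factor varying between the
arms is the split mode, so any gap between them is attributable to patient
leakage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import (PhantomSpec, AnnotatedImage, generate_cohort,
                      cohort_images, cohort_manifest)
from .annotation import label_from_scores, augment_rotations, DEFAULT_ANGLES
from .splitting import (carve_challenge_set, split_imagewise,
                        split_patientwise, mccv_schedule, audit_leakage,
                        SplitPlan)
from .classifier import (TrainingConfig, NoduleClassifier, TrainingResults,
                         evaluate_accuracy, CLASS_NAMES)
from .heatmap import CamConfig, HeatMap, compute_cam, overlay
from .scoring import score_table

__all__ = ["ExperimentReport", "FairUnfairExperiment",
           "run_fair_unfair_experiment", "render_report", "desk_spec"]

logger = logging.getLogger("leakaudit")

_LABEL_TO_INT = {name: i for i, name in enumerate(CLASS_NAMES)}


def desk_spec(seed: int = 0, signature_strength: float = 0.30,
              noise_sd: float = 0.05) -> PhantomSpec:
    """Desk-scale study cohort: 12+12 patients, 8 slices each, 64 px slices.

    These are exactly the :class:`~leakaudit.phantom.PhantomSpec` defaults —
    small enough that the full paired experiment (two training arms) runs in
    a few minutes on one CPU, while keeping per-patient multi-slice
    structure, size-separable classes, the per-patient ambiguous slices
    and the identity-signature channel.  Only the seed and the two
    leakage-relevant amplitudes are exposed for overriding here.
    """
    return PhantomSpec(signature_strength=signature_strength,
                       noise_sd=noise_sd, seed=seed)


@dataclass
class ExperimentReport:
    """Everything one paired run produced."""

    accuracy_table: pd.DataFrame     # model_tag, n_epochs, fair/unfair accs
    scores: pd.DataFrame             # per-image interpretability scores
    histories: dict[str, pd.DataFrame]
    provenance: dict
    sampled_images: list[AnnotatedImage] = field(default_factory=list)
    panel_heatmaps: dict[str, dict[str, HeatMap]] = field(default_factory=dict)

    @property
    def fair_gap(self) -> float:
        row = self.accuracy_table.iloc[0]
        return float(row.fair_test - row.fair_challenge)

    @property
    def unfair_gap(self) -> float:
        row = self.accuracy_table.iloc[0]
        return float(row.unfair_test - row.unfair_challenge)

    def median_score(self, model_tag: str, column: str,
                     cam_variant: str = "weighted_average") -> float:
        s = self.scores
        sel = s[(s.model_tag == model_tag) & (s.cam_variant == cam_variant)]
        return float(sel[column].median())

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(tag for tag in ("fair", "unfair")
                     if f"{tag}_test" in self.accuracy_table.columns)

    def summary(self) -> str:
        row = self.accuracy_table.iloc[0]
        names = {"fair": "fair (patient-wise)", "unfair": "unfair (image-wise)"}
        lines = [
            "Paired fair/unfair split experiment",
            "=" * 52,
            f"{'':20s}{'test acc':>10s}{'challenge acc':>15s}{'gap':>8s}",
        ]
        for tag in self.arms:
            gap = row[f"{tag}_test"] - row[f"{tag}_challenge"]
            lines.append(f"{names[tag]:<20s}{row[f'{tag}_test']:>10.3f}"
                         f"{row[f'{tag}_challenge']:>15.3f}{gap:>8.3f}")
        lines += ["", "interpretability (median over sampled test images, "
                      "weighted_average CAM):"]
        for col in ("nodule_mean", "nodule_max", "pearson", "spearman"):
            meds = "   ".join(
                f"{tag} {self.median_score(tag, col):8.4f}"
                for tag in self.arms)
            lines.append(f"  {col:<12s} {meds}")
        return "\n".join(lines)


def _prepared_images(spec: PhantomSpec, angles: Sequence[float]
                     ) -> tuple[list[AnnotatedImage], dict[str, str]]:
    """Generate, label (dropping excluded nodules) and augment the cohort."""
    cohort = generate_cohort(spec)
    images: list[AnnotatedImage] = []
    labels: dict[str, str] = {}
    n_excluded = 0
    for img in cohort_images(cohort):
        lab = label_from_scores(img.radiologist_scores)
        if lab.value == "excluded":
            n_excluded += 1
            continue
        for aug in augment_rotations(img, angles):
            images.append(aug)
            labels[aug.image_id] = lab.value
    if n_excluded:
        logger.info("excluded %d nodules with indeterminate scores",
                    n_excluded)
    return images, labels


def _arrays(ids: Sequence[str], by_id: dict[str, AnnotatedImage],
            labels: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([by_id[i].pixels for i in ids]).astype(np.float32)
    y = np.array([_LABEL_TO_INT[labels[i]] for i in ids])
    return x, y


class FairUnfairExperiment:
    """Model-like wrapper: configure once, ``run()`` to get the report."""

    def __init__(self, spec: PhantomSpec | None = None,
                 config: TrainingConfig | None = None,
                 fractions: tuple[float, float, float] = (0.5, 0.2, 0.3),
                 challenge_counts: tuple[int, int] = (4, 4),
                 n_score_images: int = 8,
                 cam_config: CamConfig = CamConfig(),
                 angles: Sequence[float] = DEFAULT_ANGLES,
                 arms: Sequence[str] = ("fair", "unfair"),
                 seed: int = 0):
        self.spec = spec if spec is not None else desk_spec(seed=seed)
        self.config = config or TrainingConfig()
        self.fractions = fractions
        self.challenge_counts = challenge_counts
        self.n_score_images = n_score_images
        self.cam_config = cam_config
        self.angles = tuple(angles)
        self.arms = tuple(arms)
        if not self.arms or any(a not in ("fair", "unfair")
                                for a in self.arms):
            raise ValueError(f"arms must be a nonempty subset of "
                             f"('fair', 'unfair'), got {arms}")
        self.seed = seed

    def run(self) -> ExperimentReport:
        t0 = time.perf_counter()
        ss = np.random.SeedSequence(self.seed)
        seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                 for name, s in zip(
                     ("challenge", "unfair", "fair", "mccv", "sample"),
                     ss.spawn(5))}
        images, labels = _prepared_images(self.spec, self.angles)
        by_id = {img.image_id: img for img in images}
        manifest = cohort_manifest(images)
        logger.info("cohort prepared: %d images from %d patients",
                    len(images), manifest.patient_id.nunique())

        challenge_patients, pool = carve_challenge_set(
            manifest, *self.challenge_counts, seed=seeds["challenge"])
        challenge_ids = manifest.loc[
            manifest.patient_id.isin(challenge_patients), "image_id"].tolist()

        unfair_plan = split_imagewise(pool, self.fractions, seeds["unfair"])
        fair_plan = split_patientwise(pool, self.fractions, seeds["fair"])
        fair_audit = audit_leakage(fair_plan, manifest)
        unfair_audit = audit_leakage(unfair_plan, manifest)
        logger.info("leak audit: fair %d patients, unfair %d patients",
                    fair_audit["n_leaking"], unfair_audit["n_leaking"])

        results: dict[str, TrainingResults] = {}

        if "unfair" in self.arms:
            # --- unfair arm: static image-wise split ---------------------
            cfg_unfair = replace(self.config, mccv=False)
            x_tr, y_tr = _arrays(unfair_plan.images_in("train"), by_id,
                                 labels)
            x_va, y_va = _arrays(unfair_plan.images_in("validation"), by_id,
                                 labels)
            results["unfair"] = NoduleClassifier(
                x_tr, y_tr, validation=(x_va, y_va), config=cfg_unfair).fit()
            logger.info("unfair arm trained in %.1fs",
                        time.perf_counter() - t0)

        if "fair" in self.arms:
            # --- fair arm: patient-wise split + MCCV ---------------------
            t1 = time.perf_counter()
            cfg_fair = replace(self.config, mccv=True)
            trainval_ids = (fair_plan.images_in("train")
                            + fair_plan.images_in("validation"))
            pool_df = pool.set_index("image_id")
            patient_classes = {p: c for p, c in sorted(
                set(zip(pool_df.loc[trainval_ids, "patient_id"],
                        pool_df.loc[trainval_ids, "class"])))}
            denom = self.fractions[0] + self.fractions[1]
            schedule = mccv_schedule(patient_classes,
                                     val_fraction=self.fractions[1] / denom,
                                     n_epochs=cfg_fair.n_epochs,
                                     seed=seeds["mccv"])
            x_pool, y_pool = _arrays(trainval_ids, by_id, labels)
            pids = pool_df.loc[trainval_ids, "patient_id"].to_numpy()
            results["fair"] = NoduleClassifier(
                x_pool, y_pool, mccv_schedule=schedule, patient_ids=pids,
                config=cfg_fair).fit()
            logger.info("fair arm trained in %.1fs",
                        time.perf_counter() - t1)

        # --- evaluation ---------------------------------------------------
        x_ch, y_ch = _arrays(challenge_ids, by_id, labels)
        plans = {"fair": fair_plan, "unfair": unfair_plan}
        row: dict[str, object] = {"model_tag": "small_cnn",
                                  "n_epochs": self.config.n_epochs}
        for tag, res in results.items():
            x_te, y_te = _arrays(plans[tag].images_in("test"), by_id, labels)
            row[f"{tag}_test"] = evaluate_accuracy(res, x_te, y_te)
            row[f"{tag}_challenge"] = evaluate_accuracy(res, x_ch, y_ch)
        accuracy_table = pd.DataFrame([row])

        # --- interpretability on a shared sample of held-out originals ---
        rng = np.random.default_rng(seeds["sample"])
        sample_plan = fair_plan if "fair" in self.arms else unfair_plan
        candidates = sorted(i for i in sample_plan.images_in("test")
                            if by_id[i].augmentation_angle == 0.0)
        n_take = min(self.n_score_images, len(candidates))
        sampled_ids = sorted(rng.choice(candidates, size=n_take,
                                        replace=False).tolist())
        sampled = [by_id[i] for i in sampled_ids]
        scores = pd.concat(
            [score_table(sampled, results[tag].model, self.cam_config, tag)
             for tag in self.arms], ignore_index=True)
        panel: dict[str, dict[str, HeatMap]] = {tag: {} for tag in self.arms}
        for tag in self.arms:
            model = results[tag].model
            for img in sampled:
                target = int(np.argmax(model.forward(img.pixels)))
                cams = compute_cam(model, img.pixels, target,
                                   CamConfig(channel_combination=
                                             "weighted_average"))
                panel[tag][img.image_id] = cams["weighted_average"]

        provenance = {
            "phantom_spec": asdict(self.spec),
            "training_config": self.config.to_dict(),
            "fractions": list(self.fractions),
            "challenge_counts": list(self.challenge_counts),
            "angles": list(self.angles),
            "arms": list(self.arms),
            "seed": self.seed,
            "stage_seeds": seeds,
            "challenge_patients": sorted(challenge_patients),
            "fair_audit": fair_audit,
            "unfair_audit": unfair_audit,
            "n_images": len(images),
            "sampled_image_ids": sampled_ids,
        }
        logger.info("experiment finished in %.1fs", time.perf_counter() - t0)
        return ExperimentReport(
            accuracy_table=accuracy_table, scores=scores,
            histories={tag: res.history for tag, res in results.items()},
            provenance=provenance, sampled_images=sampled,
            panel_heatmaps=panel)


def run_fair_unfair_experiment(
        spec: PhantomSpec | None = None,
        config: TrainingConfig | None = None,
        fractions: tuple[float, float, float] = (0.5, 0.2, 0.3),
        challenge_counts: tuple[int, int] = (4, 4),
        seed: int = 0, **kwargs) -> ExperimentReport:
    """Run the whole paired study; see :class:`FairUnfairExperiment`."""
    return FairUnfairExperiment(spec=spec, config=config, fractions=fractions,
                                challenge_counts=challenge_counts, seed=seed,
                                **kwargs).run()


def render_report(report: ExperimentReport, directory: str | Path
                  ) -> list[Path]:
    """Write accuracy_table.csv, scores.csv, histories, provenance.json and
    the overlay panel (mask | image | fair CAM | unfair CAM per row)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(name: str, fn) -> None:
        path = directory / name
        fn(path)
        written.append(path)

    _w("accuracy_table.csv",
       lambda p: report.accuracy_table.to_csv(p, index=False))
    _w("scores.csv", lambda p: report.scores.to_csv(p, index=False))
    for tag, hist in report.histories.items():
        _w(f"history_{tag}.csv", lambda p, h=hist: h.to_csv(p, index=False))
    _w("provenance.json", lambda p: p.write_text(
        json.dumps(report.provenance, indent=1, default=str)))

    if len(report.sampled_images) == 0 or report.scores.empty:
        logger.warning("no sampled images with scores; overlay panel omitted")
        return written

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arms = [tag for tag in ("fair", "unfair") if tag in report.panel_heatmaps]
    n = len(report.sampled_images)
    n_cols = 2 + len(arms)
    fig, axes = plt.subplots(n, n_cols, figsize=(2.25 * n_cols, 2.2 * n),
                             squeeze=False)
    titles = ("mask", "image") + tuple(f"{tag} CAM" for tag in arms)
    for r, img in enumerate(report.sampled_images):
        panels = [img.mask, img.pixels] + [
            overlay(img.pixels, report.panel_heatmaps[tag][img.image_id])
            for tag in arms]
        for c, (ax, data) in enumerate(zip(axes[r], panels)):
            ax.imshow(data, cmap=None if data.ndim == 3 else "gray",
                      vmin=0, vmax=1)
            ax.set_axis_off()
            if r == 0:
                ax.set_title(titles[c], fontsize=9)
        axes[r][0].set_ylabel(img.image_id, fontsize=7)
    fig.tight_layout()
    _w("panel.png", lambda p: fig.savefig(p, dpi=110))
    plt.close(fig)
    return written
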