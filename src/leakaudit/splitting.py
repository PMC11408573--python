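"""Image-wise ("unfair") and patient-wise ("fair") dataset splitting.

The unfair split shuffles individual images into train/validation/test, so
slices (and augmented copies) of one patient routinely straddle partitions —
the leakage hazard under audit.  The fair split assigns whole patients to a
single partition.  A challenge set of whole patients is carved out before
either split and never touches the train/validation/test pool.  Monte Carlo
cross-validation (MCCV) redraws the patient-level train/validation assignment
independently at every epoch.

All operations act on a manifest DataFrame with at least the columns
``image_id``, ``patient_id`` and ``class`` (see
:func:`leakaudit.phantom.cohort_manifest`), are stratified by class, and are
pure functions of their seed.  Fractional partition sizes are resolved with
the largest-remainder method, ties broken toward train.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SplitPlan", "MccvSchedule", "carve_challenge_set", "split_imagewise",
    "split_patientwise", "mccv_schedule", "audit_leakage",
]

PARTITIONS = ("train", "validation", "test")


class SplitError(ValueError):
    """A split request is infeasible (bad fractions, too few patients...)."""


@dataclass
class SplitPlan:
    """Assignment of every image to exactly one partition."""

    mode: str                                  # "fair" | "unfair"
    assignment: dict[str, str]                 # image_id -> partition
    fractions: tuple[float, float, float]      # train/validation/test
    seed: int

    def images_in(self, partition: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == partition]


@dataclass
class MccvSchedule:
    """Per-epoch patient-level train/validation assignments."""

    epoch_assignments: list[dict[str, str]]    # patient_id -> train|validation
    val_fraction: float
    seed: int

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_assignments)


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer partition sizes summing to n; ties go to earlier partitions."""
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    short = n - sum(sizes)
    # Stable sort by descending remainder; equal remainders keep partition
    # order (train before validation before test).
    order = sorted(range(len(fractions)), key=lambda i: -remainders[i])
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def _check_fractions(fractions: Sequence[float]) -> tuple[float, float, float]:
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f < 0 for f in fr) or not np.isclose(sum(fr), 1.0):
        raise SplitError(f"fractions must be three nonnegatives summing to 1, "
                         f"got {fractions}")
    return fr  # type: ignore[return-value]


def _patient_classes(manifest: pd.DataFrame) -> pd.Series:
    per_patient = manifest.groupby("patient_id")["class"].agg("first")
    return per_patient.sort_index()


def carve_challenge_set(manifest: pd.DataFrame, n_benign_patients: int,
                        n_malignant_patients: int, seed: int
                        ) -> tuple[list[str], pd.DataFrame]:
    """Pick whole patients (per class) for the challenge set.

    Returns the selected patient ids and the remaining pool manifest.  The
    selected patients and every one of their images (including augmented
    copies) are excluded from any later split.
    """
    classes = _patient_classes(manifest)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for label, want in (("benign", n_benign_patients),
                        ("malignant", n_malignant_patients)):
        avail = sorted(classes.index[classes == label])
        if want > len(avail):
            raise SplitError(f"requested {want} challenge patients of class "
                             f"{label!r} but only {len(avail)} available")
        chosen.extend(rng.choice(avail, size=want, replace=False).tolist())
    pool = manifest[~manifest["patient_id"].isin(chosen)].copy()
    return chosen, pool


def split_imagewise(pool: pd.DataFrame, fractions: Sequence[float],
                    seed: int) -> SplitPlan:
    """Unfair split: images shuffled and partitioned individually.

    Stratified by class; patient overlap across partitions is permitted (and,
    on any multi-slice cohort, expected)."""
    fr = _check_fractions(fractions)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for _, group in pool.groupby("class", sort=True):
        ids = sorted(group["image_id"])
        rng.shuffle(ids)
        sizes = _largest_remainder(len(ids), fr)
        start = 0
        for part, size in zip(PARTITIONS, sizes):
            for image_id in ids[start:start + size]:
                assignment[image_id] = part
            start += size
    return SplitPlan(mode="unfair", assignment=assignment, fractions=fr,
                     seed=seed)


def split_patientwise(pool: pd.DataFrame, fractions: Sequence[float],
                      seed: int) -> SplitPlan:
    """Fair split: whole patients shuffled and partitioned; images follow.

    Stratified by class.  With three nonzero fractions each class needs at
    least three patients so every partition can receive one."""
    fr = _check_fractions(fractions)
    rng = np.random.default_rng(seed)
    classes = _patient_classes(pool)
    n_nonzero = sum(1 for f in fr if f > 0)
    assignment: dict[str, str] = {}
    patient_part: dict[str, str] = {}
    for label in sorted(classes.unique()):
        patients = sorted(classes.index[classes == label])
        if len(patients) < n_nonzero:
            raise SplitError(f"class {label!r} has {len(patients)} patients; "
                             f"need >= {n_nonzero} for a patient-wise split "
                             f"with {n_nonzero} nonzero fractions")
        rng.shuffle(patients)
        sizes = _largest_remainder(len(patients), fr)
        start = 0
        for part, size in zip(PARTITIONS, sizes):
            for pid in patients[start:start + size]:
                patient_part[pid] = part
            start += size
    for image_id, pid in zip(pool["image_id"], pool["patient_id"]):
        assignment[image_id] = patient_part[pid]
    return SplitPlan(mode="fair", assignment=assignment, fractions=fr,
                     seed=seed)


def mccv_schedule(patient_classes: Mapping[str, str] | Sequence[str],
                  val_fraction: float, n_epochs: int, seed: int
                  ) -> MccvSchedule:
    """Monte Carlo cross-validation: redraw validation patients every epoch.

    ``patient_classes`` maps patient id to class (validation patients are
    drawn per class stratum); a plain sequence of patient ids is treated as a
    single stratum.  Each epoch's train and validation patient sets are
    disjoint and together cover the pool.
    """
    if not 0.0 < val_fraction < 1.0:
        raise SplitError("val_fraction must be in (0, 1)")
    if n_epochs < 1:
        raise SplitError("n_epochs must be >= 1")
    if isinstance(patient_classes, Mapping):
        by_class: dict[str, list[str]] = {}
        for pid, label in patient_classes.items():
            by_class.setdefault(label, []).append(pid)
    else:
        by_class = {"all": list(patient_classes)}
    by_class = {k: sorted(v) for k, v in sorted(by_class.items())}
    for label, pids in by_class.items():
        n_val = round(len(pids) * val_fraction)
        if n_val < 1:
            raise SplitError(f"val_fraction {val_fraction} rounds to 0 "
                             f"validation patients for class {label!r}")
        if n_val >= len(pids):
            raise SplitError(f"val_fraction {val_fraction} leaves no training "
                             f"patients for class {label!r}")
    rng = np.random.default_rng(seed)
    epochs: list[dict[str, str]] = []
    for _ in range(n_epochs):
        assignment: dict[str, str] = {}
        for pids in by_class.values():
            n_val = round(len(pids) * val_fraction)
            val = set(rng.choice(pids, size=n_val, replace=False).tolist())
            for pid in pids:
                assignment[pid] = "validation" if pid in val else "train"
        epochs.append(assignment)
    return MccvSchedule(epoch_assignments=epochs, val_fraction=val_fraction,
                        seed=seed)


def audit_leakage(plan: SplitPlan, manifest: pd.DataFrame) -> dict:
    """Report patients whose images span more than one partition.

    Returns ``{"leaking_patients": [...], "n_leaking": int, "counts":
    {partition: {class: n}}}``.  An empty leak set is exactly the fair
    (patient-disjoint) property.  Challenge images in the manifest (if any)
    are outside the plan and are ignored.
    """
    known = manifest.set_index("image_id")
    missing = [i for i in plan.assignment if i not in known.index]
    if missing:
        raise SplitError(f"plan contains image ids missing from the manifest: "
                         f"{missing[:5]}")
    rows = known.loc[list(plan.assignment)]
    parts = pd.Series(plan.assignment, name="partition")
    table = rows.assign(partition=parts)
    span = table.groupby("patient_id")["partition"].nunique()
    leaking = sorted(span.index[span > 1])
    counts = {
        part: sub.groupby("class")["patient_id"].count().to_dict()
        for part, sub in table.groupby("partition")
    }
    return {"leaking_patients": leaking, "n_leaking": len(leaking),
            "counts": counts}
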