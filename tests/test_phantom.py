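"""Cohort generator: counts, determinism, leakage channel, round trip."""

import numpy as np
import pytest
from scipy import stats

from leakaudit.phantom import (PhantomSpec, generate_cohort,
                               assign_radiologist_scores, write_cohort,
                               read_cohort, cohort_images, cohort_manifest,
                               CohortValidationError, CohortIOError)

from conftest import tiny_spec


def test_cohort_counts():
    spec = tiny_spec(n_patients_benign=8, n_patients_malignant=8,
                     slices_per_patient=10, seed=7)
    cohort = generate_cohort(spec)
    assert len(cohort) == 16
    images = cohort_images(cohort)
    assert len(images) == 160
    assert all(img.mask.shape == img.pixels.shape for img in images)
    assert len({img.image_id for img in images}) == 160


def test_determinism_byte_identical():
    spec = tiny_spec(seed=7)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    for pa, pb in zip(a, b):
        assert pa.signature_params == pb.signature_params
        for ia, ib in zip(pa.slices, pb.slices):
            assert np.array_equal(ia.pixels, ib.pixels)
            assert np.array_equal(ia.mask, ib.mask)
            assert ia.radiologist_scores == ib.radiologist_scores
    ma = cohort_manifest(cohort_images(a))
    mb = cohort_manifest(cohort_images(b))
    assert ma.equals(mb)


def test_slices_share_signature_and_nodule_class_geometry(small_cohort):
    for patient in small_cohort:
        amplitudes = {img.pixels.shape for img in patient.slices}
        assert len(amplitudes) == 1
        masks = [img.mask for img in patient.slices]
        # exactly one nodule per slice: one 8-connected mask blob
        # (spiculation tips can touch the core diagonally)
        from scipy import ndimage
        eight = np.ones((3, 3), dtype=int)
        for m in masks:
            assert m.max() == 1
            _, n_blobs = ndimage.label(m, structure=eight)
            assert n_blobs == 1
    sig = [tuple(sorted(p.signature_params.items())) for p in small_cohort]
    assert len(set(sig)) == len(small_cohort)  # continuous params all differ


def test_malignant_nodules_larger(small_cohort):
    benign_areas = [img.mask.sum() for p in small_cohort
                    if p.class_label == "benign" for img in p.slices
                    if not img.ambiguous]
    malignant_areas = [img.mask.sum() for p in small_cohort
                       if p.class_label == "malignant" for img in p.slices
                       if not img.ambiguous]
    assert max(benign_areas) < min(malignant_areas)


def test_pixels_quantized_and_bounded(small_cohort):
    img = small_cohort[0].slices[0]
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
    assert np.allclose(img.pixels * 255, np.round(img.pixels * 255))
    assert set(np.unique(img.mask)) <= {0, 1}


@pytest.mark.parametrize("field, value", [
    ("n_patients_benign", 0),
    ("slices_per_patient", 0),
    ("benign_radius_range", (5.0, 3.0)),
    ("malignant_radius_range", (3.0, 7.0)),  # low < benign high
    ("signature_strength", 1.5),
    ("noise_sd", -0.1),
])
def test_invalid_spec_raises_naming_field(field, value):
    with pytest.raises(CohortValidationError):
        tiny_spec(**{field: value})


def test_radiologist_scores_zero_jitter(small_cohort):
    benign = next(p for p in small_cohort if p.class_label == "benign")
    malignant = next(p for p in small_cohort if p.class_label == "malignant")
    sb = assign_radiologist_scores(benign, n_raters=4, score_jitter=0.0,
                                   seed=0)
    assert all(v == [1, 1, 1, 1] for v in sb.values())
    sm = assign_radiologist_scores(malignant, n_raters=3, score_jitter=0.0,
                                   seed=0)
    assert all(v == [5, 5, 5] for v in sm.values())


def test_ambiguous_counts_exact_and_class_uninformative():
    """Exactly k slices per patient are flagged ambiguous; their nodules are
    plain disks at the same two gap radii regardless of the patient's class,
    so the set of mask areas is identical across classes."""
    spec = tiny_spec(n_patients_benign=3, n_patients_malignant=3,
                     slices_per_patient=4, ambiguous_per_patient=2, seed=13)
    areas = {"benign": set(), "malignant": set()}
    for patient in generate_cohort(spec):
        flagged = [img for img in patient.slices if img.ambiguous]
        assert len(flagged) == 2
        for img in flagged:
            areas[patient.class_label].add(int(img.mask.sum()))
    # two fixed disk radii (low/high gap), shared by both classes
    assert areas["benign"] == areas["malignant"]
    assert len(areas["benign"]) == 2


def test_ambiguous_radius_between_class_ranges():
    spec = tiny_spec(ambiguous_per_patient=2, seed=13)
    cohort = generate_cohort(spec)
    disk_area = {int(i.mask.sum()) for p in cohort for i in p.slices
                 if i.ambiguous}
    benign_max = max(int(i.mask.sum()) for p in cohort for i in p.slices
                     if not i.ambiguous and p.class_label == "benign")
    malignant_min = min(int(i.mask.sum()) for p in cohort for i in p.slices
                        if not i.ambiguous and p.class_label == "malignant")
    assert all(benign_max < a < malignant_min for a in disk_area)


def test_ambiguous_zero_means_all_informative():
    spec = tiny_spec(ambiguous_per_patient=0, seed=13)
    assert all(not img.ambiguous
               for img in cohort_images(generate_cohort(spec)))


def test_ambiguous_exceeding_slices_invalid():
    with pytest.raises(CohortValidationError, match="ambiguous_per_patient"):
        tiny_spec(slices_per_patient=3, ambiguous_per_patient=4)


def test_ambiguous_odd_invalid():
    with pytest.raises(CohortValidationError, match="even"):
        tiny_spec(slices_per_patient=4, ambiguous_per_patient=3)


def test_radiologist_scores_clamped(small_cohort):
    patient = small_cohort[0]
    scores = assign_radiologist_scores(patient, n_raters=5, score_jitter=10.0,
                                       seed=3)
    for v in scores.values():
        assert all(1 <= s <= 5 for s in v)


def test_zero_signature_background_statistics_indistinguishable():
    """With signature_strength=0 the backgrounds of any two patients differ
    only by noise: a two-sample mean test on mutual background pixels rejects
    at alpha=0.01 in <5% of 100 random cross-patient slice pairs."""
    spec = tiny_spec(n_patients_benign=5, n_patients_malignant=5,
                     slices_per_patient=4, signature_strength=0.0, seed=23)
    images = cohort_images(generate_cohort(spec))
    rng = np.random.default_rng(5)
    rejections = 0
    for _ in range(100):
        a, b = rng.choice(len(images), size=2, replace=False)
        ia, ib = images[a], images[b]
        if ia.patient_id == ib.patient_id:
            continue
        both_bg = (ia.mask == 0) & (ib.mask == 0)
        p = stats.ttest_ind(ia.pixels[both_bg], ib.pixels[both_bg],
                            equal_var=False).pvalue
        rejections += p < 0.01
    assert rejections <= 5


def test_signature_is_a_patient_identity_channel():
    """A nearest-centroid classifier on background pixels identifies the
    patient of a held-out slice far above chance when the signature is
    strong, and near chance when it is absent."""

    def holdout_accuracy(strength: float) -> float:
        spec = tiny_spec(n_patients_benign=5, n_patients_malignant=5,
                         slices_per_patient=4, signature_strength=strength,
                         noise_sd=0.05, seed=31)
        cohort = generate_cohort(spec)
        centroids, tests = [], []
        for k, patient in enumerate(cohort):
            bg = [img.pixels * (1 - img.mask) for img in patient.slices]
            centroids.append(np.mean(bg[:-1], axis=0))
            tests.append((bg[-1], k))
        correct = 0
        for held_out, k in tests:
            dists = [np.linalg.norm(held_out - c) for c in centroids]
            correct += int(np.argmin(dists)) == k
        return correct / len(tests)

    assert holdout_accuracy(0.25) >= 0.8      # chance = 0.1
    assert holdout_accuracy(0.0) <= 0.5


def test_write_read_round_trip(tmp_path, small_cohort):
    manifest_path = write_cohort(small_cohort, tmp_path)
    assert manifest_path.exists()
    back = read_cohort(tmp_path)
    orig_by_id = {img.image_id: img for img in cohort_images(small_cohort)}
    back_images = cohort_images(back)
    assert len(back_images) == len(orig_by_id)
    for img in back_images:
        orig = orig_by_id[img.image_id]
        assert np.array_equal(img.pixels, orig.pixels)
        assert np.array_equal(img.mask, orig.mask)
        assert img.radiologist_scores == orig.radiologist_scores
    m1 = cohort_manifest(cohort_images(small_cohort))
    m2 = cohort_manifest(back_images)
    assert m1.sort_values("image_id").reset_index(drop=True).equals(
        m2.sort_values("image_id").reset_index(drop=True))


def test_empty_cohort_manifest_header_only(tmp_path):
    path = write_cohort([], tmp_path)
    text = path.read_text().strip().splitlines()
    assert len(text) == 1 and text[0].startswith("image_id,")


def test_missing_png_error_names_image(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path)
    victim = small_cohort[0].slices[0].image_id
    (tmp_path / "masks" / f"{victim}.png").unlink()
    with pytest.raises(CohortIOError, match=victim):
        read_cohort(tmp_path)
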