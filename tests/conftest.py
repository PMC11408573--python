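import numpy as np
import pytest

from leakaudit.phantom import PhantomSpec, generate_cohort


def tiny_spec(**overrides) -> PhantomSpec:
    """A minimal but valid cohort spec for fast unit tests."""
    defaults = dict(
        n_patients_benign=4, n_patients_malignant=4, slices_per_patient=3,
        image_size=64, benign_radius_range=(3.0, 4.5),
        malignant_radius_range=(5.5, 7.0), signature_strength=0.25,
        noise_sd=0.05, ambiguous_per_patient=2, seed=11,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(tiny_spec())


@pytest.fixture(scope="session")
def fake_manifest():
    """Manifest-shaped DataFrame without any pixel data: 20 patients x 10
    slices, balanced classes — enough structure for split/audit tests."""
    import pandas as pd
    rows = []
    for p in range(20):
        cls = "benign" if p < 10 else "malignant"
        for s in range(10):
            rows.append({"image_id": f"P{p:03d}_s{s:02d}",
                         "patient_id": f"P{p:03d}", "class": cls})
    return pd.DataFrame(rows)
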