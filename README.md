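# leakaudit

**Fair vs. unfair train/test splitting for CT nodule classifiers, on a
synthetic phantom cohort with a planted patient-identity leak.**

When a nodule classifier is trained and evaluated with an *image-wise* split
— individual slices assigned to train/val/test with no regard for which
patient they came from — almost every patient ends up on both sides of the
split. The model can then pass the test by recognizing *patients* instead of
*pathology*: test accuracy is inflated, and attention maps drift off the
nodule. A *patient-wise* split (each patient's images in exactly one
partition, validation patients reshuffled every epoch by Monte-Carlo
cross-validation) removes the leak and reports honest numbers.

Real CT data can only show this effect correlationally. `leakaudit` instead
*plants* the leak: it generates a fully synthetic phantom cohort in which a
patient-identity channel exists by construction, is spatially disjoint from
the nodule, and can be switched off — so the inflation is measurable,
mechanistically attributable, and ablatable. See
[`docs/methods.md`](docs/methods.md) for the full construction.

## The model in one paragraph

Each synthetic patient is a stack of 64×64 phantom-CT slices: shared lung
anatomy, one nodule per slice (benign = small smooth disk, malignant = large
spiculated mass — size-separable by construction), Gaussian noise, and a
private patient *signature*: a low-frequency sinusoidal texture in a Gaussian
patch at a patient-specific location, zero-mean, applied only outside the
nodule mask. Half of each patient's slices are *ambiguous* — plain disks
with radius inside the gap between the class ranges, labelled with the
patient's class — so any honest, geometry-based rule is capped near 75%
accuracy on unseen patients, while a model that has memorized patient
signatures can look the label up and beat the cap on slices of *seen*
patients. The paired experiment trains the same small NumPy CNN (conv stack
with global average+max pooling, Grad-CAM-compatible) under both split modes
and compares (a) test-minus-challenge accuracy gaps, where the challenge set
is whole held-out patients, and (b) CAM interpretability scores against the
ground-truth nodule masks.

## Worked example

Generate, label, augment, split, and audit a cohort from the command line
(output below is from a real run):

```console
$ leakaudit generate --out demo --seed 7
demo/manifest.csv
$ leakaudit label --dir demo
{"malignant": 96, "benign": 94, "excluded": 2}
$ leakaudit augment --dir demo
960 images after augmentation
$ leakaudit split --dir demo --mode unfair --seed 7
{"mode": "unfair", "n_leaking": 16, "audit": "demo/audit_unfair.json"}
$ leakaudit split --dir demo --mode fair --seed 7
{"mode": "fair", "n_leaking": 0, "audit": "demo/audit_fair.json"}
```

24 patients × 8 slices = 192 originals; rater consensus labels 190 of them
and excludes 2; ±2°/±4° rotation augmentation yields 960 images. After
carving 8 challenge patients, the image-wise split leaks all 16 remaining
patients across partitions; the patient-wise split leaks none.

The same audit from Python:

```python
from leakaudit import (PhantomSpec, generate_cohort, cohort_manifest,
                       carve_challenge_set, split_imagewise,
                       split_patientwise, audit_leakage)

spec = PhantomSpec(seed=7)
cohort = generate_cohort(spec)
manifest = cohort_manifest(img for p in cohort for img in p.slices)
challenge, pool = carve_challenge_set(manifest, 4, 4, seed=7)
for name, splitter in [("image-wise", split_imagewise),
                       ("patient-wise", split_patientwise)]:
    plan = splitter(pool, (0.5, 0.2, 0.3), seed=7)
    audit = audit_leakage(plan, manifest)
    print(f"{name:12s} leaking patients: {audit['n_leaking']}")
```

```
image-wise   leaking patients: 16
patient-wise leaking patients: 0
```

The full paired experiment (two trainings, ~4 minutes on one CPU) writes an
accuracy table, score tables and CAM overlay panels to a report directory:

```sh
leakaudit run-all --out report_seed1 --seed 1
leakaudit report --report-dir report_seed1
```

## Package layout

| Module | Responsibility |
| --- | --- |
| `leakaudit.phantom` | cohort specification, generation, PNG+CSV persistence (bit-exact round trip) |
| `leakaudit.annotation` | rater-consensus labelling, rotation augmentation |
| `leakaudit.splitting` | challenge carving, image-wise/patient-wise splits, MCCV schedule, leakage audit |
| `leakaudit.classifier` | NumPy CNN, Adam, reduce-on-plateau, training loop |
| `leakaudit.heatmap` | Grad-CAM heat maps (two channel combinations), overlays |
| `leakaudit.scoring` | nodule locality and heat-map/mask shape correlation scores |
| `leakaudit.experiment` | the paired fair/unfair experiment and report rendering |
| `leakaudit.cli` | `leakaudit` command-line pipeline |

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give byte-identical cohorts,
trainings and reports.
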