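# Methods

This note describes the synthetic study implemented by `leakaudit`: what the
phantom cohort contains, how the leakage channel is constructed, how the two
training arms differ, and how the accuracy and interpretability read-outs are
defined. Everything here is a description of the construction; the empirical
quantities themselves are computed by the test suite
(`tests/test_acceptance.py`) and by `scripts/acceptance.py`, not asserted in
prose.

## 1. The question

When a CT-nodule classifier is evaluated on a test set that shares patients
with its training set (an *image-wise* split), test accuracy can reflect
patient recognition rather than nodule pathology. `leakaudit` builds a fully
synthetic cohort in which that failure mode is *planted by construction* and
therefore measurable: a patient-identity channel exists, is spatially
disjoint from the nodule, and can be switched off. The study compares a
*fair* arm (patient-wise split, per-epoch Monte-Carlo cross-validation) with
an *unfair* arm (image-wise split) that differ in nothing else.

## 2. Phantom cohort

Each patient is a stack of `slices_per_patient` 64×64 grayscale slices
containing two elliptical lung fields (anatomy shared by all patients) and
exactly one nodule per slice, plus i.i.d. Gaussian pixel noise
(`noise_sd = 0.05`). Class geometry is separable by size by construction:
benign nodules are smooth disks with radius in 3.0–4.5 px, malignant nodules
are spiculated with base radius in 8.0–9.5 px. Four simulated raters score
each nodule 1–5 around the class centre; the consensus labeling rule maps
average score ≤ 1.5 to benign, ≥ 3.5 to malignant, and excludes the middle
band.

Pixel intensities are quantized to the 8-bit grid at generation time, so the
PNG round trip (`write_cohort`/`read_cohort`) is exact, and generation is a
pure function of the `PhantomSpec` (including its seed).

### 2.1 The planted identity signature

Every patient carries a private *signature*: a product-of-sinusoids texture
(frequencies drawn per patient from 0.05–0.15 cycles/px) inside a Gaussian
patch (σ = 0.12·N) centred at a patient-specific location drawn
area-uniformly from an annulus (0.16–0.38)·N around the body centre. The
texture is demeaned over its applied region (zero net DC, so it cannot shift
the mean lung intensity, a quantity that correlates with nodule area) and is
applied only outside the nodule mask, keeping the identity channel spatially
disjoint from the pathology. Its amplitude is `signature_strength`
(default 0.30); at 0 the channel does not exist and patients differ only by
noise — the study's ablation.

The frequency band and patch geometry are chosen so that the signature
survives the ±2°/±4° rotation augmentation: a memorised signature detector
still fires on rotated copies of the same patient's slices, which is
precisely what an image-wise split leaks into the test set.

### 2.2 Ambiguous slices: the accuracy ceiling

`ambiguous_per_patient` slices of each patient (default 4 of 8) are rendered
as plain disks whose radius lies strictly inside the gap between the two
class radius ranges — half at 1/3 of the gap, half at 2/3 — identically for
both classes. Their image content carries no class information, while their
label (the patient's class) remains valid. Consequences:

- Any size-based decision rule gets exactly half of each patient's ambiguous
  slices right, so accuracy on *unseen* patients is capped near
  `1 − ambiguous/(2·slices)` (0.75 at the defaults).
- A model that has memorised patient identities can look the label up from
  the signature and recover ambiguous slices of *seen* patients, exceeding
  the cap on an image-wise test set.

The gap between an image-wise test accuracy and accuracy on truly unseen
patients is therefore a designed, mechanistically understood quantity rather
than an accident of training noise.

## 3. Splits and training arms

From the augmented cohort (each original plus rotations of ±2°, ±4°; ×5
images), a *challenge set* of whole patients (4 benign + 4 malignant) is
carved out first and never enters either split. The remaining pool is split
train/val/test with fractions (0.5, 0.2, 0.3):

- **Fair arm** — `split_patientwise`: every patient's images land in exactly
  one partition; additionally, Monte-Carlo cross-validation reshuffles which
  *patients* form the validation set every epoch.
- **Unfair arm** — `split_imagewise`: images are assigned independently of
  patient, so nearly every patient leaks across partitions (the audit
  `audit_leakage` counts leaking patients; the property is exercised over
  100 seeds in the acceptance tests).

Both arms share the cohort, challenge set, architecture, configuration and
initialization seed; the split mode is the only varying factor.

The classifier is a small CNN implemented in NumPy (three conv blocks with
layer norm and leaky ReLU, two 2×2 max-pools, global average+max pooling,
one hidden layer, two-class softmax; conv channels (12, 16, 32), 24 hidden
units), trained with Adam at lr 1e-3, batch 32, 50 epochs, and a
reduce-on-plateau rule (×0.1 after 15 epochs without validation
improvement).

## 4. Read-outs

**Accuracy gaps.** For each arm, test accuracy minus challenge accuracy.
The challenge set consists of whole unseen patients, so it estimates honest
generalization for both arms; the *unfair gap* measures how much the
image-wise test set overstates it. The ablation repeats the unfair arm at
`signature_strength = 0`.

**Interpretability.** Grad-CAM-style heat maps at the last conv layer
(gradient-weighted activations, channel-combined by average and by maximum,
rectified, min-max normalized, bilinearly upsampled), computed for the
model's predicted class on 8 test images sampled at random from the
unaugmented test originals. Two score families compare each heat map with
the binary nodule mask: nodule locality (max and mean heat inside the mask)
and shape correlation (Pearson and Spearman against the mask). The study
reports per-arm medians over the sampled images.

The CAM gradient implementation is verified against central finite
differences and an analytically solvable toy model; the correlation
implementations are verified against brute-force definitional formulas and
the Spearman monotone-invariance property.

## 5. Determinism

All randomness derives from explicit integer seeds through
`numpy.random.SeedSequence` spawning: cohort generation, challenge carving,
both splits, the MCCV schedule, network initialization, batch shuffling and
the scoring sample each receive an independently derived stream. Identical
seeds reproduce byte-identical cohorts and runs.

## 6. Scope and limitations

- The signature is a deliberate synthetic surrogate for "whatever
  patient-specific feature a real network latches onto"; no claim is made
  that real CT leakage is sinusoidal.
- The fair arm is not a nodule-only model: fitting its own training
  ambiguous slices requires some signature memorization, so fair-arm CAMs
  can carry signature responses that misfire on unseen patients. The
  accuracy-gap contrast is robust to this; the CAM-direction contrast
  (fair more nodule-localized than unfair) is a small-sample median over
  8 images × 3 seeds and is noticeably seed-sensitive.
- Conclusions are about split methodology, not about any particular CNN
  architecture.
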