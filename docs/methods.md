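# Methods

This note records the models, parameter choices and numerical decisions
behind `sinuslms`, and what the synthetic experiments do and do not
demonstrate.

## Pipeline

A coronal sinus CT volume is preprocessed (clip to [−1000, +1000] HU,
crop to an air-driven region of interest, resample each slice to
448×512, z-score per volume), segmented slice-by-slice into the twelve
Lund–Mackay regions by a 2D U-Net, and scored: per region, the fraction
of voxels above an air/soft-tissue threshold maps through a fixed band
rule (0 if < 0.01; 1 if 0.01–0.95 inclusive; 2 if > 0.95) and sub-scores
are summed per side and in total.

## Segmentation network

Encoder stages each open with a strided 3×3 convolution followed by a
stride-1 3×3 convolution; every convolution is followed by instance
normalization and LeakyReLU (slope 0.01). Instance normalization is the
standard companion of this block design and is what keeps the stack
trainable at the configured learning rate. The decoder mirrors the
encoder with kernel-equals-stride transposed convolutions and skip
concatenation; dropout (rate 0.1) sits between the two convolutions of
each decoder block. A final 1×1 convolution emits 13-class logits at
input resolution; prediction is per-pixel argmax with ties broken toward
the lowest class code (background wins ties).

**Bottleneck arithmetic.** Six uniform stride-2 stages map 448 → 7 on
the row axis but 512 → 8 on the column axis. The default configuration
therefore uses per-axis factors (2,2)×5 followed by (2,4), yielding a
480-channel 7×4 bottleneck with channel schedule 32, 64, 128, 256, 480,
480 (cap 480); `default_net_config(uniform_strides=True)` selects the
uniform (2,2)×6 alternative (bottleneck 7×8). Input sizes must be
exactly divisible by the per-axis stride products; anything else is a
configuration error rather than a silent padding choice.

**Training.** Combined loss = soft Dice (averaged over the 12 foreground
classes, smoothing 1e−5) + cross-entropy, weighted 1:1. Adam with
learning rate 0.01, β₁ 0.9, β₂ 0.999; batch size 16; up to 100 epochs
with early stopping (patience 10) on validation loss, restoring the best
weights. No data augmentation. Weight init is He-normal scaled for
LeakyReLU. All randomness (init, shuffling, dropout) derives from one
seed, so runs are bit-reproducible on a single device. The network and
its backward pass are implemented directly in NumPy (im2col convolutions
over BLAS matmuls); gradients are verified against central finite
differences to ~1e−7 relative error in the test suite.

**Cross-validation.** Folds partition *subjects*, never slices
(`sklearn.model_selection.KFold` over shuffled subject IDs), so 77
subjects over 5 folds give validation sizes {16, 16, 15, 15, 15}.
Per-region Dice is averaged over the two sides per subject and
summarized as mean with a seeded percentile-bootstrap 95% CI (1000
resamples) over subjects.

## Scoring

The default threshold is a fixed −300 HU: air (≈ −1000 HU) and any soft
tissue or fluid (≳ 0 HU) sit far on opposite sides, so the count is
insensitive to the exact cutoff over a wide range. An adaptive
alternative (`otsu_per_region`) maximizes between-class variance on each
region's own intensity histogram. Thresholding runs on Hounsfield-scale
intensities before z-score normalization. Fractions are volume-wide per
region (counts aggregated over all slices), not per-slice. Band
endpoints are inclusive in the middle band, making the three bands
exhaustive and non-overlapping. An absent (aplastic) region has no
opacifiable space: it is scored 0 and flagged `absent` (override via
`absent_score`). Clinical practice sometimes scores the ostiomeatal
complex on {0, 2} only; the default applies one rule to all twelve
regions, with `omc_binary=True` collapsing OMC sub-score 1 to 2.

## Evaluation metrics

Dice = 2|A∩B| / (|A|+|B|). Empty-mask convention: both masks empty → 1.0
(perfect agreement on an aplastic region), exactly one empty → 0.0; this
keeps per-region means defined. LMS agreement uses 3×3 confusion tables
of (true, predicted) sub-scores, pooled left+right per sinus type;
accuracy = trace/total, and precision/recall/F1 are weighted by
true-class support, zero-support classes excluded from weighting,
never-predicted classes contributing precision 0. For single-label
multiclass input, weighted recall equals accuracy algebraically — the
suite uses this identity as a self-check.

## Synthetic phantoms

Each phantom is a bone-intensity (+700 HU) stack carved with twelve
non-overlapping ellipsoidal air cavities (−1000 HU) laid out in
anatomically plausible relative positions: maxillary largest, OMC
deliberately tiny (smallest pixel count, the hard case), anterior and
posterior ethmoids separated along the slice axis, sphenoid posterior.
Opacification fills each cavity with soft-tissue intensity (+40 HU) from
the inferior end upward — a flat, deterministic air–fluid level — with
the filled voxel count `round(fraction × cavity size)`, so the realized
fraction deviates from the designed one by quantization only (≤ 1/2N).
Additive Gaussian intensity noise (default sd 20 HU) is applied *after*
the truth table is extracted from the exact construction masks.
Overlapping or out-of-bounds ellipsoids are rejected; on very short
stacks, semi-axes are floored at 1.2 voxels and centers pulled inward so
regions stay non-empty.

The documented fixture suite (`default_fixture_suite`) holds five
volumes — all-clear, all-opacified (designed total 24), all-partial
(0.30), a mixed volume cycling fractions 0.005/0.50/0.96/1.0/0.0/0.30,
and an aplastic variant with the right frontal sinus absent — so every
region visits every score band across the suite. Its default canvas is
448×512 with 24 slices; the suite is generated noiseless so it doubles
as the exact-recovery fixture, with noise added explicitly when testing
robustness.

**What the phantoms do not emulate:** real anatomy (mucosal thickening,
bony septa, Onodi/supraorbital cells, post-surgical cavities), partial
volume effects, beam hardening, or inter-scanner intensity variation.
Passing the synthetic recovery tests demonstrates the correctness of the
counting, mapping and training machinery — not clinical performance.

## Problem sizes for CPU-scale experiments

Training experiments use a small-canvas mode: 112×128 slices, four
stages (channels 16, 32, 64, 128; factors (2,2)×3 + (2,4), preserving
the 7×4 bottleneck shape). The reference scaled-down experiment trains
on 7 synthetic subjects × 10 slices (last subject held out), 20 epochs,
batch 16, with the full-size optimizer settings; under these conditions
the mean validation Dice over the two maxillary region classes exceeds
0.8. Seven subjects were chosen so that an epoch contains enough
optimizer steps for stable convergence in a 20-epoch budget; the
random per-subject fractions (uniform on [0, 1]) force the network to
learn intensity and position cues rather than one fill level.

## Known limitations

- The segmenter trains on one CPU at toy scale; reproducing
  clinical-scale training (tens of thousands of slices, 100 epochs at
  448×512) is out of scope for a NumPy implementation.
- The OMC is small by design and, as with real data, is the hardest
  region; scaled-down runs do not segment it reliably.
- DICOM support covers single coherent series with standard
  rescale/geometry tags; multi-frame and enhanced-CT objects are not
  parsed.
- The ROI crop is driven by sub-threshold (air) voxels dilated by 16
  pixels; volumes with no air below −300 HU fall back to the full frame.
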