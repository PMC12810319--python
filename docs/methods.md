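# Methods

`sift2d` scores cryo-EM 2D class averages with a convolutional regressor
and uses those scores to drive an iterative particle-curation policy.  This
note records the model, the choices that were genuinely open, and what the
synthetic data does and does not establish.

## Quality score and grade rubric

Class quality is expressed on a continuous scale where 1.0 anchors the best
expert grade and 5.0 the worst, via the five-letter rubric A→1, B→2, C→3,
D→4, F→5 (A: sharp, secondary-structure detail; F: unusable, no particle).
The regressor is trained with a mean-square-error loss on these anchors
rather than a classification loss, so its output range is deliberately
open: a class worse than anything in training legitimately scores above 5,
and a better-than-best class below 1.  Scores are never clipped anywhere in
the package.

## Canvas preprocessing

Every input image is mapped onto a fixed 210×210 canvas; the smallest
accepted input is 31×31.

- **Sides > 210** are Fourier-cropped: the central 210×210 block of the
  centered 2D spectrum is kept.  An even-sized crop severs the conjugate
  partner of the band-edge (Nyquist) rows, so the cropped spectrum is
  Hermitian-symmetrized (only the edge rows/columns change; DC — and hence
  the image mean — is untouched).  The result preserves the input mean to
  better than 1e-6 relative, and any pattern band-limited below the crop is
  recovered exactly by Fourier up-sampling.
- **Sides < 210** are standardized (zero mean, unit SD over the whole
  image; a constant image becomes all zeros) and centered in a zero field,
  odd remainders padding the extra row/column at bottom/right.  Padding is
  done in real space after standardization so the padded zeros match the
  background statistics of the standardized image; cropping the central
  block back out reproduces the standardized input bit-exactly.
- **Side = 210** is standardized in place.

Fourier-cropped images are also standardized before scoring, so the
network always sees zero-mean/unit-SD canvases.

## Mass estimation

Particle signal is every pixel strictly above the image mean plus three
standard deviations (statistics over the whole image, population SD, no
morphology).  The mass proxy is the sum of background-mean-subtracted
particle intensities times the pixel area (Å²); the background mean is
subtracted per pixel before summation, the only reading under which the
subsequent sum is meaningful.  A linear calibration fit through the origin
(slope = ΣI·M / ΣI², kDa per intensity·Å²) converts the proxy to kDa on
known-mass standards.  Three per-class features — signed deviations from
the stack's mean, median, and mode mass — feed the scorer; the mode of a
continuous sample is the center of the most populated Freedman–Diaconis
histogram bin (single bin when IQR = 0, ties to the lowest bin; chosen for
scale-freeness).  Deviations are left in kDa, unnormalized: feature scaling
is the scorer's job.

## Scorer architecture

A residual CNN with batch normalization after every convolution.
Downsampling uses two consecutive 2×2 stride-2 convolutions in place of
pooling — a learned, weighted form of average pooling — read literally, so
each downsampling unit quarters the spatial side.  There are no pooling
layers in the trunk.  After the last stage, adaptive average pooling
(PyTorch `AdaptiveAvgPool2d` window semantics: window *i* spans
`[floor(i·H/6), ceil((i+1)·H/6))`) produces a 6×6 map for any trunk
resolution, including maps smaller than 6×6, which are expanded by window
replication.  The pooled map is flattened and concatenated with the six
metadata features (pixel size, FRC resolution, class distribution, and the
three mass deviations), z-scored with training-split statistics stored in
the checkpoint.  A fully connected head ends in a single linear unit — no
softmax.

The default configuration is a 3×3 stem at 32 channels and four residual
stages at widths 32/64/128/256 (two blocks of two 3×3 convolutions each),
trunk resolutions 210→52→13→3; head width 256.  Exact depths and widths
are configurable because the reference layer table is not fixed by the
method's constraints.

**Desk-scale configuration** (`desk_scorer_config`, used by the test and
acceptance suites so a full training run takes minutes on one CPU core):
three stages at widths 4/16/32, one block per stage, head width 64, and the
first downsampling pair moved in front of the stem (`stem_downsample`) so
no convolution runs at full canvas resolution — the position a classical
ResNet reserves for its stem pooling, realized here with the same paired
2×2 stride-2 convolutions.  Candidate widths were compared on short pilot
runs (validation MSE and cross-seed rank correlation) before the test
suite was frozen.

## Training

Adam (learning rate 1e-4, weight decay 1e-4 added to the raw gradient,
matching `torch.optim.Adam` semantics), batch size 32, MSE loss.  A seeded
10% validation split is held out before training; per-epoch train and
validation MSE are recorded on the model.  The regression head's bias is
initialized to the training-label mean — standard practice that removes the
burden of learning the constant at this learning rate.  The default epoch
budget is 200; the suites train 30 epochs, past the point where validation
loss flattens on the synthetic corpus.  All randomness (split, weight
initialization, batch order) flows from one seed, and the engine is pure
single-threaded NumPy, so training is bit-reproducible.

The network engine (`sift2d.nn`) is a small hand-written CPU implementation
(im2col convolutions on BLAS, analytic backward passes, float32 by default
with a float64 switch used by the finite-difference gradient check in the
test suite).

## Evaluation

`evaluate` reports raw MSE on the 1–5 scale and, additionally, maps scores
via s → (5 − s)/4 onto [0, 1] (higher = better) and bins labels and
predictions into 10 equal bins for a confusion matrix; 10 bins matches the
granularity convention of RELION-style class rankers.

## Selection policy

The number of classify→score→route rounds follows the extraction box side:
5 rounds below 200 px, 3 for 200–300 px inclusive, 2 above 300 px.  Each
round every working particle inherits its class score; then

- score ≥ 4.5 → discarded (permanently);
- score ≤ 2.5 → a seeded uniform-random 70% is banked (set aside from
  further rounds), the rest keep working; sampling is global, not
  per-class, with a per-round derived seed;
- 2.5 < score < 4.5 → keep working.

After the scheduled rounds, banked and surviving working particles are
pooled for one final classification and scoring, then split into three
nested batches at final scores ≤ 2.5, ≤ 3.5, ≤ 4.5.  Pooled particles whose
final score exceeds 4.5 are discarded, so the ≤ 4.5 batch and the discard
set exactly partition the input.  If the working set empties early,
remaining rounds are skipped and logged.  The audit log is line-oriented
JSON with sorted keys: identical inputs and seed give a byte-identical log.

`recommend_class2d_params` mirrors the box-size tiers: small boxes
(< 200 px) get the small-particle job settings (3 Å maximum resolution,
initial class uncertainty factor 3, force-max over poses/shifts off, 40
online-EM iterations, batch size 400); 200–300 px keeps defaults; large
boxes (> 300 px) are Fourier-cropped to 100 px with adaptive binning.

The 2D classification engine itself is a pluggable backend (the
`Classifier2DBackend` protocol); the package ships a synthetic backend and
deliberately does not bind to any processing platform.

## Synthetic data

The generator renders simple particle projections (disc, annulus,
two-lobed blob; noise-only for unusable classes) whose integrated
background-subtracted intensity times pixel area equals a target mass under
a unit calibration, then degrades them by grade: Gaussian blur, additive
Gaussian noise (relative to the rendered amplitude), and — past grade 3 —
streak and edge-clip artifacts.

Degradation schedules interpolate between endpoints chosen once so that
grades are spectrally separable and the generator stays consistent with
the 3σ mass estimator: blur is quadratic in grade (σ 0.4→4.0 px) and noise
mildly convex (power 1.5, relative SD 0.01→0.6).  The convexity reflects
real data — class *averages* suppress background noise, so "decent"
classes are sharp and clean and degradation across an expert rubric is
strongly nonlinear — and it keeps unit-calibration mass recovery on
grades 1–2 at a few percent median error, which linear schedules violate.
The FRC-resolution metadata is a self-consistent proxy, not a real FRC:
the frequency where the blur transfer function falls to 0.5 (capped at
Nyquist), mapped to Å via pixel size, inflated by a 1 + 1.5·noise factor
(noise degrades a real FRC too, and the Nyquist cap would otherwise make
the top two grades indistinguishable), and jittered ~12% multiplicatively.

Corpus-level metadata matters: class distributions are drawn within pseudo
classification runs of 10–60 classes — the realistic size of a 2D
classification — so the feature scale during training matches what any
backend produces at scoring time (grade-weighted Gamma variates, better
classes holding more particles).  Mass deviations are computed cohort-wide
with the mass estimator itself.

The synthetic backend groups particles by latent grade plus Gaussian
jitter (SD 0.35 grades) into k contiguous rank groups and renders each
group's class average at the members' median grade.

**What passing tests show, and what they do not.**  The synthetic images
contain none of the physics of real class averages — no CTF, no structured
noise, no preferred orientation, no heterogeneity within a class — and the
metadata proxies are generated from the same latent grade the labels come
from.  Tests on this data therefore establish that the pipeline is wired
correctly end to end (preprocessing, feature fusion, optimization,
routing) and that the scorer can recover a planted quality signal across
generator seeds; they say nothing about accuracy on real micrograph-derived
class averages, which requires an expert-labeled corpus.

## Problem sizes used by the suites

Training: n = 2000 corpus (uniform grade mixture, seed 7), 30 epochs,
desk-scale architecture.  Cross-seed evaluation: n = 500, seed 123.  Sift
simulation: 3000 particles, 20% planted junk, 10 classes, box 150 px
(5 + 1 rounds).  Mass-calibration recovery: 20 standards of 150–800 kDa.

## Numerical notes and limitations

- The Fourier crop takes the real part after Hermitian symmetrization and
  asserts the imaginary residue below 1e-6 relative.
- Standardization of a constant image yields all zeros (SD = 0 guard).
- `route` banks `round(0.70 · n_good)` particles without replacement.
- Boundary semantics are inclusive: "better than or equal to 2.5" is
  ≤ 2.5, "worse than or equal to 4.5" is ≥ 4.5; box sides 200 and 300
  belong to the middle (3-round) band.
- Checkpoints store weights, batch-norm running statistics, feature
  scaling and configuration in one archive; the recorded validation split
  is a runtime attribute and is not persisted.
- The engine is CPU-only and single-threaded by design; training the
  default (full-width) configuration on a large corpus is out of its
  intended envelope.
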