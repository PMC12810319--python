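# sift2d

Quality scoring and iterative curation of cryo-EM 2D class averages.

In single-particle cryo-EM, picked particles are grouped into 2D class
averages, and deciding which classes are "good" is a recurring, subjective
bottleneck: new users need guidance, and high-throughput projects need the
decision automated entirely.  `sift2d` addresses both with

1. **a CNN quality regressor** that maps a class-average image plus six
   platform-independent metadata features to a continuous quality score —
   1.0 (best) to 5.0 (worst) on the training anchors, with *open*
   boundaries: classes worse than anything seen in training score above 5;
2. **an iterative selection policy** that alternates 2D classification,
   scoring and routing to clean a particle stack, banking good particles,
   discarding junk, and keeping ambiguous particles in play.

It is aimed at method developers and pipeline builders: the 2D
classification engine is a pluggable backend, and the package ships a
synthetic data generator so that training, mass calibration and the full
curation loop run end to end with no external data.

## The model

**Score.** Expert grades A–F map to score anchors 1–5 (A "sharp,
secondary-structure detail" → 1.0; F "unusable" → 5.0).  The regressor is
trained with an MSE loss — not softmax — so predictions are real numbers
relative to the training range, never clipped.

**Inputs.** Any square image with side ≥ 31 px is mapped onto a fixed
210×210 canvas: larger images are Fourier-cropped (the central 210×210
block of the centered spectrum), smaller ones standardized and zero-padded.
Alongside the image, six metadata features are fused into the network:
pixel size (Å/px), FRC resolution estimate (Å), relative class
distribution, and the deviations of an intensity-based mass estimate from
the stack's mean, median and mode mass (kDa).

**Mass features.** Particle signal = pixels above mean + 3σ; the mass proxy
is Σ(I − Ī_bg)·(pixel size)² over the particle pixels, converted to kDa by
a through-origin linear calibration (slope ΣI·M/ΣI²) on known-mass
standards.

**Architecture.** A residual CNN with batch normalization; downsampling is
done by two consecutive 2×2 stride-2 convolutions instead of pooling;
adaptive average pooling produces a fixed 6×6 map regardless of trunk
resolution; the pooled map is concatenated with the z-scored metadata and a
dense head emits one score.  Training uses Adam, learning rate 1e-4, weight
decay 1e-4, batch size 32, with a seeded 10% validation hold-out.

**Policy.** The number of classify→score→route rounds depends on the
extraction box: 5 below 200 px, 3 for 200–300 px, 2 above 300 px.  Per
round: class score ≥ 4.5 → particle discarded; ≤ 2.5 → 70% banked at
random, 30% keep classifying; in between → keep classifying.  Afterwards,
banked and surviving particles are pooled, classified and scored once more,
and split into three nested batches at final scores ≤ 2.5 / ≤ 3.5 / ≤ 4.5.

See `docs/methods.md` for the full account, including the synthetic-data
model and its limits.

## Worked example

Generate a synthetic stack, train a desk-scale scorer, and score the stack.
`desk.yaml` selects the reduced architecture that trains in minutes on one
CPU core:

```yaml
channel_widths: [4, 16, 32]
blocks_per_stage: 1
stem_downsample: true
head_width: 64
```

```sh
sift2d synth --n 20 --seed 3 --out fixtures
sift2d train --n 300 --epochs 8 --seed 7 --config desk.yaml --out model.sift2d
sift2d score --stack fixtures/classes.mrcs --metadata fixtures/metadata.csv \
             --model model.sift2d --out scores.star
```

which prints

```
wrote 20 synthetic class averages to fixtures
trained 8 epochs; final val MSE 0.5516; saved model.sift2d
wrote 20 class scores to scores.star
```

`scores.star` holds one row per class — the image reference and its
continuous quality score (lower = better):

```
data_

loop_
_rlnReferenceImage #1
_cryosiftScore #2
000001@classes.mrcs 1.460634
000002@classes.mrcs 3.032588
000003@classes.mrcs 3.760890
```

A validation MSE of 0.55 on the 1–5 scale after eight quick epochs means
the model already orders classes broadly by quality; longer training (the
suites use 30 epochs) sharpens it.  Running the full curation loop on a
synthetic cohort with 20% planted junk:

```sh
sift2d sift --model model.sift2d --n-particles 2000 --junk-fraction 0.2 \
            --k-classes 10 --box-px 150 --seed 11 --out siftrun
```

```
sift complete: batches {'<=2.5': 692, '<=3.5': 1558, '<=4.5': 1732} , discarded 268 of 2000
```

The three batch sizes are cumulative (nested) particle sets at the three
final score cutoffs; the discarded count plus the ≤ 4.5 batch always equals
the input.  Every command writes a JSON manifest beside its outputs, and
all randomness flows from `--seed`, so runs replay exactly.

As a library, the same loop is three calls:

```python
from sift2d import run_sift, PolicyConfig
from sift2d.synthetic_data import make_cohort, synthetic_backend

cohort = make_cohort(2000, junk_fraction=0.2, seed=11)
backend = synthetic_backend(cohort, k_classes=10, seed=11)
result = run_sift(cohort.particle_ids, backend, model, box_side_px=150,
                  config=PolicyConfig(seed=11))
result.batches[3.5]          # particle ids passing the 3.5 cutoff
print(result.audit_json())   # per-round JSON audit log
```

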