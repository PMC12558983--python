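# purecl — regional feature-purification contrastive learning

`purecl` is a CPU-only implementation of a two-stage training framework
for classifying biotic stress (disease) in plant leaf images, built for
the regime where field photographs have cluttered, low-contrast
backgrounds, small localized lesions, high intra-class variance and low
inter-class variance — wheat rusts, mildew, blights and their lookalikes.
It is aimed at researchers who want to study the method's components
(augmentation, attention, loss) in isolation or end to end, on synthetic
or real image-folder datasets, without a GPU.

## The method

**Stage 1 — supervised contrastive pretraining.**  Every image in a batch
of N = 8 is augmented twice with **W-Paste**: two 15x15 rectangles are cut
out and filled with crops from other samples, giving two semantically
perturbed views.  The 2N views pass through a **feature-purification
encoder** — five bottleneck residual stages (widths 256/512/1024/2048/2048)
in which multi-scale attention modules (kernels 1/3/5/7 over four channel
subspaces) after stages 1-2 capture low-level interference features that
are *subtracted* from the stage-3/4 features for the first 15 epochs and
*added* afterwards ("reverse learning").  The pooled 2048-d unit-norm
embeddings are projected to 256-d by a discardable MLP head, and the
supervised contrastive (SupCon) loss

    L = sum_i  -1/|P(i)| sum_{p in P(i)} log [ exp(z_i.z_p / tau)
                                / sum_{a in A(i)} exp(z_i.z_a / tau) ]

pulls same-class views together and pushes other classes apart
(tau = 0.07; A(i) = all other views, P(i) = same-label subset).

**Stage 2 — linear probe.**  The encoder is frozen and a single
2048-to-K linear layer is trained for 20 epochs with cross-entropy;
evaluation reports accuracy and macro precision/recall/F1 with a
confusion matrix and per-class table.

Everything runs on a compact NumPy reverse-mode autodiff engine
(`purecl.nn`) with JIT (numba) column transforms and FFT convolutions for
the large attention kernels, so the full pipeline trains on one CPU core.
A synthetic leaf-disease generator with controllable class structure,
clutter and jitter makes every stage testable offline; real datasets in
the standard image-folder layout (one subdirectory per class) are read
directly.  See `docs/methods.md` for modeling details and choices.

## Worked example

```python
import numpy as np
from purecl import (SyntheticDatasetSpec, TrainConfig,
                    generate_synthetic_dataset, run_experiment)

images = generate_synthetic_dataset(
    SyntheticDatasetSpec(n_classes=3, n_per_class=20, seed=0))
config = TrainConfig(stage1_epochs=4, switch_epoch=2, stage2_epochs=10, seed=0)
result = run_experiment(config, images, verbose=True)
print(result.metrics.accuracy)
```

prints the per-epoch stage-1 log and final metrics:

```
[stage1] epoch   0 mode=subtract loss=2.1139
[stage1] epoch   1 mode=subtract loss=2.0574
[stage1] epoch   2 mode=add      loss=2.2210
[stage1] epoch   3 mode=add      loss=2.1185
0.6666666666666666
```

The `mode` column is the interference-feature schedule (subtract before
the switch epoch, add after); `loss` is the mean per-anchor SupCon value,
which starts near log(2N-1) = log 15 ≈ 2.71 for uninformative projections
and falls as same-class views cluster.  At this miniature scale (60
images, 4 epochs) the probe reaches about 2/3 accuracy; the full
desk-scale study below reaches ≥ 0.90.  The `examples/` directory holds
one short script per capability (generator, W-Paste, loss + oracle,
encoder contracts, end-to-end run, augmentation ablation), and the
`purecl` CLI exposes `generate`, `train`, `evaluate` and `ablate` for
shell use.

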