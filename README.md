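# surgphase

Dual-tower multimodal transformer for **surgical phase recognition** in
laparoscopic cholecystectomy video, with a fully seeded synthetic
seven-phase benchmark so the entire pipeline is trainable and testable on a
desktop CPU.

## Who this is for

Researchers in surgical workflow analysis who want a small, dependency-light
reference implementation of a vision–language phase classifier: how the two
modality encoders are trained with a contrastive objective, how the joint
space is formed, and how such a model is evaluated with video-level
cross-validation and paired significance testing — without needing the
Cholec80 videos, pretrained ViT/BERT weights or a GPU.

## The model

A laparoscopic cholecystectomy passes through seven ordered phases
(preparation, Calot's triangle dissection, clipping and cutting, gallbladder
dissection, gallbladder packaging, cleaning and coagulation, gallbladder
retraction). Each video frame, paired with a short text description, is
classified into one of these phases:

1. **Towers.** A ViT-style image tower (16×16 patches → linear projection →
   transformer blocks) and a token-embedding text tower produce one
   embedding sequence per modality.
2. **Encoders.** Two separate transformer encoders (self-attention +
   sinusoidal positional encoding, post-norm residual blocks) refine each
   sequence; mean pooling gives one vector per modality.
3. **Contrastive training.** Both encoders and their projection heads are
   trained with the multimodal contrastive (InfoNCE) loss

   L = −(1/n) Σᵢ log [ exp(sim(xᵢ, yᵢ)/τ) / Σⱼ exp(sim(xᵢ, yⱼ)/τ) ],

   where sim is cosine similarity, τ a temperature, and the batch's
   mismatched pairs serve as negatives. Optimization is plain SGD with
   weight decay, linear warmup and cosine-annealed decay.
4. **Fusion + classification.** Each pooled vector passes through its
   projection head (two fully connected layers with a ReLU, then a linear
   map); the two projected vectors are concatenated (image first) and a
   small MLP with a softmax outputs the seven phase probabilities.

An ablation path trains a **single** shared encoder on the concatenated
modality sequences with cross-entropy (no contrastive stage), and a paired
t-test compares the two architectures fold by fold. A standalone
noise-contrastive-estimation (NCE) loss is provided as a utility objective.

The synthetic generator emulates the benchmark's structure: per-video phase
sequences in canonical order, per-phase durations drawn from a gamma law
moment-matched to the published mean ± sd (e.g. Calot's triangle dissection
954 ± 538 s), phase-specific frame motifs with tool/smoke/noise nuisance
factors, and per-frame template texts.

## Worked example

```python
import numpy as np
import surgphase as sp
from surgphase import pipeline as pl

ds = sp.default_benchmark(seed=0)          # 10 videos, ~700 frame/text pairs
cfg = pl.TrainConfig.desk_preset(seed=0)   # SGD, lr 0.02, 30 epochs, batch 16
result = pl.run_crossval(ds, cfg, k=5)
print(result.aggregate["accuracy"])
```

Output from this exact run:

```
{'mean': 1.0, 'sd': 0.0}
```

Every held-out video frame of the seeded synthetic benchmark is classified
into the correct phase in all five folds — the synthetic task is separable
by construction, so this shows the pipeline learns the alignment it was
designed for, not that real surgical video is this easy. Training curves,
per-fold confusion matrices and weighted precision/recall are in
`result.fold_reports`; `pl.run_ablation(ds, cfg)` produces the paired
one- vs two-encoder comparison, and

```sh
surgphase generate --n-videos 10 --fps 0.03 --seed 0 --out data/
surgphase train --data data/ --out model/
surgphase infer --model model/ data/video000
```

does the same from the shell (inference pairs each frame with each
canonical phase text and keeps the best-supported hypothesis).

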