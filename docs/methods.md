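# Methods

## Problem and scope

The package classifies laparoscopic-cholecystectomy video frames into the
seven canonical surgical phases using a dual-tower vision–language model:
separate image and text towers, one transformer encoder per modality
trained with a multimodal contrastive loss, projection-head fusion into a
joint space, and an MLP softmax classifier. Everything runs at desk scale
on one CPU: the towers are trained from scratch on synthetic data rather
than fine-tuned from large pretrained checkpoints, and externally computed
embeddings (e.g. from a pretrained ViT or BERT) can be injected through the
TSV import path in `embedders.load_precomputed_embeddings` without changing
any downstream code.

## The synthetic benchmark

`synthdata.generate_dataset` emulates the structure of a phase-annotated
cholecystectomy corpus:

- **Phases.** Exactly seven, in the canonical order (preparation → Calot's
  triangle dissection → clipping and cutting → gallbladder dissection →
  gallbladder packaging → cleaning and coagulation → gallbladder
  retraction). Real surgeries occasionally permute the last phases; the
  generator keeps the fixed listing order for determinism.
- **Durations.** Published statistics give only a per-phase mean ± sd in
  seconds (preparation 125 ± 95 up to Calot's dissection 954 ± 538). A
  gamma law with shape = mean²/sd² and scale = sd²/mean reproduces both
  moments exactly while keeping every draw positive; a truncated normal
  would bias the mean. Per-phase frame count is round(duration × fps),
  minimum 1.
- **Frames.** 64×64×3 arrays in [0,1] (configurable up to patch-divisible
  sizes): a phase-specific base colour plus deterministic elliptical
  "anatomy", with three nuisance factors — bright line segments (surgical
  tools, probability 0.3/frame), a low-frequency brightening blob (smoke,
  0.2/frame) and additive Gaussian pixel noise (default sd 0.05). The
  base colours are chosen so the zero-noise task is exactly separable by a
  nearest-centroid rule on raw pixels; this is asserted in the tests and is
  what makes "the classifier reaches 100%" a meaningful health check rather
  than an empirical claim.
- **Texts.** One canonical sentence per phase plus template variants
  (chosen with probability `variability`, default 0.25), each containing a
  unique phase keyword. Real frame-level annotations would carry more
  instrument- and event-level detail; the templates only encode phase
  identity.
- **Splits.** By whole videos, default fraction 0.625 train (mirroring a
  50/30 video split); a frame-count split mode exists because the source
  description of the training split is ambiguous between 50 videos and 50
  frames. The default benchmark is 10 videos at 0.03 frames/s (~700
  pairs) — large enough for 5-fold video-level cross-validation, small
  enough that a full CV run takes ~1–2 minutes on one CPU.

What passing on this benchmark shows: the training objectives, gradient
flow, fusion and evaluation machinery behave as designed on a task whose
structure (paired modalities, phase-blocked label runs, nuisance factors)
matches the real problem. What it does not show: performance on real
surgical video, where appearance differences between phases are far
subtler, texts are absent at inference time, and adverse events disrupt
the phase grammar.

## Architectures and numerical choices

- **Autodiff.** All models run on `surgphase.nn`, a float64 numpy
  reverse-mode engine (~15 primitives). Float64 keeps the finite-difference
  gradient checks meaningful at 1e-5 and the loss oracles at 1e-12.
  Gradients propagate only into parameters and their descendants.
- **Towers.** Image: 16×16 patchify → linear projection → sinusoidal
  positional encoding → transformer blocks → global average pooling (no
  class token). Text: whitespace/lowercase frequency vocabulary with
  reserved padding/unknown ids → embedding rows → positional encoding.
  Both towers multiply embeddings by √d_model before adding the positional
  encoding (the original transformer convention); without this the shared
  positional component dominates the pooled vectors, cosine similarities
  collapse into a narrow band and contrastive training stalls.
- **Encoders.** Post-norm blocks (attention + residual + LayerNorm, FFN +
  residual + LayerNorm) — post-norm keeps the zero-initialized-block
  oracle closed-form. Pooling is the positional mean, matching the image
  tower's global-average convention. Padded text positions are masked out
  of both attention (additive −1e9 mask) and pooling, so batched and
  per-sample forwards agree bitwise. Full-scale default is 12 layers at
  d_model 768; the desk preset is 2 layers at d_model 32, 4 heads, FFN 64.
  Dropout exists but defaults to 0 so evaluation is deterministic.
- **Fusion.** One projection head per modality (linear → ReLU → linear,
  hidden width = input width, then a final linear to the joint size);
  concatenation image-first; MLP with one hidden layer of width 128.
  Argmax ties break toward the lowest phase index.
- **Losses.** The contrastive loss normalizes rows (cosine), divides by
  τ (default 0.1) and uses a log-sum-exp-stable log-softmax; zero-norm
  rows raise rather than silently passing 0. The printed image→text
  direction is the default; a symmetric flag averages both directions.
  The NCE loss is provided as a standalone utility and is not part of the
  default training path. Probability-space cross-entropy floors the log at
  1e-12.
- **Optimization.** Plain SGD, weight decay 1e-5, linear warmup then
  cosine-annealed decay. Full-scale defaults follow the published recipe
  (lr 0.001, 50 epochs, 5-epoch warmup). The desk preset trains from
  scratch, which needs a larger step: lr 0.02 for 30 epochs (warmup 2)
  converges reliably across seeds, while much larger rates collapse the
  embedding space. Momentum is available in the optimizer but off by
  default. With lr = 0 the optimizer provably never touches parameters.

## Evaluation

- Confusion matrix with rows = true phase; weighted precision/recall use
  true-class supports as weights, so weighted recall coincides with
  accuracy (asserted as an identity test). A phase with zero predicted
  positives gets precision 0 with a warning.
- Cross-validation is k = 5 by whole videos (seeded shuffle, round-robin);
  the MLP is retrained inside each fold — the only leakage-safe reading.
  Fold metrics aggregate as sample mean ± sd (n−1).
- The one- vs two-encoder ablation shares fold plans and seeds between
  arms and reports the two-sided paired t-test on per-fold accuracies
  (α = 0.05). Zero-variance differences — common when both arms saturate
  on the synthetic benchmark — are flagged degenerate instead of
  producing an undefined statistic.
- In-batch cross-modal retrieval is scored at the **phase level** on
  candidate sets holding one pair per phase (chance = 1/7): paired texts
  are unique only up to phase, so exact-pair retrieval within arbitrary
  batches is capped by within-batch phase multiplicity and would not
  measure alignment.

## Inference without paired text

The trained classifier consumes a joint image+text vector, but at
deployment only a frame is available. Two documented modes:
`canonical-scan` (default) pairs the frame with each of the seven canonical
phase texts and keeps, per hypothesised phase, the probability assigned to
that phase, then normalizes; `fixed-text` pairs every frame with one
neutral sentence. Neither is claimed to be the original system's procedure,
which is unspecified.

## Known limitations

- Synthetic frames are colour motifs, not anatomy; results do not transfer
  to real video and are not compared against published real-data numbers.
- The text modality encodes phase identity directly, so classification
  accuracy on the benchmark mainly certifies plumbing; the contrastive
  alignment and ablation results are the informative checks.
- Vocabulary is whitespace-based, not WordPiece; adverse events, phase
  permutations and real-time operation are out of scope.
- The first-epoch contrastive loss approximates ln(batch size) only when
  τ does not amplify the initial similarity spread (the uniform-softmax
  baseline test therefore uses τ = 1).
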