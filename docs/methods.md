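# Methods

## The model

`ssmil` implements contrastive multiple-instance learning for whole-slide
histopathology: an unsupervised route from a slide — a gigapixel image, or
equivalently a *bag* of tile embeddings — to a single compact feature
vector, learned without any slide-level labels.

The pipeline has two contrastive stages sharing one loss, NT-Xent. For a
batch of 2N projection vectors in which item i has positive partner p(i),

    L = (1/2N) Σ_i −log [ exp(cos(z_i, z_{p(i)})/τ) / Σ_{k≠i} exp(cos(z_i, z_k)/τ) ].

**Stage 1 — tile encoder (SSL / SSLn).** Two augmented views of a tile form
a positive pair (SimCLR); all other views in the batch repel. The
transformation family reflects histopathology's invariances: rotation
(multiples of 90°), rescaling, color/contrast jitter, and — in SSLn mode —
*adjacency*: one view is drawn from a uniformly chosen retained grid
neighbor (Chebyshev distance 1) of the anchor tile, because neighboring
tissue is very likely the same microanatomy. Tile-level temperature is 0.5,
Adam with learning rate 0.001, 20 epochs with patience 5 on validation
loss, 1000 sampled tiles per slide by default. The embedding used
downstream is the encoder output h; the projection head (2-layer, output
dimension 128) is discarded after pretraining.

**Stage 2 — contrastive MIL.** Each slide's bag of K tile embeddings is
subsampled *with replacement* into views of max(1, round(K/4)) instances;
two independently seeded views of the same slide form a positive pair,
views of different slides repel. Each view is pooled by gated attention

    a_k = softmax_k( wᵀ( tanh(V h_k) ⊙ σ(U h_k) ) ),     z = Σ_k a_k h_k,

projected by a 2-layer head, and trained with NT-Xent at temperature 1.0,
Adam with learning rate 2·10⁻⁴ and weight decay 10⁻⁵, batches of up to 70
slides (140 views), keeping the checkpoint with the lowest validation loss
(validation views are fixed by a seed so selection is reproducible). The
slide representation served downstream is the attention-pooled encoding z
of the *full* bag, projection head again discarded.

The mechanism this is designed to elicit: to make two subsamples of the
same slide map together while different slides map apart, attention must
concentrate on the instances that *distinguish* slides — the unique
microanatomy — rather than on tissue shared by every slide. The package
tests this directly on synthetic bags (see below).

## Downstream evaluation protocol

Five-fold cross-validation with 60/20/20 train/validation/test splits: the
cohort is cut into five class-stratified groups; fold i tests on group i,
validates on group i+1, trains on the rest, so the five test sets partition
the cohort. Three regimes are compared on identical folds:

* **supervised** — gated-attention MIL trained from scratch on labels;
* **fine_tune** — attention initialized from the contrastively trained
  model, output head warm-started as a linear probe, then all parameters
  trained ("probe then fine-tune"; see Numerical choices);
* **frozen** — slide representations fixed; only a linear head is trained.

A label-fraction ablation retrains each regime with 25/50/75% of the
training labels; subsets are class-stratified and nested under a fixed seed
(each class keeps one seeded permutation and takes a prefix).

Metrics: sensitivity and specificity at threshold 0.5; AUC by the
Mann–Whitney formulation (ties count one half); for regression, R² is the
squared Pearson correlation between predictions and targets (a
coefficient-of-determination mode is available behind a switch).

## Synthetic data

`generate_bags` emulates the statistical structure the method assumes.
Instances are drawn from isotropic Gaussian clusters whose means sit on
scaled coordinate axes of the embedding space: *shared* clusters common to
all slides (stroma, normal epithelium, ...) and *class-unique* clusters
(the discriminative microanatomy). `effect_size` is exactly the Euclidean
distance between unique-cluster means divided by the within-cluster
standard deviation. A per-slide Gaussian jitter of the unique-cluster means
(`slide_jitter_sd`, default 0.5) emulates patient-level morphological
variation and gives the contrastive objective a within-class reason to
attend to unique instances. For regression, the target is the *realized*
fraction of instances drawn from a designated signal cluster — a
proliferation-score surrogate at the level synthetic data can honestly
test. `generate_slide_image` renders small tile-grid rasters with
per-cluster textures (base color + band-limited noise) plus optional white
background, so tessellation, Otsu masking, neighbor lookup and tile-level
pretraining run without any slide download.

What the generator does *not* emulate: H&E stain distributions, scanner
artifacts, pen marks, spatial correlation of tissue within a slide beyond
the cluster structure, or class signal that is anything other than a mean
shift. Passing tests therefore show the machinery is correct and the
mechanism operates as designed — not that any particular clinical
performance would be attained on real cohorts.

## Study conditions and problem sizes

Two synthetic studies back the acceptance checks; their conditions are
fixed choices of this package:

* **Signal recovery** — 200 slides × 250 instances, embedding dim 32,
  8 shared + 2 unique clusters per class, unique fraction 0.2, effect size
  4.0 (strongly separated microanatomy), noise sd 1.0, jitter 0.5;
  contrastive MIL trained 250 epochs. A zero-effect twin of the same cohort
  serves as the null control. Five seeds, one fold each.
* **Label-fraction ablation** — 120 slides × 160 instances, 6 shared + 2
  unique clusters per class, effect size 2.5. The moderate effect is
  deliberate: it places the task in the operating range where labels still
  buy performance (probe AUCs ~0.8–0.9) rather than a regime where the
  unsupervised representation already saturates the task. Five seeds × two
  folds, all three regimes, fractions 25/50/75%; ordering statements are
  made on means over the seed × fold replicates (fraction orderings on the
  regime-pooled mean, the frozen-vs-fine-tune comparison on regime means).

Epoch counts are desk-scale choices: the attention module and heads here
are small dense models in float64 on CPU, and the loss plateaus within a
few hundred epochs at these cohort sizes.

## Numerical choices

* **All neural components run on a small reverse-mode autodiff engine over
  NumPy (float64)** written for this package: the models are tiny (a few
  thousand parameters) and this keeps every result bit-reproducible from a
  seed on any machine. The registered tile backbone is `pooled-mlp`
  (block-averaged pixels → MLP); the backbone slot is a config switch.
* Gated attention: "·" between the tanh and sigmoid branches is the
  elementwise product (the standard gated-attention mechanism); the softmax
  over instances is normalized so Σa = 1; no bias terms by default.
  Attention dim 128.
* NT-Xent excludes only the anchor itself from the denominator; negatives
  are all other items in the batch. Cosine similarity requires nonzero
  projections; a zero-norm projection raises rather than silently
  regularizing.
* Tile-level temperature 0.5 and batch size 256 are configuration defaults;
  MIL-level temperature 1.0. The two are independent config keys.
* View-size rounding: round(K/4) with a floor of 1, banker's rounding.
* Weight initialization: Glorot-uniform weights; biases uniform in
  ±1/√fan_in (zero biases plus ReLU can emit exactly-zero projection rows
  at initialization, which cosine similarity cannot handle).
* Head training. The frozen probe is a convex fit, so it runs at learning
  rate 10⁻² for up to 500 epochs (patience 100) — under-trained probes were
  observed to inherit their initialization as noise. Full-model regimes use
  a separate budget (300 epochs, patience 60). Supervised training
  from scratch uses 3·10⁻³; at the contrastive stage's 2·10⁻⁴ these small
  models underfit badly within a desk-scale epoch budget. Fine-tuning uses 10⁻³
  (lower, to preserve the pretrained attention) and the probe-then-fine-tune
  recipe: the head is first fit on frozen representations, the combined
  model is the first checkpoint candidate, and a later checkpoint replaces
  it only when validation loss improves by at least `finetune_min_delta`
  (default 0.01) — guarding against checkpoint churn on small validation
  sets, where marginal validation-loss improvements can swap in models that
  differ wildly on test data.
* Tissue masking: Otsu on the HSV saturation channel of a thumbnail, with
  the threshold capped at saturation 0.2 — without the cap Otsu bisects an
  all-tissue thumbnail. Constant thumbnails fall back to an absolute
  saturation test. Retention threshold 0.5 tissue fraction.
* Tiling: 0-based half-open pixel coordinates, origin top-left, partial
  edge tiles dropped, 256 px default tile size for real slides (32 px for
  the procedural rasters), working magnification 20×, neighbors
  8-connected (4-connectivity available).
* Degenerate inputs raise rather than warn: empty bag to pool/subsample,
  single-class AUC, constant-series correlation, fewer than 2 slides for
  any contrastive batch.
* All randomness flows through `numpy.random.SeedSequence` hierarchies;
  per-slide view seeds mix the epoch seed with a CRC32 of the slide id, so
  view pairs differ across epochs but are exactly reproducible.

## Known limitations

* The ResNet-class backbone of full-scale practice is out of scope here;
  the `pooled-mlp` backbone separates procedural textures but would not
  transfer to real histopathology tiles.
* SVS reading depends on what `tifffile` can decode; vendor-specific
  pyramids may not open. Precomputed embedding HDF5 input (the
  `passthrough` mode) sidesteps slide decoding entirely.
* At desk scale the fine-tune-over-frozen margin is small (~0.01–0.03 AUC)
  because the unsupervised representation already captures most of the
  class signal; the orderings are asserted on means over seeds × folds and
  are tendency statements, not per-seed guarantees.
* The regression path shares all machinery with classification but the
  synthetic regression target is deliberately simple (signal-cluster
  fraction); no claim is made about calibrated proliferation scoring.
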