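# Methods

This note documents the models, procedures and design choices behind
`specband`: a pipeline for classifying water-deficient plants from
dual-sensor (VNIR + SWIR) hyperspectral images with a band-attention residual
network, for quantifying how dataset construction biases inflate the measured
performance, and for selecting informative spectral bands from the trained
attention weights.

## Data model

A sample is a reflectance tile `h ∈ R^{C×64×64}` cut from a co-registered
plant image whose spectral axis concatenates a VNIR block (400–988 nm,
160 bands at full scale) and a SWIR block (950–2500 nm, 288 bands). The two
sensors overlap around 950–988 nm; overlapping wavelengths are kept as
distinct channels, so wavelengths increase strictly only within each block.
Each sample carries four metadata attributes: imaging session (week 1–5),
plant identifier, treatment (`C` well-watered / `D` water-deficient) and
variety.

### Preprocessing

Starting from a radiance cube, the chain is:

1. **Reflectance conversion** — ratio against the mean spectrum of a
   calibrated reflectance panel (default 20%):
   `out[c,i,j] = radiance[c,i,j] / mean_panel[c] × 0.20`. This is a
   simplified flat-field conversion; radiometric calibration and VNIR/SWIR
   co-registration are assumed done upstream.
2. **Capping** — reflectance clipped into [0, 1] (saturated pixels).
3. **Masking** — background pixels set to zero using the segmentation mask.
4. **Edge trim** — the first and last 5 channels of each sensor block are
   removed (noisy band edges); 160 + 288 bands become 428.
5. **Tiling** — a non-overlapping 64×64 grid anchored at the image origin
   (remainders discarded); a tile is kept iff the fraction of plant pixels
   inside it is ≥ 0.90, with ≥ interpreted inclusively (a tile at exactly
   90% is kept; 0.90 × 4096 = 3686.4, so 3687 plant pixels keep a tile and
   3686 do not).

"Coverage" is computed tile-locally (fraction of in-tile pixels that are
plant), which needs no whole-plant bookkeeping. An NDVI threshold mask
`(R800 − R670)/(R800 + R670) > 0.3` is provided as a convenience segmenter
for real imports; synthetic data carries its own ground-truth mask.

## Dataset construction schemes

Four schemes emulate sampling strategies with and without deliberate bias.
All start by **equalizing sessions**: every (session, treatment) cell is
downsampled without replacement to the global minimum cell size.

* **UD-SS** — equalize, then a *plant-stratified* split: each plant's tiles
  go whole to one of train/test/validation, targeting fractions
  (0.65, 0.20, 0.15). Within each treatment group, plants are ordered by
  descending tile count (a seeded shuffle breaks ties) and greedily assigned
  to the set with the largest remaining deficit. Running the greedy
  assignment per treatment keeps both classes in every set; whole-plant
  assignment guarantees no identifier ever spans the train/test boundary
  (validation is treated like train for the leakage rule, and in practice
  also receives whole plants).
* **UD-RS** — equalize, then a tile-level random split with counts
  `floor(0.20·n)` test, `floor(0.15·n)` validation, remainder train.
* **BDT-SS** — equalize, then skew treatments per session (keep 20% of
  deficient tiles in sessions 1–2, 60% of both in session 3, 20% of control
  tiles in sessions 4–5), then stratified split.
* **BDI-SS** — equalize, then skew sessions uniformly over treatments
  (20% / 20% / 60% / 100% / 100%), then stratified split.

Fractional retention uses `floor(fraction × n)` per cell, which reproduces
the reference cell counts exactly (306 → 61 at 20%, 306 → 183 at 60%,
58 → 11, 151 → 30, 30 → 6) and makes `fraction = 1` the identity.

## Model

**Band attention.** Two per-channel spatial statistics of the input tile are
computed: the global average `z_avg` and global maximum `z_max` over the
spatial plane. Both pass through one *shared* two-layer MLP with a bottleneck
— C → ⌊C/2⌋ (ReLU) → C (sigmoid); 428 channels give a hidden width of 214 —
yielding `s_avg` and `s_max` in (0,1)^C. The spectral attention map is their
sum, `m = s_max + s_avg ∈ (0,2)^C`, and the rescaled sample is the
channel-wise product `h_l = m ⊗ h`. The sigmoid is applied inside each
branch *before* the summation (the map deliberately lives in (0,2), not
(0,1)).

The second FC layer is zero-initialised, so at the start `s ≡ 0.5`,
`m ≡ 1` and the attention block is an exact identity; the per-channel
ranking that develops during training therefore reflects learned structure
rather than initialisation noise. Biases are included in both layers.

**Backbone.** A standard 18-layer residual network: 7×7 stride-2 stem
convolution, BN + ReLU, 3×3 max pooling, four stages of two basic blocks
(3×3 convolutions, each followed by batch normalisation and ReLU; identity
shortcuts, 1×1 projection where width or resolution changes), global average
pooling and a single-logit fully connected head with sigmoid. Stage widths
default to (64, 128, 256, 512); a "tiny" preset (8, 16, 32, 64) serves
desk-scale experiments and tests. The network expects C×50×50 input.
A probability `p ≥ 0.5` maps to class 1 (water-deficient); the boundary case
goes to class 1.

The network and its training loop run on a compact numpy reverse-mode
autodiff engine written for this package (`specband.nn`): tensors record
their parents and a backward closure, convolution is im2col + BLAS matmul,
and gradients flow through conv/BN/ReLU/pooling/attention exactly as in any
tape-based framework. Everything is float32 and fully seeded.

**Training.** Adam (learning rate 1e-3, weight decay 5e-4 added to the
gradient), binary cross-entropy on probabilities (clamped at 1e-7),
mini-batches of 32 with the last partial batch kept, at most 200 epochs with
early stopping after 50 epochs without a strict validation-loss improvement,
and learning-rate decay ×0.1 every 15 epochs. Augmentation: random
horizontal/vertical flips (p = 0.5 each — top-down plant imagery has no
preferred orientation) followed by a uniform-random 64→50 crop; validation
and test use a deterministic centre crop ([7, 57) in both axes) without
flips. The model reported is the one with the lowest validation loss; one
master seed fans out to named sub-seeds for shuffling and augmentation.

**Evaluation.** AUC-ROC (rank/Mann–Whitney formulation, ties = 0.5) and
precision/recall/F1 computed per class and averaged by support, each with
95% percentile-bootstrap confidence intervals over 1000 paired resamples
(resamples on which a metric is undefined are skipped and logged; BCa was
not used — the percentile interval is the reproducible default). Reports
carry one row per imaging session plus a pooled row; sessions with a single
class report P/R/F1 but omit AUC. Plant-level results use majority voting:
a plant is labelled deficient iff strictly more of its tiles are, an exact
tie falls back to the mean tile score vs 0.5 (label 0 at exactly 0.5), and
the plant-level continuous score for AUC is the mean tile score (a binary
vote alone cannot yield a smooth ROC). Sensitivity and specificity are the
recalls of the deficient and control classes.

**Band selection.** The significance of channel c is the training-set mean
of the average-pool branch, `r_c = (1/N) Σ_k s_avg[c,k]`, computed in
inference mode (centre crop, no flips); only the average branch enters the
score even though the forward pass uses both. Ties rank the lower channel
index first. The top-b subset can back a reduced model whose attention
bottleneck is ⌊b/2⌋ (b ≥ 2). In the desk-scale experiments significance is
read from the attention weights at the *end* of training rather than the
best-validation snapshot: the validation optimum is typically reached within
a few epochs, long before the ranking has accumulated.

## Synthetic data generator

The generator emulates the structure of a greenhouse drought trial — plants
× weekly sessions × two treatments — with planted ground truth so every
pipeline stage is testable without downloads. Components:

* **Base spectrum** — a closed-form vegetation-like curve: low blue/red
  reflectance, a green bump at 550 nm, a logistic red edge onto a ~0.5 NIR
  plateau, and Gaussian notches at the water features (970, 1200, 1450,
  1940 nm) plus a far-SWIR roll-off. The closed form permits pointwise tests
  (e.g. reflectance at 1450 nm < at 1250 nm).
* **Treatment effect** — an additive `+magnitude` at every channel inside
  configurable wavelength windows (closed intervals), zero elsewhere;
  drought *raises* reflectance in the water-absorption windows (less leaf
  water → weaker absorption). The magnitude is indexed by session and grows
  over time, emulating progressing stress.
* **Plant fingerprint** (`plant_sigma`) — per plant: a constant spectral
  offset ~N(0, σ_plant) and a smooth random spectral wiggle (low-frequency
  cosines, SD ≈ σ_plant/2), both fixed across sessions; per image: a smooth
  low-frequency brightness field (SD σ_plant) shared across channels. This
  is the identity signal a tile-level random split lets a classifier
  exploit.
* **Acquisition noise** (`pixel_sigma`) — iid pixel noise plus a spatially
  smooth, per-channel random field of the same SD. The structured component
  matters: pooling over 2500 pixels averages iid noise to nothing, so
  without it any plausible effect size saturates the task, the BCE gradient
  vanishes after a few epochs, and attention-based band ranking has nothing
  to learn from.
* **Mask** — a filled ellipse (radii ≈ 0.45 × image size) with a ragged,
  harmonically perturbed edge, producing both full- and partial-coverage
  tiles so the 90% filter has work to do. Background pixels are zero.

With `plant_sigma = pixel_sigma = 0` the drought-minus-control difference is
exactly zero outside the effect windows (localization); with
`plant_sigma > 0` and zero effect, between-plant variance exceeds
within-plant variance (nuisance). Identical configs (including seed) yield
bit-identical outputs; seeds fan out per plant and per session through
`numpy.random.SeedSequence`.

Defaults mirror the emulated trial: 5 weekly sessions, 9 plants per group,
160 + 288 bands, effect windows at the water features (940–1000, 1420–1520,
1870–2000 nm), effect magnitude growing 0.01→0.05 across sessions,
σ_plant = 0.02, σ_pixel = 0.01. The within- vs between-plant variance ratio
of real cubes is not characterised in the emulated trial, so the noise
scales are realistic-by-construction choices, not estimates.

## Desk-scale experiments

`specband.experiments` packages three findings at laptop scale (minutes on
one CPU). They use the tiny backbone preset, 256×256 images (≈4 interior
tiles each after the coverage filter), reduced band counts (24–34 per
sensor), and short training runs; the learning-rate decay step is set to the
run length (the recipe's epoch-15 decay presumes 200-epoch training and
would freeze learning a third of the way into a 30-epoch run). The
scientific structure — generator, preprocessing, dataset schemas, model,
metrics — is exactly the full pipeline.

1. **Separability** (`separability_experiment`) — strong effect
   (0.10–0.18), weak nuisance, UD-SS: the classifier should reach test
   AUC ≥ 0.95 within 20 epochs.
2. **Band recovery** (`band_recovery_experiment`) — moderate effect
   (0.05–0.09) in windows 1380–1620 and 1830–2080 nm (11 of 44 trimmed
   channels) against structured acquisition noise (σ_pixel = 0.04), which
   keeps the loss — and the gradient pressure on the attention — alive
   through a 35-epoch run. The top-10 channels by r_c are tested against the
   planted channels with a hypergeometric test (null: 10 channels drawn at
   random from 44).
3. **Split-bias inflation** (`split_bias_experiment`) — weak effect
   (0.005–0.025) dominated by the plant fingerprint (σ_plant = 0.06):
   per seed, the same tiles are split once stratified (UD-SS) and once at
   random (UD-RS) and the tiny model is trained on each; the mean test AUC
   across seeds is higher under the random split because test tiles come
   from plants seen in training.

What passing these experiments does — and does not — show about real data:
the generator's treatment effect is a clean additive shift, its nuisance is
Gaussian and smooth, and tiles of one plant differ only by noise fields and
crop jitter. Real drought responses are nonlinear in wavelength, masks are
imperfect, and neighbouring tiles of a plant share structure beyond a global
fingerprint. The experiments therefore validate the *machinery* (the
pipeline ranks truly informative bands above chance and measures leakage
inflation) rather than any field-level effect size.

## Numerical choices and degenerate inputs

* Probabilities are clamped to [1e-7, 1−1e-7] inside the BCE; batch
  normalisation uses ε = 1e-5 and momentum 0.1 with unbiased running
  variance.
* Max pooling pads with −∞ so padded positions never win; gradient ties in
  global max pooling route to the first maximising pixel (row-major).
* "Improvement" for early stopping is any strict decrease (no minimum
  delta).
* Empty manifests round-trip as header-only CSV; an image smaller than the
  tile yields an empty sample list; a session with one class omits AUC with
  a warning; bias fractions of 0 or 1 are valid (empty cell / identity).
* Adam applies weight decay to all parameters, including BN scale/shift.

## Known limitations

* The full-scale 428-channel model trains at realistic speed only on
  hardware beyond a single CPU; the package's numpy engine is sized for the
  desk-scale presets and for correctness, not throughput.
* Band significance at desk scale is statistically marginal by construction
  (10–40 training steps per epoch on ~150 tiles); individual seeds
  fluctuate, which is why the recovery experiment reports a per-seed
  hypergeometric test over several seeds.
* The percentile bootstrap undercovers for extreme AUC values on small
  plant counts (the plant-level interval can be degenerate when all plants
  vote identically).
* ENVI import parses only band count and wavelengths; proprietary vendor
  formats are out of scope, as are radiometric calibration and VNIR/SWIR
  co-registration.
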