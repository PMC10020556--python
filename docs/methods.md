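# Methods

This note documents the models implemented in `histomil`, the synthetic
cohort used to exercise them, the numerical choices that matter, and what
the package's tests do and do not demonstrate.

## Problem setting

The package implements a slide-to-genotype pipeline for H&E histology:
given a whole-slide RGB image of a lung adenocarcinoma resection, predict a
binary driver-genotype label (EGFR short-variant mutant vs. not) and explain
the prediction through the tissue morphology the model attends to.  Real
cohorts of this kind are private; the package therefore ships a synthetic
slide generator that reproduces the statistical structure the pipeline
assumes, so that every stage is exercised end to end without any download.

## Pipeline stages

### Tissue masking and patch extraction

Slides are masked on a block-mean downsampled copy (default factor 16):
RGB is converted to HSV, the saturation channel is thresholded (default
0.07 on a [0, 1] scale; white glass has saturation near 0), then objects
smaller than `min_object_px` are removed and holes smaller than
`min_hole_px` filled (both default 64 px at mask scale).  The threshold,
downsample factor and cleanup sizes are conventional whole-slide-imaging
defaults and are exposed as parameters; the pipeline's behaviour on the
synthetic cohort is insensitive to them over a wide range.

Patches are taken from a non-overlapping grid anchored at (0, 0), 0-based,
row-major, half-open.  Mutation-model patches are 1024 px at 20x and kept
when at least 0.2 of their footprint is tissue; no other selection is
applied.  Morphology-training patches are 512 px and require at least 0.75
of their area inside a single annotated region.  Two adapters reconcile
geometry: the morphology model's input is the central 512 px of a 1024 px
patch resized to 448 px (the resulting call is propagated to the whole
patch), and mutation-model inputs are full-frame resizes of 1024 px patches
to 224 px.  All resizes are bilinear.

### Morphology classifier

A K=5-class patch classifier (tumor, immune foci, stroma, necrosis,
normal): a trainable convolutional feature extractor with global average
pooling feeding a 5-dimensional fully-connected softmax head, trained with
Adam under categorical cross-entropy for 15 epochs; the checkpoint with the
highest validation accuracy is kept.  The backbone is pluggable; the
default is a stack of stride-k "patchify" convolution blocks
(conv + batch normalisation + ReLU) sized for CPU training.  Per-slide
morphology profiles are patch-count fractions over the slide's grid.

### Genotype model families

All three families end in a 1-dimensional sigmoid head optimised with Adam
(learning rate 1e-5 at full scale) under binary cross-entropy.

1. *Weakly supervised*: every patch inherits its slide's label; slide
   scores aggregate patch predictions by mean or median.  Trained up to 200
   epochs with early stopping on validation AUC (patience 20).
2. *Two-stage*: identical, restricted to patches of one morphology class
   (tumor, necrosis, ...).  Slides with no qualifying patches are excluded
   from training and scored as missing.
3. *Attention-based MIL*: per-patch embeddings pass through a two-layer
   attention trunk (512- then 256-dimensional, ReLU); a scorer
   (256-dimensional tanh layer, then 1-dimensional) produces per-patch
   scores that a softmax across the bag turns into attention weights; the
   weighted sum of reduced embeddings is the slide embedding, classified by
   the final sigmoid layer.  Bags hold 40 patches sampled per slide per
   epoch (without replacement when the slide has enough patches).  The
   scorer's tanh nonlinearity is the field's convention for attention
   scoring; the trunk uses ReLU.

**Batch normalisation at inference.**  MIL inference offers two modes:
`moving_stats` (the exponentially decaying running statistics from
training) and `batch_stats` (statistics of the presented bag itself, the
default).  Because a bag's patches all come from one slide, batch
statistics act as an implicit per-slide normaliser.

**Slides per training batch.**  Each MIL gradient step processes bags from
two slides jointly (configurable).  This matters: with a single slide per
batch, the batch-normalisation statistics of the bag are a deterministic
function of that slide, and a bag-level classifier can read the slide label
directly out of the normalisation shift of any low-variance patch — the
attention mechanism then has no reason to localise on informative
morphology.  Mixing two slides per step makes that shortcut unreliable
while keeping the one-slide-per-bag structure at inference.

### Evaluation

AUC (equal to the Mann–Whitney pair statistic, ties half-weighted), NPV and
PPV at a 0.5 threshold (scores at the threshold count as positive calls —
a convention that must be fixed; undefined metrics are reported as missing
with the empty-denominator cause, never as 0), high-confidence subsetting
(score < 0.25 or > 0.75), and cross-fold mean ± sample standard deviation.
Model families are compared by a two-sided two-sample t-test on per-fold
AUCs; the package treats this test choice as an assumption, since fold-level
AUCs are not strictly independent.

### Attention audit

Attention weights are grouped by predicted morphology (all patches, median
per slide, maximum per slide).  The top-25 highest-attention patches of
each reviewed bag are summarised: numeric review scores by mean, sample
standard deviation, minimum and maximum; categorical reviews by mode with a
deterministic lexicographic tie-break (ties are flagged).  Numeric
summaries are compared between predicted-status groups by a two-sided
two-sample t-test (interpreting the source's "two-way T-test"; equal
variances assumed) with Benjamini–Hochberg FDR correction, plus Pearson's r
against status coded mutant = 1.  Categorical summaries use a chi-square
test without continuity correction.  Association rules are mined by a
level-wise apriori enumeration over `field=value` items with the predicted
status as the sole consequent; rules are ranked by lift, ties by support,
then lexicographically.  Default thresholds: support 0.1, confidence 0.5.

### Cross-validation design

Training sets are balanced by majority under-sampling; validation sets are
prevalence-matched at 15%.  With `n_mut` mutant specimens and training
fraction 0.8: `mutant_train = round_half_up(0.8 * n_mut)` and the
validation total is `floor(mutant_val / 0.15)`.  Round-half-up plus floor
is the only rounding scheme consistent with a 716-mutant cohort producing
1146-slide training and 953-slide validation sets.  Mutant validation
blocks are disjoint across the five folds; when the block size does not
divide the mutant cohort, the remainder (1 specimen for 716 mutants) is
never validated.  Whether non-mutant specimens recur across folds is a free
choice; they may.

## The synthetic cohort

`histomil.synthetic` renders slides as procedural textures — class-specific
blob length-scales, colours, anisotropy (stroma), and threshold quantiles
from Gaussian-filtered noise — on a near-white background, with contiguous
class regions assigned by ranking smooth random fields to hit target area
fractions exactly up to block rounding.  Defaults encode the study
conditions:

* **Low tumor content**: per-slide tumor fractions are drawn around a
  median of 0.364 (sd 0.12, clipped to [0.12, 0.62]).
* **Genotype signal in tumor texture**: the tumor blob length-scale is
  multiplied by `1 ± 0.20 × signal_strength` (mutant up, wild-type down).
  The cohort default `signal_strength = 1.5` was chosen once so that the
  signal is clearly learnable per patch yet far from trivially readable
  from slide-level moments.  The effect has partial penetrance: with
  probability `1 − signal_penetrance` (default 0.25) a slide expresses it
  at only a quarter strength.  Morphological correlates of genotype are
  not universal in real tumors, and partial penetrance is what gives
  bag-level models that can also read the immune signal a structural edge
  over tumor-only models, mirroring the ordering the pipeline is meant to
  demonstrate.
* **Secondary immune signal**: wild-type slides render their immune foci
  at a `1 + 0.35 × immune_boost_wildtype` coarser blob scale (default
  boost 2.0) at identical immune area and dot coverage.  Expressing the
  immune signal as region *appearance* rather than extra immune *area*
  keeps it out of two shortcut channels that were observed to matter: a
  slide-brightness shift (which contaminates even label-permutation nulls,
  because null models' residual outputs tend to align with the dominant
  intensity axis) and contamination of tumor-labelled patches (extra
  immune area raises the immune content in the context around tumor
  regions, letting the tumor-restricted family read the immune signal
  second-hand).
* **Nuisance structure**: per-slide stain jitter (random RGB offset, sd 6
  intensity units, and contrast scale) on all tissue; per-slide,
  per-class texture-parameter jitter (log-sd 0.45, damped to 0.3x for
  tumor so the planted effect dominates the tumor class's own nuisance);
  within-slide regional contrast modulation; and compositional variability
  in the non-tumor class fractions (log-sd 0.3).  These emulate the
  slide-to-slide staining, processing and composition variability of real
  cohorts.  Without them, slide-level feature moments are so informative
  that any bag-level model can classify without attending to tumor — an
  unrealistic regime in which attention audits are meaningless.

The generator does **not** render nuclei, glandular architecture, stain
deconvolution-consistent chromatics, or pyramidal WSIs, and its morphology
classes are far more separable than real tissue.  Passing tests therefore
demonstrate that the pipeline's machinery is correct and that its models
can recover a planted signal of realistic shape — not that the
architecture achieves any particular performance on real slides.

## Desk-scale study conditions

The end-to-end study (used by the demo, the acceptance script, and the
stochastic acceptance tests) runs on one CPU in roughly ten minutes with
these reduced problem sizes, chosen once as the package's benchmark
conditions:

* 60 mutant + 60 wild-type slides of 1024×1024 px; mutation patches 128 px
  resized to 64 px model inputs; morphology patches 64 px resized to 56 px
  (the full-scale 1024/512/448/224 geometry remains the default of every
  operation and is exercised by unit tests).
* One fold with training fraction 2/3 and validation prevalence 0.5
  (40 + 40 training, 20 + 20 validation) — the 15% validation prevalence of
  the full design cannot be realised on a balanced 120-slide cohort.
* Morphology: 150 annotation patches per class from 10 slides, 15 epochs;
  held-out macro F1 measured on patches from 8 different slides.
* Patch families: up to 24 patches per slide, at most 60 epochs, early
  stopping patience 15.  MIL: 50 epochs, bag size 40, two slides per batch.
* Learning rate 1e-3 for all desk-scale training (the 1e-5 full-scale
  default cannot converge within this epoch budget at this model size).
* Label-permutation null: the weakly supervised family retrained on
  shuffled training labels (three independent shuffles, 15 epochs each) and
  scored on the shuffled-label training slides against their true labels;
  the three AUCs are averaged.  Scoring a single permutation null on the
  40 held-out slides is unstable in an instructive way: the model amplifies
  whatever chance correlation the shuffle has with the cohort's dominant
  feature axis and generalises it, so single-replicate held-out null AUCs
  range roughly 0.1–0.9.  The training-cohort evaluation tests the same
  property — predictions follow the assigned labels, not the slides' true
  genotypes — with a sampling standard deviation near 0.03.

## Numerical choices

* Softmax and sigmoid are shift-stabilised; cross-entropies clip
  probabilities at 1e-12.
* Batch normalisation uses eps 1e-5 and running-stat momentum 0.1.
* Convolutions are non-overlapping stride-k windows ("patchify"), so the
  backward pass to the input is a reshape; this is what makes pure-numpy
  training affordable.  He-normal initialisation throughout.
* Mode tie-breaks (bag summaries) are lexicographic and flagged; top-k
  attention ties break by patch index.
* Scores exactly at a classification threshold are positive calls.
* All randomness flows from a single seed through SHA-256-derived
  stage seeds (`stage_seed`), so each stage is independently reproducible
  and two runs with the same seed produce identical outputs.

## Known limitations

* At the desk-scale cohort size (~120 slides) the stochastic study results
  carry real seed-to-seed variability: the MIL-over-tumor-only margin can
  close to within sampling noise on some cohorts (128 px "tumor" patches
  inherit surrounding immune context, so the tumor-restricted family
  partially reads the immune signal too), and a 3-shuffle permutation null
  has a standard deviation near 0.1.  The packaged study conditions and
  seeds are fixed; conclusions about orderings are statements about this
  benchmark, not universal guarantees at any cohort size.

* The backbone is a small CNN, not a ResNet50; the package's claims are
  about the pipeline, weak supervision, and attention pooling, not about
  backbone capacity.
* Bags at inference use all patches of a slide rather than a fixed-size
  sample; for slides with very many patches a sampled bag may behave
  differently under `batch_stats` normalisation.
* The two-sample t-test between families over folds ignores fold
  correlation.
* Non-mutant specimens may recur across folds (the design leaves this
  open); analyses that require disjoint non-mutant folds must subsample.
* The synthetic review tables plant associations through bag-level
  category tendencies; they do not model reviewer disagreement or ordinal
  correlation between numeric scores.
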