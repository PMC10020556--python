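# histomil

Attention-based multiple-instance learning (MIL) for slide-level genotype
prediction from H&E histology images, together with the full surrounding
pipeline: HSV tissue masking, grid patch extraction, a five-class tissue
morphology classifier, balanced/prevalence-matched cross-validation splits,
three genotype model families, slide-level metrics, and an interpretation
layer (attention audits, pathologist-review statistics, association-rules
mining).  A synthetic slide generator with planted morphology/genotype
signal makes every stage testable end to end without any private data.

## Who this is for

Computational pathology researchers who want a compact, fully inspectable
reference implementation of the weakly supervised / two-stage /
attention-MIL modelling ladder for mutation prediction — e.g. EGFR status
in lung adenocarcinoma — on real-world-style cohorts with low tumor
content, plus a controlled synthetic benchmark for validating each stage.

## The models

All patches are 0-based grid crops at 20x.  Mutation-model patches
(1024 px, kept when tissue fraction ≥ 0.2) are resized to 224 px inputs;
morphology patches (512 px, ≥ 0.75 inside one annotated region) are resized
to 448 px.

* **Morphology classifier** — CNN feature extractor, global average
  pooling, 5-dim fully-connected softmax head `a(z)_i = e^{z_i}/Σ_j e^{z_j}`
  with `z = wᵀx + b`, trained 15 epochs under categorical cross-entropy
  `l = −Σ_j ŷ_j log a(z)_j`; best-validation-accuracy checkpoint kept.
* **Weakly supervised patch model** — feature extractor, pooling, dropout
  0.3, 1-dim sigmoid head `g(z) = 1/(1+e^{−z})` under binary cross-entropy
  `l = −(ŷ log g(z) + (1−ŷ) log(1−g(z)))`; every patch inherits its
  slide's label; slide score = mean (or median) patch prediction.
* **Two-stage models** — the same classifier restricted to patches of one
  predicted morphology class (tumor, necrosis, ...).
* **Attention MIL** — per-patch embeddings pass a 512→256 attention trunk;
  a 256→1 scorer is softmax-normalised across the bag into attention
  weights `a_i`; the slide embedding `Σ_i a_i v_i` feeds a final sigmoid
  head.  Bags of 40 patches; at inference, batch-normalisation can use the
  presented bag's own statistics (`batch_stats`, default).

Splits balance training by majority under-sampling and fix validation
prevalence at 15%: a 716-mutant / 1383-other registry yields 1146-slide
training and 953-slide validation sets per fold, exactly.

## Worked example

Run the desk-scale synthetic study (about ten minutes on one CPU):

```python
from histomil import PipelineConfig, run_demo

results = run_demo(PipelineConfig(seed=0), outdir="demo_out")
for key in ("morphology_macro_f1", "median_tumor_mask_fraction",
            "weak_auc", "tumor_auc", "necrosis_auc", "mil_auc",
            "null_auc", "mean_attention_tumor", "mean_attention_necrosis"):
    print(f"{key:>30}: {results[key]:.4f}")
```

which prints (seed 0):

```
           morphology_macro_f1: 0.9654
    median_tumor_mask_fraction: 0.3588
                      weak_auc: 0.8675
                     tumor_auc: 0.9350
                  necrosis_auc: 0.5583
                       mil_auc: 0.9650
                      null_auc: 0.5131
          mean_attention_tumor: 0.0415
       mean_attention_necrosis: 0.0000
```

Reading: the morphology model separates the five synthetic tissue classes
(held-out macro F1 0.97); cohort tumor content sits at the intended low
median (0.36); the attention-MIL model (AUC 0.97) beats the
tumor-restricted two-stage model (0.94), which beats the weakly
supervised baseline (0.87) and the uninformative necrosis-restricted
model (0.56, near chance); retraining on shuffled labels collapses to
chance (0.51); and attention concentrates on tumor patches (mean weight
0.042) rather than necrosis (1e-7) — the genotype signal is planted in
tumor texture, with a secondary immune-density signal in wild-type
slides.
`demo_out/` contains the fold assignments, attention tables, bag
summaries, mined rules, and a `metrics.json` stamped with the config hash.

The same stages are available as a CLI: `histomil simulate|patch|split|
evaluate|audit|demo` (see `histomil --help`).

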