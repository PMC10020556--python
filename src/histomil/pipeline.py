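"""End-to-end orchestration on the synthetic cohort.

``run_benchmark`` executes the full chain at desk scale — generate slides,
mask and patch them, train and apply the morphology classifier, split the
cohort, train the three genotype model families, evaluate, and audit the
MIL attention — and returns every measured quantity in one dictionary.
``run_demo`` additionally writes the artifact files (registry, fold
assignments, profiles, predictions, attention and rules tables, metrics
JSON stamped with the config hash).

Problem sizes come from the ``demo_*`` fields of :class:`PipelineConfig`;
see the methods note for why those sizes were chosen.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import audit, evaluation, models, morphology, patching, splits, synthetic
from .config import PipelineConfig, stage_seed
from .models import SlideData
from .patching import _resize  # shared bilinear resize


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def build_cohort(cfg: PipelineConfig) -> list[synthetic.SyntheticSlide]:
    return synthetic.generate_cohort(
        n_mutant=cfg.demo_n_mutant, n_wildtype=cfg.demo_n_wildtype,
        seed=stage_seed(cfg.seed, "cohort"),
        slide_size=cfg.demo_slide_size,
        mutation_patch_size=cfg.demo_mutation_patch_size,
        signal_strength=cfg.demo_signal_strength,
        immune_boost_wildtype=cfg.demo_immune_boost_wildtype,
        signal_penetrance=cfg.demo_signal_penetrance)


def annotation_patches(slides, cfg: PipelineConfig, per_class: int,
                       seed: int):
    """Labelled morphology patches from the generator's masks (standing in
    for pathologist region annotations), capped per class and resized to the
    morphology input size."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for slide in slides:
        man = patching.extract_annotation_patches(
            slide.morphology_mask, size=cfg.demo_morphology_patch_size,
            min_region_fraction=cfg.min_annotation_fraction,
            slide_id=slide.slide_id)
        for _, rec in man.df.iterrows():
            X.append(_resize(patching.get_patch(slide.image, rec),
                             cfg.demo_morphology_input_size))
            y.append(rec["morphology_call"])
    X, y = np.stack(X), np.asarray(y)
    keep = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))][:per_class]
        keep.append(idx)
    keep = np.concatenate(keep)
    return X[keep], y[keep]


def train_morphology_stage(slides, cfg: PipelineConfig):
    """Train the morphology classifier on annotation patches from a small
    slide subset; report macro f1 on patches from held-out slides."""
    seed = stage_seed(cfg.seed, "morphology")
    n_mut = cfg.demo_n_mutant
    train_slides = slides[:5] + slides[n_mut:n_mut + 5]
    test_slides = slides[5:9] + slides[n_mut + 5:n_mut + 9]
    X, y = annotation_patches(train_slides, cfg,
                              cfg.demo_morphology_patches_per_class, seed)
    model = morphology.MorphologyClassifier(
        epochs=cfg.morphology_epochs, lr=cfg.demo_learning_rate,
        random_state=seed).fit(X, y)
    Xt, yt = annotation_patches(test_slides, cfg,
                                cfg.demo_morphology_patches_per_class,
                                seed + 1)
    macro_f1 = float(f1_score(yt, model.predict(Xt), average="macro"))
    return model, macro_f1


def prepare_slide(slide, morph_model, cfg: PipelineConfig) -> SlideData | None:
    mask = patching.tissue_mask(
        slide.image, downsample=cfg.demo_mask_downsample,
        saturation_threshold=cfg.saturation_threshold,
        min_object_px=cfg.demo_mask_min_object_px,
        min_hole_px=cfg.demo_mask_min_hole_px)
    manifest = patching.extract_patches(
        slide.image, mask, size=cfg.demo_mutation_patch_size,
        min_tissue_fraction=cfg.min_tissue_fraction,
        slide_id=slide.slide_id)
    if len(manifest) == 0:
        return None
    profiled = morphology.profile_slide(
        morph_model, slide.image, manifest,
        in_size=cfg.demo_mutation_patch_size,
        crop_size=cfg.demo_mutation_patch_size // 2,
        out_size=cfg.demo_morphology_input_size)
    patches = np.stack([
        patching.resize_for_mil(patching.get_patch(slide.image, rec),
                                in_size=cfg.demo_mutation_patch_size,
                                out_size=cfg.demo_model_input_size)
        for _, rec in profiled.df.iterrows()])
    return SlideData(
        slide_id=slide.slide_id, label=int(slide.is_mutant),
        patches=patches,
        morphology_calls=profiled.df["morphology_call"].to_numpy(),
        patch_coords=profiled.df[["row", "col"]].to_numpy())


def prepare_cohort(slides, morph_model, cfg: PipelineConfig):
    data = []
    for slide in slides:
        sd = prepare_slide(slide, morph_model, cfg)
        if sd is not None:
            data.append(sd)
    return data


def split_cohort(slide_data, cfg: PipelineConfig):
    registry = pd.DataFrame({
        "specimen_id": [s.slide_id for s in slide_data],
        "is_mutant": [bool(s.label) for s in slide_data]})
    plan = splits.make_folds(
        registry, n_folds=1, mutant_train_frac=cfg.demo_mutant_train_frac,
        val_prevalence=cfg.demo_val_prevalence,
        seed=stage_seed(cfg.seed, "split"))[0]
    by_id = {s.slide_id: s for s in slide_data}
    train = [by_id[i] for i in plan.train_ids]
    val = [by_id[i] for i in plan.val_ids]
    return train, val, plan


def _auc_dropna(scores, labels):
    """AUC over slides with defined scores; None when undefined (both
    classes not represented among scored slides)."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    ok = ~np.isnan(scores)
    try:
        return evaluation.auc(scores[ok], labels[ok])
    except evaluation.UndefinedMetric:
        return None


# ---------------------------------------------------------------------------
# the full benchmark
# ---------------------------------------------------------------------------

def run_benchmark(cfg: PipelineConfig | None = None, collect=None) -> dict:
    """Run the synthetic planted-signal study end to end; returns a flat
    dictionary of everything measured.  ``collect``, when given, receives
    intermediate objects (models, tables) for artifact writing."""
    cfg = PipelineConfig() if cfg is None else cfg
    out: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    store = collect if collect is not None else {}
    t0 = time.time()

    def _stamp(stage):
        print(f"[histomil] {stage} done at {time.time() - t0:.0f}s",
              file=sys.stderr, flush=True)

    slides = build_cohort(cfg)
    out["n_slides"] = len(slides)
    mask_tumor = [s.realized_fractions()["tumor"] for s in slides]
    out["median_tumor_mask_fraction"] = float(np.median(mask_tumor))
    _stamp("cohort")

    morph_model, macro_f1 = train_morphology_stage(slides, cfg)
    out["morphology_macro_f1"] = macro_f1
    store["morphology_model"] = morph_model
    _stamp("morphology")

    slide_data = prepare_cohort(slides, morph_model, cfg)
    profiled_tumor = [
        morphology.class_fractions_from_calls(s.morphology_calls).get("tumor", 0.0)
        for s in slide_data]
    out["median_profiled_tumor_fraction"] = float(np.median(profiled_tumor))
    store["slide_data"] = slide_data
    _stamp("prepare")

    train, val, plan = split_cohort(slide_data, cfg)
    out["n_train"], out["n_val"] = len(train), len(val)
    store["split_plan"] = plan
    y_val = np.array([s.label for s in val])
    y_all = np.array([s.label for s in slide_data])

    mut_params = dict(epochs=cfg.demo_mutation_epochs,
                      lr=cfg.demo_learning_rate,
                      patience=cfg.demo_patience)

    # cap patches per slide for the patch-level families to bound epoch cost
    sub_rng = np.random.default_rng(stage_seed(cfg.seed, "patch_cap"))
    cap = cfg.demo_max_patches_per_slide

    def _subsample(sds):
        out = []
        for s in sds:
            if len(s.patches) <= cap:
                out.append(s)
            else:
                idx = sub_rng.choice(len(s.patches), size=cap, replace=False)
                out.append(SlideData(s.slide_id, s.label, s.patches[idx],
                                     s.morphology_calls[idx]))
        return out

    weak_train = _subsample(train)
    weak = models.train_weakly_supervised(
        weak_train, random_state=stage_seed(cfg.seed, "weak"), **mut_params)
    out["weak_auc"] = _auc_dropna(
        models.slide_scores(weak, val, "mean"), y_val)
    out["weak_auc_median_agg"] = _auc_dropna(
        models.slide_scores(weak, val, "median"), y_val)
    _stamp("weak")

    two_stage = {}
    for target in ("tumor", "necrosis"):
        try:
            model, excluded = models.train_two_stage(
                train, target,
                random_state=stage_seed(cfg.seed, f"two_{target}"),
                **mut_params)
        except ValueError as exc:
            # a morphology class can be absent from every profiled slide at
            # very small problem sizes; the family is then unavailable
            out[f"{target}_auc"] = None
            out[f"{target}_note"] = str(exc)
            continue
        scores = models.slide_scores(model, val, "mean", target_class=target)
        out[f"{target}_auc"] = _auc_dropna(scores, y_val)
        out[f"{target}_excluded_train"] = len(excluded)
        two_stage[target] = model
        _stamp(f"two_stage_{target}")
    store["two_stage"] = two_stage

    mil = models.train_mil(train, epochs=cfg.demo_mil_epochs,
                           bag_size=cfg.bag_size, lr=cfg.demo_learning_rate,
                           random_state=stage_seed(cfg.seed, "mil"))
    store["mil_model"] = mil
    mil_scores = mil.predict_proba([s.patches for s in val])[:, 1]
    out["mil_auc"] = evaluation.auc(mil_scores, y_val)
    _stamp("mil")
    npv, ppv, _ = evaluation.npv_ppv(mil_scores, y_val,
                                     cfg.classification_threshold)
    out["mil_npv"], out["mil_ppv"] = npv, ppv
    hc = evaluation.high_confidence_subset(mil_scores, cfg.confidence_low,
                                           cfg.confidence_high)
    if hc.size and len(np.unique(y_val[hc])) == 2:
        hnpv, hppv, _ = evaluation.npv_ppv(mil_scores[hc], y_val[hc],
                                           cfg.classification_threshold)
        out["mil_highconf_npv"], out["mil_highconf_ppv"] = hnpv, hppv

    # attention audit on validation slides
    records = models.attention_records(mil, val)
    store["attention_records"] = records
    per_class = records.groupby("morphology_call")["weight"].mean()
    for cls in synthetic.CLASS_NAMES:
        if cls in per_class.index:
            out[f"mean_attention_{cls}"] = float(per_class[cls])
    store["attention_by_morphology"] = {
        g: audit.attention_by_morphology(records, g)
        for g in ("all_patches", "median_per_slide", "max_per_slide")}

    # label-permutation null: the weakly-supervised family retrained on
    # shuffled labels; scored on the shuffled-label training slides against
    # their true labels and averaged over three shuffles.  (On held-out
    # slides a single-permutation null is dominated by sign-random
    # amplification of the cohort's main feature axis — see methods.)
    rng = np.random.default_rng(stage_seed(cfg.seed, "null"))
    y_train = np.array([s.label for s in train])
    null_aucs = []
    for rep in range(3):
        null_train = [
            SlideData(s.slide_id, lbl, s.patches, s.morphology_calls)
            for s, lbl in zip(weak_train, rng.permutation(y_train))]
        null_model = models.train_weakly_supervised(
            null_train, epochs=15, patience=20, lr=cfg.demo_learning_rate,
            random_state=stage_seed(cfg.seed, f"null_fit{rep}"))
        null_aucs.append(_auc_dropna(
            models.slide_scores(null_model, train, "mean"), y_train))
    defined = [a for a in null_aucs if a is not None]
    out["null_auc"] = float(np.mean(defined)) if defined else None
    out["null_auc_replicates"] = null_aucs
    _stamp("null")

    # pathologist-review emulation: top-k selection, summaries, stats, rules
    review = synthetic.generate_review_table(
        cfg.review_bags, cfg.review_patches_per_bag,
        seed=stage_seed(cfg.seed, "review"))
    rng_w = np.random.default_rng(stage_seed(cfg.seed, "review_weights"))
    review["weight"] = rng_w.random(len(review))
    summaries = audit.summarize_bags(review, k=cfg.review_top_k)
    out["review_rows"] = int(len(summaries) * cfg.review_top_k)
    store["review_summaries"] = summaries
    store["numeric_comparisons"] = audit.compare_all_numeric(summaries)
    store["categorical_comparison"] = audit.compare_categorical(
        summaries, "predominant_architecture")
    transactions = audit.transactions_from_summaries(summaries)
    rules_wt = audit.mine_rules(transactions, "status=wildtype",
                                min_support=0.1, min_confidence=0.5)
    store["rules_wildtype"] = rules_wt
    solid = [r for r in rules_wt
             if r.antecedent == frozenset({"predominant_architecture=solid"})]
    if solid:
        out["solid_wildtype_lift"] = solid[0].lift
    if rules_wt:
        out["top_wildtype_rule_lift"] = rules_wt[0].lift
    return out


def run_demo(cfg: PipelineConfig | None = None, outdir=None) -> dict:
    """Run the benchmark and, if ``outdir`` is given, write artifact files."""
    cfg = PipelineConfig() if cfg is None else cfg
    store: dict = {}
    results = run_benchmark(cfg, collect=store)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")
        plan = store["split_plan"]
        splits.folds_to_frame([plan]).to_csv(outdir / "folds.csv", index=False)
        store["attention_records"].to_csv(outdir / "attention.csv", index=False)
        store["review_summaries"].to_csv(outdir / "bag_summaries.csv",
                                         index=False)
        store["numeric_comparisons"].to_csv(outdir / "numeric_tests.csv",
                                            index=False)
        audit.rules_to_frame(store["rules_wildtype"]).to_csv(
            outdir / "rules_wildtype.csv", index=False)
        for g, tbl in store["attention_by_morphology"].items():
            tbl.to_csv(outdir / f"attention_{g}.csv", index=False)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
    return results
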