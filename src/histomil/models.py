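"""The three slide-genotype predictor families.

1. **Weakly supervised patch model** — every patch inherits its slide's
   binary genotype label; a convolutional patch classifier (feature
   extractor, global average pooling, dropout 0.3, 1-dimensional sigmoid
   head) is trained under binary cross-entropy, and slide scores are the
   mean (or median) of its patch predictions.
2. **Two-stage morphology-restricted models** — identical training restricted
   to patches whose morphology call equals one target class (e.g. tumor);
   slides with no qualifying patches are excluded and logged.
3. **Attention-based multiple-instance learning (MIL)** — bags of patches
   sampled per slide carry the slide label; patch embeddings pass through a
   two-layer attention trunk (512- and 256-dimensional), per-patch scores
   from a further 256- and 1-dimensional layer are softmax-normalised across
   the bag into attention weights, the weighted sum of reduced embeddings
   forms the slide embedding, and a final 1-dimensional sigmoid layer
   predicts the genotype.

At inference the MIL model can normalise its batch-normalisation layers with
the statistics of the presented bag itself (``batch_stats``; one slide per
batch, so instance interdependence is non-arbitrary) or with the running
statistics tracked during training (``moving_stats``).

All estimators are deterministic under a fixed ``random_state`` and use Adam
(default learning rate 1e-5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from ._common import as_float_images, batches, stratified_split
from .evaluation import UndefinedMetric, auc


@dataclass
class SlideData:
    """Per-slide inputs to the genotype models: model-ready patch images,
    the slide label, and (after profiling) per-patch morphology calls."""

    slide_id: str
    label: int  # 1 = mutant
    patches: np.ndarray                      # (n, H, W, 3)
    morphology_calls: np.ndarray | None = None
    patch_coords: np.ndarray | None = None   # (n, 2) row/col, optional

    def __post_init__(self):
        if self.patches.ndim != 4:
            raise ValueError("patches must be a (n, H, W, 3) array")


@dataclass
class Bag:
    """One sampled bag: the patch subset of a slide, its inherited label,
    and, after inference, the per-patch attention weights and prediction."""

    slide_id: str
    patch_indices: np.ndarray
    label: int | None = None
    attention_weights: np.ndarray | None = None
    prediction: float | None = None
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# patch-level classifier (weak supervision and two-stage restriction)
# ---------------------------------------------------------------------------


class PatchMutationClassifier(BaseEstimator, ClassifierMixin):
    """Binary patch classifier: small-CNN feature extractor + global average
    pooling + dropout (0.3) + 1-dimensional sigmoid head, trained with Adam
    on binary cross-entropy with early stopping on validation AUC."""

    def __init__(self, channels=(8, 16, 32), k=2, dropout=0.3, epochs=200,
                 lr=1e-5, batch_size=32, patience=20, val_fraction=0.15,
                 random_state=None):
        self.channels = channels
        self.k = k
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        X = as_float_images(X)
        y = np.asarray(y).astype(int)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present to train")
        rng = np.random.default_rng(self.random_state)
        train_idx, val_idx = stratified_split(y, self.val_fraction, rng)
        backbone = nn.small_cnn(self.channels, self.k, rng=rng)
        net = nn.Sequential([backbone,
                             nn.Dropout(self.dropout, rng),
                             nn.Dense(self.channels[-1], 1, rng=rng)])
        opt = nn.Adam(net.params(), lr=self.lr)
        self._net = net
        self.history_ = []
        best = (-np.inf, None)
        stale = 0
        for _epoch in range(self.epochs):
            for batch in batches(len(train_idx), self.batch_size, rng):
                idx = train_idx[batch]
                p = nn.sigmoid(net.forward(X[idx], mode="train")[:, 0])
                opt.zero_grad()
                net.backward(((p - y[idx]) / len(idx))[:, None])
                opt.step()
            try:
                val_auc = auc(self._scores(X[val_idx]), y[val_idx])
            except UndefinedMetric:
                val_auc = 0.5
            self.history_.append(val_auc)
            if val_auc > best[0]:
                best = (val_auc, nn.get_weights(net))
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        nn.set_weights(net, best[1])
        self.best_val_auc_ = best[0]
        self._net = net
        return self

    def _scores(self, X_float, batch_size=128):
        out = []
        for start in range(0, len(X_float), batch_size):
            z = self._net.forward(X_float[start:start + batch_size],
                                  mode="eval_moving")
            out.append(nn.sigmoid(z[:, 0]))
        return np.concatenate(out) if out else np.empty(0)

    def score_patches(self, X) -> np.ndarray:
        """Per-patch mutant probability in (0, 1)."""
        return self._scores(as_float_images(X))

    def predict_proba(self, X):
        p = self.score_patches(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.score_patches(X) >= 0.5).astype(int)


def aggregate_slide(patch_predictions, method: str = "mean") -> float:
    """Slide score from patch predictions by the slide average or median."""
    p = np.asarray(patch_predictions, dtype=float)
    if p.size == 0:
        raise ValueError("no patch predictions to aggregate: score missing")
    if method == "mean":
        return float(p.mean())
    if method == "median":
        return float(np.median(p))
    raise ValueError(f"unknown aggregation method {method!r}")


def train_weakly_supervised(slides: list[SlideData],
                            **params) -> PatchMutationClassifier:
    """Fit the weakly supervised family: all patches, labels inherited from
    the slide."""
    if not slides:
        raise ValueError("empty training partition")
    X = np.concatenate([s.patches for s in slides])
    y = np.concatenate([np.full(len(s.patches), s.label) for s in slides])
    return PatchMutationClassifier(**params).fit(X, y)


def train_two_stage(slides: list[SlideData], target_class: str,
                    **params) -> tuple[PatchMutationClassifier, list[str]]:
    """Fit a morphology-restricted model on patches called ``target_class``.

    Returns the model and the ids of slides excluded for having no
    qualifying patches (also reported via a warning).
    """
    keep_X, keep_y, excluded = [], [], []
    for s in slides:
        if s.morphology_calls is None:
            raise ValueError("two-stage training needs morphology-profiled slides")
        sel = s.morphology_calls == target_class
        if sel.any():
            keep_X.append(s.patches[sel])
            keep_y.append(np.full(int(sel.sum()), s.label))
        else:
            excluded.append(s.slide_id)
    if not keep_X:
        raise ValueError(f"no patches of class {target_class!r} on any slide")
    if excluded:
        warnings.warn(f"{len(excluded)} slides had no {target_class!r} "
                      "patches and were excluded")
    model = PatchMutationClassifier(**params).fit(
        np.concatenate(keep_X), np.concatenate(keep_y))
    return model, excluded


def slide_scores(model: PatchMutationClassifier, slides: list[SlideData],
                 method: str = "mean", target_class: str | None = None):
    """Aggregated slide scores; slides with no (qualifying) patches get NaN."""
    scores = np.full(len(slides), np.nan)
    for i, s in enumerate(slides):
        patches = s.patches
        if target_class is not None:
            sel = s.morphology_calls == target_class
            if not sel.any():
                continue
            patches = patches[sel]
        scores[i] = aggregate_slide(model.score_patches(patches), method)
    return scores


# ---------------------------------------------------------------------------
# attention-based MIL
# ---------------------------------------------------------------------------


class _AttentionPool:
    """Softmax attention pooling: per-patch scores from a scorer network are
    normalised across the bag and used to weight the reduced embeddings."""

    def __init__(self, scorer: nn.Sequential):
        self.scorer = scorer

    def params(self):
        return self.scorer.params()

    def forward(self, V: np.ndarray, mode: str):
        e = self.scorer.forward(V, mode)[:, 0]
        a = nn.softmax(e)
        self._V, self._a = V, a
        return a @ V, a

    def backward(self, dm: np.ndarray) -> np.ndarray:
        V, a = self._V, self._a
        dV = a[:, None] * dm[None, :]
        da = V @ dm
        de = a * (da - a @ da)
        dV += self.scorer.backward(de[:, None])
        return dV


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Attention-based multiple-instance learning genotype classifier.

    Parameters mirror the published architecture: a trainable convolutional
    feature extractor with global average pooling, an attention trunk of two
    fully-connected layers (``attention_dims``, default 512 and 256) that
    reduces the embedding, a scorer (``scorer_dim``-dimensional then
    1-dimensional fully-connected layers) whose outputs are softmax-weighted
    across the bag, and a final 1-dimensional sigmoid head on the
    attention-weighted slide embedding.  Bags of ``bag_size`` patches
    (default 40) are sampled once per slide per epoch, one slide per batch;
    the bag-level binary cross-entropy is optimised by Adam.

    ``inference_mode`` selects how batch-normalisation statistics are formed
    at prediction time: ``"batch_stats"`` (from the presented bag) or
    ``"moving_stats"`` (running statistics from training).
    """

    def __init__(self, channels=(8, 16, 32), k=2, attention_dims=(512, 256),
                 scorer_dim=256, bag_size=40, epochs=50, lr=1e-5,
                 random_state=None, inference_mode="batch_stats",
                 slides_per_batch=2):
        self.channels = channels
        self.k = k
        self.attention_dims = attention_dims
        self.scorer_dim = scorer_dim
        self.bag_size = bag_size
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state
        self.inference_mode = inference_mode
        self.slides_per_batch = slides_per_batch

    def _build(self, rng):
        d = self.channels[-1]
        d1, d2 = self.attention_dims
        self._backbone = nn.small_cnn(self.channels, self.k, rng=rng)
        self._trunk = nn.Sequential([nn.Dense(d, d1, rng=rng), nn.ReLU(),
                                     nn.Dense(d1, d2, rng=rng), nn.ReLU()])
        self._pool = _AttentionPool(nn.Sequential(
            [nn.Dense(d2, self.scorer_dim, rng=rng), nn.Tanh(),
             nn.Dense(self.scorer_dim, 1, rng=rng)]))
        self._head = nn.Dense(d2, 1, rng=rng)
        return (self._backbone.params() + self._trunk.params()
                + self._pool.params() + self._head.params())

    def fit(self, bags: list[np.ndarray], y):
        if self.bag_size < 2:
            raise ValueError("bag_size must be >= 2 (attention over a "
                             "single instance is degenerate)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        y = np.asarray(y).astype(int)
        if len(bags) != len(y):
            raise ValueError("one label per bag required")
        if any(len(b) < 1 for b in bags):
            raise ValueError("every slide must yield at least one patch")
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        params = self._build(rng)
        opt = nn.Adam(params, lr=self.lr)
        floats = [as_float_images(b) for b in bags]
        self.loss_history_ = []
        spb = max(1, int(self.slides_per_batch))
        for _epoch in range(self.epochs):
            losses = []
            order = rng.permutation(len(floats))
            for start in range(0, len(order), spb):
                group = order[start:start + spb]
                xs = [self._sample_bag(floats[i], rng) for i in group]
                # one joint backbone pass: batch-normalisation statistics mix
                # the grouped slides during training
                emb = self._backbone.forward(np.concatenate(xs), mode="train")
                opt.zero_grad()
                dembs = []
                off = 0
                for i, xb in zip(group, xs):
                    e = emb[off:off + len(xb)]
                    off += len(xb)
                    V = self._trunk.forward(e, mode="train")
                    m, _a = self._pool.forward(V, mode="train")
                    z = self._head.forward(m[None, :], mode="train")[0, 0]
                    p = float(nn.sigmoid(z))
                    losses.append(nn.binary_cross_entropy([p], [y[i]]))
                    dm = self._head.backward(np.array([[p - y[i]]]))[0]
                    dembs.append(self._trunk.backward(self._pool.backward(dm)))
                self._backbone.backward(np.concatenate(dembs))
                opt.step()
            self.loss_history_.append(float(np.mean(losses)))
        self.fitted_ = True
        return self

    def _sample_bag(self, patches, rng):
        n = len(patches)
        replace = n < self.bag_size
        idx = rng.choice(n, size=self.bag_size, replace=replace)
        return patches[idx]

    def _forward(self, xb, mode):
        emb = self._backbone.forward(xb, mode)
        V = self._trunk.forward(emb, mode)
        m, a = self._pool.forward(V, mode)
        z = self._head.forward(m[None, :], mode)[0, 0]
        return float(nn.sigmoid(z)), a

    def _backward(self, dz):
        dm = self._head.backward(np.array([[dz]]))[0]
        dV = self._pool.backward(dm)
        demb = self._trunk.backward(dV)
        self._backbone.backward(demb)

    def _infer_mode(self, override=None):
        mode = self.inference_mode if override is None else override
        if mode not in ("batch_stats", "moving_stats"):
            raise ValueError(f"unknown batchnorm mode {mode!r}")
        return "eval_batch" if mode == "batch_stats" else "eval_moving"

    def predict_bag(self, bag: np.ndarray, batchnorm_mode: str | None = None):
        """(prediction, attention weights) for one bag; weights are positive
        and sum to 1."""
        if len(bag) == 0:
            raise ValueError("empty bag")
        xb = as_float_images(bag)
        return self._forward(xb, mode=self._infer_mode(batchnorm_mode))

    def predict_proba(self, bags, batchnorm_mode: str | None = None):
        p = np.array([self.predict_bag(b, batchnorm_mode)[0] for b in bags])
        return np.column_stack([1.0 - p, p])

    def predict(self, bags):
        return (self.predict_proba(bags)[:, 1] >= 0.5).astype(int)


def train_mil(slides: list[SlideData], **params) -> AttentionMILClassifier:
    """Fit the attention-MIL family on per-slide bags with inherited labels."""
    if not slides:
        raise ValueError("empty training partition")
    bags = [s.patches for s in slides]
    y = [s.label for s in slides]
    return AttentionMILClassifier(**params).fit(bags, y)


def infer_mil(model: AttentionMILClassifier, slide: SlideData,
              batchnorm_mode: str = "batch_stats",
              patch_indices: np.ndarray | None = None) -> Bag:
    """Run MIL inference on one slide's bag (all patches unless
    ``patch_indices`` selects a sample) and return the populated Bag."""
    idx = (np.arange(len(slide.patches)) if patch_indices is None
           else np.asarray(patch_indices))
    if idx.size == 0:
        raise ValueError("empty bag")
    pred, weights = model.predict_bag(slide.patches[idx], batchnorm_mode)
    return Bag(slide_id=slide.slide_id, patch_indices=idx, label=slide.label,
               attention_weights=weights, prediction=pred)


def attention_records(model: AttentionMILClassifier,
                      slides: list[SlideData],
                      batchnorm_mode: str = "batch_stats") -> pd.DataFrame:
    """Per-patch attention table across slides (slide_id, patch_index,
    weight, morphology_call, label, prediction) for the audit layer."""
    rows = []
    for s in slides:
        bag = infer_mil(model, s, batchnorm_mode)
        calls = (s.morphology_calls if s.morphology_calls is not None
                 else np.full(len(s.patches), "unknown"))
        for j, w in zip(bag.patch_indices, bag.attention_weights):
            rows.append({"slide_id": s.slide_id, "patch_index": int(j),
                         "weight": float(w),
                         "morphology_call": calls[j],
                         "label": s.label, "prediction": bag.prediction})
    return pd.DataFrame(rows)
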