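"""Patch-level tissue morphology classification (stage one of the two-stage
genotype models).

:class:`MorphologyClassifier` is a K-class convolutional classifier: a
trainable feature extractor ending in global average pooling, followed by a
K-dimensional fully-connected layer with softmax activation, optimised by
Adam under the categorical cross-entropy loss.  Training runs a fixed number
of epochs (default 15) and keeps the weights of the epoch with the highest
validation accuracy.

``profile_slide`` applies a trained classifier to every mutation-scale grid
patch of a slide by classifying its centre crop (1024 -> central 512 -> 448
at full scale) and propagating that call to the whole patch; per-slide
morphology area fractions are then patch counts over total patches.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from ._common import as_float_images, batches, stratified_split
from .patching import PatchManifest, center_crop_resize, get_patch


class MorphologyClassifier(BaseEstimator, ClassifierMixin):
    """K-class patch classifier with a pluggable small-CNN backbone.

    Parameters
    ----------
    channels : tuple of int
        Feature channels of the strided conv blocks; the last entry is the
        embedding dimension fed to the softmax head.
    k : int
        Window/stride of each conv block; input sides must be divisible by
        ``k ** len(channels)``.
    epochs, lr, batch_size : training schedule (Adam).
    val_fraction : fraction of examples held out per class to pick the best
        epoch by validation accuracy.
    random_state : seed for weight init, shuffling and the split.
    """

    def __init__(self, channels=(8, 16, 32), k=2, epochs=15, lr=1e-5,
                 batch_size=32, val_fraction=0.2, random_state=None):
        self.channels = channels
        self.k = k
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        X = as_float_images(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to train")
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state)
        train_idx, val_idx = stratified_split(y_idx, self.val_fraction, rng)
        k_classes = len(self.classes_)
        self._backbone = nn.small_cnn(self.channels, self.k, rng=rng)
        self._head = nn.Dense(self.channels[-1], k_classes, rng=rng)
        net = nn.Sequential([self._backbone, self._head])
        opt = nn.Adam(net.params(), lr=self.lr)
        self._net = net
        onehot = np.eye(k_classes)[y_idx]
        self.history_ = []
        best = (-1.0, None)
        for _epoch in range(self.epochs):
            for batch in batches(len(train_idx), self.batch_size, rng):
                idx = train_idx[batch]
                logits = net.forward(X[idx], mode="train")
                probs = nn.softmax(logits, axis=1)
                opt.zero_grad()
                net.backward((probs - onehot[idx]) / len(idx))
                opt.step()
            acc = float(np.mean(
                self._predict_idx(X[val_idx]) == y_idx[val_idx]))
            self.history_.append(acc)
            if acc > best[0]:
                best = (acc, nn.get_weights(net))
        nn.set_weights(net, best[1])
        self.best_val_accuracy_ = best[0]
        self.best_epoch_ = int(np.argmax(self.history_)) + 1
        self._net = net
        return self

    # -- inference ----------------------------------------------------------

    def _predict_idx(self, X_float, batch_size=64):
        out = []
        for start in range(0, len(X_float), batch_size):
            logits = self._net.forward(X_float[start:start + batch_size],
                                       mode="eval_moving")
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def predict_proba(self, X):
        X = as_float_images(X)
        out = []
        for start in range(0, len(X), 64):
            logits = self._net.forward(X[start:start + 64], mode="eval_moving")
            out.append(nn.softmax(logits, axis=1))
        return np.vstack(out)

    def predict(self, X):
        return self.classes_[self._predict_idx(as_float_images(X))]


def train_morphology(patches, labels, epochs: int = 15,
                     **params) -> MorphologyClassifier:
    """Fit a :class:`MorphologyClassifier`; returns the estimator whose
    ``history_`` holds per-epoch validation accuracy and whose weights are
    the best-epoch checkpoint."""
    return MorphologyClassifier(epochs=epochs, **params).fit(patches, labels)


def profile_slide(model: MorphologyClassifier, slide: np.ndarray,
                  manifest: PatchManifest, in_size: int | None = None,
                  crop_size: int | None = None,
                  out_size: int | None = None) -> PatchManifest:
    """Morphology-profile every patch of a manifest.

    Each patch is centre-cropped to half its side, resized (default
    1024 -> 512 -> 448), classified, and the call propagated to the whole
    patch in a new manifest.
    """
    if len(manifest) == 0:
        raise ValueError("cannot profile an empty manifest")
    size = int(manifest.df["size"].iloc[0])
    in_size = size if in_size is None else in_size
    crop_size = in_size // 2 if crop_size is None else crop_size
    out_size = round(crop_size * 448 / 512) if out_size is None else out_size
    crops = np.stack([
        center_crop_resize(get_patch(slide, rec), in_size=in_size,
                           crop_size=crop_size, out_size=out_size)
        for _, rec in manifest.df.iterrows()])
    calls = model.predict(crops)
    df = manifest.df.copy()
    df["morphology_call"] = calls
    return PatchManifest(df, dict(manifest.params, profiled=True))


def class_fractions_from_calls(calls) -> dict[str, float]:
    """Morphology area fractions from an array of per-patch calls."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("fractions undefined without patches")
    values, counts = np.unique(calls, return_counts=True)
    return {str(v): float(c) / calls.size for v, c in zip(values, counts)}


def class_fractions(manifest: PatchManifest) -> dict[str, float]:
    """Per-slide fractional area per class: class patch count / total patches.

    Fractions sum to 1 across the classes present; an empty manifest has no
    defined fractions and is rejected.
    """
    if len(manifest) == 0:
        raise ValueError("fractions undefined for an empty manifest")
    counts = manifest.df["morphology_call"].value_counts()
    total = int(counts.sum())
    return {cls: float(n) / total for cls, n in counts.items()}
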