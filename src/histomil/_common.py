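"""Shared helpers for the trainable estimators."""

from __future__ import annotations

import numpy as np


def as_float_images(X: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) images to float in [-0.5, 0.5]; accepts uint8 (0..255)
    or float arrays already scaled to [0, 1]."""
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got shape {X.shape}")
    X = X.astype(np.float32)  # float32 keeps large patch stacks affordable
    if X.max(initial=0.0) > 1.5:
        X = X / 255.0
    return X - 0.5


def stratified_split(y: np.ndarray, val_fraction: float,
                     rng: np.random.Generator):
    """Per-class shuffled train/validation index split with at least one
    validation example per class."""
    y = np.asarray(y)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        if n_val >= len(idx):
            raise ValueError(f"class {cls!r} has too few examples "
                             f"({len(idx)}) for a validation split")
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def batches(n: int, batch_size: int, rng: np.random.Generator | None = None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
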