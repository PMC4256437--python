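"""Class-imbalance correction for training data.

Behavioral states are far from equally frequent (in the original study
roughly 5% walking, 70% grazing, 25% resting), and classifiers trained
on raw frequencies over-predict the majority state.  Two corrections are
provided: random undersampling (RUS), which draws each class down to the
smallest class size without replacement, and SMOTE, which synthesizes
new minority rows by interpolating between a minority point and one of
its k nearest same-class neighbors.

Both operate on a numeric feature matrix plus a label vector and are
deterministic under a fixed seed.  When RUS is used inside a random
forest, the trainer draws a fresh undersample per tree (see
``grazetrack.classify``); the functions here are the single-draw
primitives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["BalancingSpec", "random_undersample", "smote_augment"]


@dataclass(frozen=True)
class BalancingSpec:
    """How to rebalance training data before (or inside) a classifier."""

    method: Literal["none", "rus", "smote"] = "none"
    k_neighbors: int = 5
    target_size: int | None = None  # per-class rows; None = majority count (SMOTE)
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("none", "rus", "smote"):
            raise ValueError(f"unknown balancing method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_size is not None and self.target_size < 1:
            raise ValueError("target_size must be >= 1")


def _as_array(features):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(), features.columns
    return np.asarray(features), None


def random_undersample(features, labels, seed: int = 0):
    """Downsample every class without replacement to the smallest class size.

    Parameters
    ----------
    features : (n, p) array or DataFrame
    labels : (n,) array of class labels
    seed : int
        Seed for the row draw; fixed seed gives byte-identical output.

    Returns
    -------
    (features, labels)
        Same container types as the input; rows are a subset of the input
        rows, ``min-class-count`` per class, in class-then-draw order.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any():
        raise ValueError("every class needs at least one row")
    n_min = counts.min()
    keep = np.concatenate(
        [rng.choice(np.flatnonzero(labels == c), size=n_min, replace=False) for c in classes]
    )
    if isinstance(features, pd.DataFrame):
        return features.iloc[keep], labels[keep]
    return np.asarray(features)[keep], labels[keep]


def smote_augment(features, labels, k: int = 5, target_size: int | None = None, seed: int = 0):
    """Raise every minority class to ``target_size`` rows with SMOTE.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of ``x``'s ``k`` nearest same-class neighbors under
    Euclidean distance, so every synthetic row lies on a segment between
    two same-class originals.  All original rows are retained.

    Parameters
    ----------
    k : int
        Neighborhood size; every class below target must have more than
        ``k`` rows.
    target_size : int, optional
        Per-class row count after augmentation; defaults to the majority
        class count (full three-class balance).
    """
    labels = np.asarray(labels)
    x, columns = _as_array(features)
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("SMOTE requires missing-free numeric features")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    target = int(target_size) if target_size is not None else int(counts.max())

    new_x, new_y = [x], [labels]
    for c, count in zip(classes, counts):
        n_needed = target - count
        if n_needed <= 0:
            continue
        if count <= k:
            raise ValueError(
                f"class {c!r} has {count} rows; SMOTE with k={k} needs more than k rows"
            )
        xc = x[labels == c]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(xc)
        neighbor_idx = nn.kneighbors(xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, count, size=n_needed)
        pick = rng.integers(0, k, size=n_needed)
        u = rng.uniform(0.0, 1.0, size=n_needed)
        seeds_ = xc[base]
        neighbors_ = xc[neighbor_idx[base, pick]]
        new_x.append(seeds_ + u[:, None] * (neighbors_ - seeds_))
        new_y.append(np.full(n_needed, c, dtype=labels.dtype))

    out_x = np.vstack(new_x)
    out_y = np.concatenate(new_y)
    if columns is not None:
        out_x = pd.DataFrame(out_x, columns=columns)
    return out_x, out_y
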