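"""Behavioral-state classifiers: random forest, LDA, RBF-SVM, null model.

The model grid mirrors the study design: eight classifiers that differ in
approach (random forest A–E, linear discriminant analysis F, Gaussian
radial-basis support vector machine G, state-space model H — the latter
lives in :mod:`grazetrack.ssm`), in training-data preselection (none,
per-tree random undersampling, SMOTE) and in predictor set (1 distance +
turning angle; the full 87 + 15 catalog at 20 s; the thinned 27 + 5
catalog at 60 s).  A frequency-matched null model draws states at random
in the abundance in which they occur.

The random forest is a thin in-package ensemble over sklearn decision
trees rather than ``RandomForestClassifier``: random undersampling has to
happen *inside* the forest (a fresh stratified draw per tree), and the
per-class permutation variable importance is computed from each tree's
out-of-bag rows — neither is exposed by the sklearn forest.  Trees use
bootstrap (or RUS) row sampling and sqrt(p) feature subsetting with
unlimited depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr_pivot
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balancing import BalancingSpec, random_undersample, smote_augment
from .metrics import BASIC_PREDICTORS, LABEL_COLUMN

__all__ = [
    "UNCLASSIFIABLE",
    "ClassifierSpec",
    "PredictionResult",
    "RandomForest",
    "FittedClassifier",
    "table1_spec",
    "fit_classifier",
    "predict_states",
    "null_model_assign",
    "variable_importance",
]

logger = logging.getLogger(__name__)

#: Predicted label for rows with missing predictors.
UNCLASSIFIABLE = "unclassifiable"

Approach = Literal["rf", "lda", "svm", "null"]
PredictorSet = Literal["basic", "full", "thinned"]


@dataclass(frozen=True)
class ClassifierSpec:
    """One row of the model grid.

    ``predictor_set``: ``basic`` = distance to the preceding position plus
    turning angle; ``full`` = the complete 20 s catalog (87 + 15);
    ``thinned`` = the 60 s catalog (27 + 5).  ``interval`` is the fix
    interval the features are built at; 60 s implies thinning 20 s data by
    a factor of 3 first.
    """

    model_id: str
    approach: Approach
    balancing: BalancingSpec = BalancingSpec()
    predictor_set: PredictorSet = "full"
    interval: float = 20.0
    rf_trees: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.approach not in ("rf", "lda", "svm", "null"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")


#: The published model grid (approach, balancing, predictor set, interval).
_TABLE1: dict[str, tuple[Approach, str, PredictorSet, float]] = {
    "A": ("rf", "none", "basic", 20.0),
    "B": ("rf", "none", "full", 20.0),
    "C": ("rf", "rus", "full", 20.0),
    "D": ("rf", "smote", "full", 20.0),
    "E": ("rf", "rus", "thinned", 60.0),
    "F": ("lda", "smote", "full", 20.0),
    "G": ("svm", "smote", "full", 20.0),
    "null": ("null", "none", "basic", 20.0),
}


def table1_spec(model_id: str, *, seed: int = 0, rf_trees: int = 500) -> ClassifierSpec:
    """Spec for one of the published machine-learning models (A–G, null).

    The state-space model H is fitted with :func:`grazetrack.ssm.fit_ssm`.
    """
    key = model_id if model_id == "null" else model_id.upper()
    if key not in _TABLE1:
        raise KeyError(f"unknown model {model_id!r}; choose from {sorted(_TABLE1)} (H is in grazetrack.ssm)")
    approach, balancing, predictors, interval = _TABLE1[key]
    return ClassifierSpec(
        model_id=key,
        approach=approach,
        balancing=BalancingSpec(method=balancing, seed=seed),
        predictor_set=predictors,
        interval=interval,
        rf_trees=rf_trees,
        seed=seed,
    )


@dataclass
class PredictionResult:
    """Per-position predicted states for one scored sequence."""

    labels: np.ndarray
    model_id: str
    sequence_id: str | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return self.labels.size


# ---------------------------------------------------------------------------
# random forest with per-tree sampling


class RandomForest:
    """Ensemble of CART trees with per-tree row sampling.

    ``sampler='bootstrap'`` draws n rows with replacement per tree (the
    classic forest); ``sampler='rus'`` draws a fresh stratified
    undersample per tree — every class sampled without replacement down
    to the smallest class size — which is how undersampling is combined
    with a forest in the study design.  Feature subsetting is sqrt(p) at
    every split, trees are grown to purity.
    """

    def __init__(self, n_trees: int = 500, sampler: str = "bootstrap", seed: int = 0):
        if sampler not in ("bootstrap", "rus"):
            raise ValueError(f"unknown sampler {sampler!r}")
        self.n_trees = int(n_trees)
        self.sampler = sampler
        self.seed = int(seed)

    def fit(self, x: np.ndarray, y: Sequence) -> "RandomForest":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        n = x.shape[0]
        rng = np.random.default_rng(self.seed)
        class_indices = [np.flatnonzero(codes == c) for c in range(self.classes_.size)]
        n_min = min(idx.size for idx in class_indices)
        self.trees_: list[DecisionTreeClassifier] = []
        self.inbag_: list[np.ndarray] = []
        for _ in range(self.n_trees):
            if self.sampler == "bootstrap":
                rows = rng.integers(0, n, size=n)
            else:
                rows = np.concatenate(
                    [rng.choice(idx, size=n_min, replace=False) for idx in class_indices]
                )
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(x[rows], codes[rows])
            self.trees_.append(tree)
            self.inbag_.append(rows)
        self._n_rows = n
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        votes = np.zeros((x.shape[0], self.classes_.size), dtype=np.int32)
        for tree in self.trees_:
            votes[np.arange(x.shape[0]), tree.predict(x).astype(int)] += 1
        return self.classes_[votes.argmax(axis=1)]

    def oob_permutation_importance(self, x: np.ndarray, y: Sequence, seed: int = 0) -> np.ndarray:
        """Per-class permutation importance from out-of-bag rows.

        For every tree, each predictor column is permuted among the
        tree's out-of-bag rows and the drop in class-specific accuracy
        (recall) is recorded; the result is the (p, n_classes) mean drop
        over trees.  Noise columns score ~0, informative columns > 0.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        codes = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(seed)
        p, k = x.shape[1], self.classes_.size
        drops = np.zeros((p, k))
        counts = np.zeros((p, k))
        all_rows = np.arange(x.shape[0])
        for tree, inbag in zip(self.trees_, self.inbag_):
            oob = np.setdiff1d(all_rows, np.unique(inbag), assume_unique=True)
            if oob.size == 0:
                continue
            xo, yo = x[oob], codes[oob]
            base_pred = tree.predict(xo).astype(int)
            class_masks = [yo == c for c in range(k)]
            base_acc = np.array(
                [np.mean(base_pred[m] == c) if m.any() else np.nan for c, m in enumerate(class_masks)]
            )
            for j in range(p):
                xp = xo.copy()
                xp[:, j] = xp[rng.permutation(oob.size), j]
                perm_pred = tree.predict(xp).astype(int)
                for c, m in enumerate(class_masks):
                    if m.any():
                        drops[j, c] += base_acc[c] - np.mean(perm_pred[m] == c)
                        counts[j, c] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)


class _ConstantClassifier:
    """Returned when training data contains a single class."""

    def __init__(self, label):
        self.classes_ = np.array([label])

    def predict(self, x):
        return np.full(np.asarray(x).shape[0], self.classes_[0])


# ---------------------------------------------------------------------------
# fitting and prediction


def _collinear_columns(x: np.ndarray, y: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that make the pooled within-class covariance singular."""
    centered = np.vstack([x[y == c] - x[y == c].mean(axis=0) for c in np.unique(y)])
    _, r, piv = _qr_pivot(centered, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(centered.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator, max_rows: int = 500) -> float:
    """RBF bandwidth: gamma = 1 / (2 * median pairwise squared distance)."""
    if x.shape[0] > max_rows:
        x = x[rng.choice(x.shape[0], size=max_rows, replace=False)]
    sq = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    med = np.median(sq[np.triu_indices_from(sq, k=1)])
    return 1.0 / (2.0 * med) if med > 0 else 1.0


@dataclass
class FittedClassifier:
    """A fitted model plus the feature-column contract it was trained on."""

    model: object
    columns: tuple[str, ...]
    classes: np.ndarray
    spec: ClassifierSpec

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predict one label per complete row; incomplete rows are
        ``unclassifiable``.  Feature columns must match training."""
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.columns if c not in features.columns]
            if missing:
                raise ValueError(f"feature columns missing at prediction time: {missing}")
            x = features.loc[:, list(self.columns)].to_numpy(dtype=float)
        else:
            x = np.asarray(features, dtype=float)
            if x.ndim != 2 or x.shape[1] != len(self.columns):
                raise ValueError(
                    f"expected {len(self.columns)} feature columns, got {x.shape[1] if x.ndim == 2 else 'non-2d'}"
                )
        out = np.full(x.shape[0], UNCLASSIFIABLE, dtype=object)
        complete = ~np.isnan(x).any(axis=1)
        if complete.any():
            out[complete] = self.model.predict(x[complete])
        return out


def _select_columns(features: pd.DataFrame, spec: ClassifierSpec) -> list[str]:
    cols = [c for c in features.columns if c != LABEL_COLUMN]
    if spec.predictor_set == "basic":
        missing = [c for c in BASIC_PREDICTORS if c not in cols]
        if missing:
            raise ValueError(f"basic predictor columns absent from the feature table: {missing}")
        return list(BASIC_PREDICTORS)
    return cols


def fit_classifier(spec: ClassifierSpec, features: pd.DataFrame, labels: Sequence) -> FittedClassifier:
    """Train the classifier described by ``spec`` on a feature table.

    Rows with missing predictors are dropped from training; balancing is
    applied per the spec (SMOTE/global RUS before fitting, per-tree RUS
    inside the forest).  ``features`` may include the label column, which
    is ignored in favor of ``labels``.
    """
    columns = _select_columns(features, spec)
    x = features.loc[:, columns].to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    y = np.asarray(labels)
    complete = ~np.isnan(x).any(axis=1)
    if not complete.all():
        logger.info("dropping %d incomplete training rows", int((~complete).sum()))
        x, y = x[complete], y[complete]
    if x.shape[0] == 0:
        raise ValueError("no complete training rows")

    classes = np.unique(y)
    if classes.size == 1:
        return FittedClassifier(_ConstantClassifier(classes[0]), tuple(columns), classes, spec)

    bal = spec.balancing
    if bal.method == "smote":
        x, y = smote_augment(x, y, k=bal.k_neighbors, target_size=bal.target_size, seed=bal.seed)
    elif bal.method == "rus" and spec.approach != "rf":
        x, y = random_undersample(x, y, seed=bal.seed)

    if spec.approach == "rf":
        sampler = "rus" if bal.method == "rus" else "bootstrap"
        model = RandomForest(n_trees=spec.rf_trees, sampler=sampler, seed=spec.seed).fit(x, y)
        model_classes = model.classes_
    elif spec.approach == "lda":
        bad = _collinear_columns(x, y, columns)
        if bad:
            raise ValueError(
                "singular pooled within-class covariance; collinear columns: " + ", ".join(bad)
            )
        model = LinearDiscriminantAnalysis().fit(x, y)
        model_classes = model.classes_
    elif spec.approach == "svm":
        rng = np.random.default_rng(spec.seed)
        model = SVC(kernel="rbf", C=1.0, gamma=_median_heuristic_gamma(x, rng)).fit(x, y)
        model_classes = model.classes_
    else:  # null
        model = _NullModel(y, seed=spec.seed)
        model_classes = model.classes_
    return FittedClassifier(model, tuple(columns), model_classes, spec)


def predict_states(
    classifier: FittedClassifier,
    features: pd.DataFrame | np.ndarray,
    sequence_id: str | None = None,
) -> PredictionResult:
    """Apply a fitted classifier to a feature table."""
    labels = classifier.predict(features)
    return PredictionResult(labels, classifier.spec.model_id, sequence_id)


class _NullModel:
    """Draws states i.i.d. from the empirical class distribution."""

    def __init__(self, labels, seed: int = 0):
        labels = np.asarray(labels)
        self.classes_, counts = np.unique(labels, return_counts=True)
        self.probs_ = counts / counts.sum()
        self._rng = np.random.default_rng(seed)

    def predict(self, x):
        return self._rng.choice(self.classes_, size=np.asarray(x).shape[0], p=self.probs_)


def null_model_assign(labels: Sequence, seed: int = 0, model_id: str = "null") -> PredictionResult:
    """Frequency-matched random assignment over the observed labels.

    Each position receives an i.i.d. draw from the empirical distribution
    of the given label vector, so the expected state-specific accuracy of
    every state equals that state's relative frequency.
    """
    labels = np.asarray(labels)
    model = _NullModel(labels, seed=seed)
    return PredictionResult(model.predict(np.empty((labels.size, 0))), model_id)


def variable_importance(
    spec: ClassifierSpec,
    features: pd.DataFrame,
    labels: Sequence,
    n_realizations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean per-state permutation importance over forest realizations.

    Fits ``n_realizations`` independent forests (fresh seeds) and averages
    the out-of-bag per-class permutation importance of every predictor.
    Returns a DataFrame indexed by metric name with one column per state.
    Only defined for random-forest specs.
    """
    if spec.approach != "rf":
        raise ValueError("variable importance is defined for random-forest specs only")
    columns = _select_columns(features, spec)
    x = features.loc[:, columns].to_numpy(dtype=float)
    y = np.asarray(labels)
    complete = ~np.isnan(x).any(axis=1)
    x, y = x[complete], y[complete]
    sampler = "rus" if spec.balancing.method == "rus" else "bootstrap"
    total = None
    for r in range(n_realizations):
        forest = RandomForest(n_trees=spec.rf_trees, sampler=sampler, seed=seed + 1000 * r).fit(x, y)
        imp = forest.oob_permutation_importance(x, y, seed=seed + 1000 * r + 1)
        total = imp if total is None else total + imp
    mean_imp = total / n_realizations
    forest_classes = np.unique(y)
    return pd.DataFrame(mean_imp, index=columns, columns=forest_classes)
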