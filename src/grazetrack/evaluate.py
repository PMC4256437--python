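"""Leave-one-sequence-out validation and accuracy accounting.

Classification accuracy is quantified the way it would be used in the
field: whole observed sequences are held out in turn and predicted from
models fitted to the remaining sequences (LOSO).  Accuracy is the
percentage of correctly classified positions, computed per sequence and
jointly over all scored positions; only positions observed as one of the
three behavioral states and predicted as a state enter the denominator
(unlabeled, "other" and unclassifiable positions are excluded).

The module also provides row-normalized confusion matrices, behavioral
budgets (relative state abundance), paired t-tests between models'
per-sequence accuracies, and per-state kinematic summaries (speed and
absolute turning angle) that reproduce the study's descriptive figures
on labeled data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    UNCLASSIFIABLE,
    ClassifierSpec,
    FittedClassifier,
    fit_classifier,
)
from .metrics import LABEL_COLUMN, build_feature_table, metric_catalog
from .tracks import BEHAVIOR_STATES, TrackSequence, subsample
from . import ssm as _ssm

__all__ = [
    "AccuracyReport",
    "BehavioralBudget",
    "TTestResult",
    "ClassifierPipeline",
    "SSMPipeline",
    "NullPipeline",
    "OraclePipeline",
    "loso_evaluate",
    "accuracy_report",
    "confusion_matrix",
    "behavioral_budget",
    "compare_models",
    "summarize_state_kinematics",
]

logger = logging.getLogger(__name__)

_STATES = set(BEHAVIOR_STATES)


@dataclass
class AccuracyReport:
    """Per-sequence and joint classification accuracies (percent)."""

    model_id: str
    per_sequence: dict[str, float]
    joint_overall: float
    per_sequence_mean: float
    per_state: dict[str, float]
    interval_50: tuple[float, float]
    interval_95: tuple[float, float]
    confusion: pd.DataFrame
    predicted_budget: dict[str, float]
    n_scored: int


@dataclass(frozen=True)
class BehavioralBudget:
    """Relative abundance of the three behavioral states."""

    proportions: dict[str, float]

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("budget proportions must sum to 1")

    def __getitem__(self, state: str) -> float:
        return self.proportions[state]


@dataclass(frozen=True)
class TTestResult:
    """Paired two-sided t-test between per-sequence accuracy vectors."""

    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# pipelines: fit on training sequences, predict a held-out sequence


class ClassifierPipeline:
    """Feature-building + balancing + classifier, as one refittable unit.

    ``fit`` builds per-sequence feature tables at the spec's interval
    (thinning 20 s tracks by 3 for 60 s specs), pools complete rows with
    a modeled-state label, applies the spec's balancing, and trains the
    classifier.  ``predict`` returns the (possibly thinned) scored track
    and one predicted label per position, ``unclassifiable`` where
    predictors are incomplete.
    """

    def __init__(self, spec: ClassifierSpec, horizon: float = 300.0):
        self.spec = spec
        self.horizon = horizon
        self.catalog = metric_catalog(spec.interval, horizon)
        self.classifier_: FittedClassifier | None = None

    def _prepare(self, track: TrackSequence) -> TrackSequence:
        if self.spec.interval == track.interval:
            return track
        factor = self.spec.interval / track.interval
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                f"track interval {track.interval}s incompatible with spec interval {self.spec.interval}s"
            )
        return subsample(track, int(round(factor)))

    def fit(self, tracks: Sequence[TrackSequence]) -> "ClassifierPipeline":
        tables = [build_feature_table(self._prepare(t), self.catalog) for t in tracks]
        table = pd.concat(tables, ignore_index=True)
        usable = table[LABEL_COLUMN].isin(_STATES)
        table = table.loc[usable]
        self.classifier_ = fit_classifier(self.spec, table, table[LABEL_COLUMN].to_numpy())
        return self

    def predict(self, track: TrackSequence) -> tuple[TrackSequence, np.ndarray]:
        if self.classifier_ is None:
            raise RuntimeError("pipeline is not fitted")
        scored = self._prepare(track)
        features = build_feature_table(scored, self.catalog)
        return scored, self.classifier_.predict(features)


class SSMPipeline:
    """State-space model H: joint fit on training sequences, FFBS decode
    of the held-out sequence under the posterior draws."""

    def __init__(self, mcmc: _ssm.MCMCConfig | None = None, seed: int = 0, thin: int = 5):
        self.mcmc = mcmc
        self.seed = seed
        self.thin = thin
        self.posterior_: _ssm.PosteriorSample | None = None

    def fit(self, tracks: Sequence[TrackSequence]) -> "SSMPipeline":
        self.posterior_ = _ssm.fit_ssm(list(tracks), mcmc=self.mcmc, seed=self.seed)
        return self

    def predict(self, track: TrackSequence) -> tuple[TrackSequence, np.ndarray]:
        if self.posterior_ is None:
            raise RuntimeError("pipeline is not fitted")
        result = _ssm.decode_track(self.posterior_, track, seed=self.seed, thin=self.thin)
        return track, result.labels


class NullPipeline:
    """Frequency-matched random assignment, frequencies from training data."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self.probs_: np.ndarray | None = None

    def fit(self, tracks: Sequence[TrackSequence]) -> "NullPipeline":
        labels = np.concatenate([t.labels for t in tracks])
        labels = labels[np.isin(labels, list(_STATES))]
        classes, counts = np.unique(labels, return_counts=True)
        self.classes_, self.probs_ = classes, counts / counts.sum()
        return self

    def predict(self, track: TrackSequence) -> tuple[TrackSequence, np.ndarray]:
        if self.probs_ is None:
            raise RuntimeError("pipeline is not fitted")
        return track, self._rng.choice(self.classes_, size=len(track), p=self.probs_)


class OraclePipeline:
    """Returns the true labels; pins the top of the accuracy scale."""

    def fit(self, tracks):
        return self

    def predict(self, track):
        return track, track.labels.copy()


# ---------------------------------------------------------------------------
# scoring


def _scored_mask(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    return np.isin(observed, list(_STATES)) & np.isin(predicted, list(_STATES))


def accuracy_report(
    results: dict[str, tuple[np.ndarray, np.ndarray]], model_id: str = ""
) -> AccuracyReport:
    """Accuracy accounting over per-sequence (observed, predicted) pairs.

    Scored positions are those observed as one of the three states and
    predicted as a state; per-sequence accuracies are simple percentages,
    the joint accuracy pools all scored positions, and the 50%/95%
    intervals are quantile ranges of the per-sequence accuracies.
    """
    per_sequence: dict[str, float] = {}
    obs_all, pred_all = [], []
    for sid, (obs, pred) in results.items():
        obs, pred = np.asarray(obs, dtype=object), np.asarray(pred, dtype=object)
        keep = _scored_mask(obs, pred)
        if keep.any():
            per_sequence[sid] = 100.0 * float(np.mean(obs[keep] == pred[keep]))
            obs_all.append(obs[keep])
            pred_all.append(pred[keep])
        else:
            logger.warning("sequence %s has no scorable positions", sid)
    if not obs_all:
        raise ValueError("no scorable positions in any sequence")
    obs_cat = np.concatenate(obs_all)
    pred_cat = np.concatenate(pred_all)
    joint = 100.0 * float(np.mean(obs_cat == pred_cat))
    per_state = {
        s: 100.0 * float(np.mean(pred_cat[obs_cat == s] == s))
        for s in BEHAVIOR_STATES
        if (obs_cat == s).any()
    }
    accs = np.array(list(per_sequence.values()))
    return AccuracyReport(
        model_id=model_id,
        per_sequence=per_sequence,
        joint_overall=joint,
        per_sequence_mean=float(accs.mean()),
        per_state=per_state,
        interval_50=(float(np.quantile(accs, 0.25)), float(np.quantile(accs, 0.75))),
        interval_95=(float(np.quantile(accs, 0.025)), float(np.quantile(accs, 0.975))),
        confusion=confusion_matrix(obs_cat, pred_cat),
        predicted_budget=behavioral_budget(pred_cat).proportions,
        n_scored=int(obs_cat.size),
    )


def loso_evaluate(
    pipeline, sequences: Sequence[TrackSequence], model_id: str = ""
) -> AccuracyReport:
    """Leave-one-sequence-out evaluation of a pipeline.

    Each sequence is predicted by the pipeline fitted to all other
    sequences.  Folds whose training sequences lack one of the three
    states are skipped with a warning.
    """
    sequences = list(sequences)
    if len(sequences) < 2:
        raise ValueError("LOSO needs at least two sequences")
    results: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, held_out in enumerate(sequences):
        train = sequences[:i] + sequences[i + 1 :]
        train_states = set(np.concatenate([t.labels for t in train])) & _STATES
        if train_states != _STATES:
            warnings.warn(
                f"fold {held_out.sequence_id}: training set lacks states "
                f"{sorted(_STATES - train_states)}; fold skipped"
            )
            continue
        pipeline.fit(train)
        scored, pred = pipeline.predict(held_out)
        results[held_out.sequence_id] = (scored.labels, pred)
    if not results:
        raise ValueError("all LOSO folds were skipped")
    mid = model_id or getattr(getattr(pipeline, "spec", None), "model_id", "")
    return accuracy_report(results, model_id=mid)


def confusion_matrix(observed, predicted) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent.

    Rows are observed states, columns predicted states; each row sums to
    100.  Unlabeled/other/unclassifiable positions are dropped first.
    """
    obs = np.asarray(observed, dtype=object)
    pred = np.asarray(predicted, dtype=object)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be aligned")
    keep = _scored_mask(obs, pred)
    if not keep.any():
        raise ValueError("no overlapping scorable positions")
    obs, pred = obs[keep], pred[keep]
    mat = pd.DataFrame(0.0, index=list(BEHAVIOR_STATES), columns=list(BEHAVIOR_STATES))
    for o in BEHAVIOR_STATES:
        row_mask = obs == o
        n_row = int(row_mask.sum())
        if n_row == 0:
            mat.loc[o] = np.nan
            continue
        for p in BEHAVIOR_STATES:
            mat.loc[o, p] = 100.0 * float(np.mean(pred[row_mask] == p))
    mat.index.name = "observed"
    mat.columns.name = "predicted"
    return mat


def behavioral_budget(labels) -> BehavioralBudget:
    """Relative abundance of the three behavioral states."""
    labels = np.asarray(labels, dtype=object)
    labels = labels[np.isin(labels, list(_STATES))]
    if labels.size == 0:
        raise ValueError("no positions labeled with a behavioral state")
    return BehavioralBudget(
        {s: float(np.mean(labels == s)) for s in BEHAVIOR_STATES}
    )


def compare_models(
    accuracies_a: Sequence[float], accuracies_b: Sequence[float]
) -> TTestResult:
    """Paired two-sided t-test on per-sequence accuracy differences."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired accuracy vectors")
    diff = a - b
    df = a.size - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            warnings.warn("zero-variance, zero-mean differences; t = 0, p = 1")
            return TTestResult(0.0, 1.0, df, degenerate=True)
        warnings.warn("zero-variance differences with nonzero mean; test degenerate")
        return TTestResult(float(np.sign(diff.mean()) * np.inf), 0.0, df, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), df)


def summarize_state_kinematics(track: TrackSequence) -> pd.DataFrame:
    """Per-state mean and (0.05, 0.95) quantiles of speed and |turn angle|.

    Speed at position i is the length of the move into i divided by the
    fix interval [m/s]; the turning angle is the absolute direction
    change at i [rad].  States with fewer than two labeled positions are
    omitted with a warning.
    """
    from .metrics import step_lengths, turning_angles

    n = len(track)
    speed = np.full(n, np.nan)
    speed[1:] = step_lengths(track) / track.interval
    angle = turning_angles(track, signed=False)
    rows = []
    for s in BEHAVIOR_STATES:
        mask = (track.labels == s) & np.isfinite(speed)
        if mask.sum() < 2:
            warnings.warn(f"state {s!r} has fewer than 2 positions with kinematics; omitted")
            continue
        sp = speed[mask]
        an = angle[(track.labels == s) & np.isfinite(angle)]
        rows.append(
            {
                "state": s,
                "n": int(mask.sum()),
                "speed_mean": sp.mean(),
                "speed_q05": np.quantile(sp, 0.05),
                "speed_q95": np.quantile(sp, 0.95),
                "angle_mean": an.mean() if an.size else np.nan,
                "angle_q05": np.quantile(an, 0.05) if an.size else np.nan,
                "angle_q95": np.quantile(an, 0.95) if an.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("state")
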