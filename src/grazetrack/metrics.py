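"""Multi-scale movement metrics and per-position feature tables.

Two basic metrics are derived from a planar track: the step distance
between subsequent fixes and the turning angle at each fix.  Because a
grazing animal's activities last minutes rather than seconds, both are
extended over multiple time steps: cumulative (path) and linear
(straight-line) distances are computed backward and forward of each
position at every multiple of the fix interval up to a horizon (default
5 min), averages of the backward/forward pair are added per span and
distance type, and turning angles are averaged over centered windows of
3, 5, 7, ... positions.

At a 20 s fix interval with a 300 s horizon this catalog contains exactly
87 distance metrics and 15 turning-angle metrics; rebuilt at 60 s it
contains 27 and 5.  At span 1 the linear and cumulative distances (and
their means) coincide by definition; those three duplicates are removed
from the catalog, which is the only reading that reconciles the raw
enumeration of 90 distance specs with the 87 distinct predictors.

Boundary positions whose span would reach past the ends of the track get
missing values; rows with missing predictors are excluded from training
and reported as unclassifiable at prediction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .tracks import Position, TrackSequence

__all__ = [
    "MetricSpec",
    "metric_catalog",
    "step_distance",
    "turning_angle",
    "step_lengths",
    "turning_angles",
    "cumulative_distance",
    "linear_distance",
    "mean_distance",
    "mean_turning_angle",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
    "LABEL_COLUMN",
    "BASIC_PREDICTORS",
]

Family = Literal[
    "cumulative_distance",
    "linear_distance",
    "mean_cumulative",
    "mean_linear",
    "turning_angle",
    "mean_turning_angle",
]
Direction = Literal["backward", "forward", "symmetric"]

DISTANCE_FAMILIES = ("cumulative_distance", "linear_distance", "mean_cumulative", "mean_linear")
ANGLE_FAMILIES = ("turning_angle", "mean_turning_angle")

#: Name of the label column appended to feature tables.
LABEL_COLUMN = "label"

#: Predictor set of the basic random-walk models: distance to the preceding
#: position plus the (absolute) turning angle at the position.
BASIC_PREDICTORS = ("cumdist_bwd_1", "angle")


@dataclass(frozen=True)
class MetricSpec:
    """One movement metric: family, direction and span in Δ-steps.

    ``span_steps`` counts fix intervals for distance metrics and the
    window size in positions (odd) for turning-angle means.  ``name`` is
    the canonical column identifier, e.g. ``cumdist_bwd_3`` (cumulative
    distance over the 3 steps before the position), ``lindist_fwd_15``,
    ``meanangle_w7``.
    """

    family: Family
    direction: Direction
    span_steps: int
    name: str

    def __post_init__(self):
        if self.span_steps < 1:
            raise ValueError("span_steps must be >= 1")
        if self.family == "mean_turning_angle" and self.span_steps % 2 == 0:
            raise ValueError("turning-angle windows must be odd")


_DIR_TAG = {"backward": "bwd", "forward": "fwd"}


def _make_spec(family: Family, direction: Direction, span: int) -> MetricSpec:
    if family == "cumulative_distance":
        name = f"cumdist_{_DIR_TAG[direction]}_{span}"
    elif family == "linear_distance":
        name = f"lindist_{_DIR_TAG[direction]}_{span}"
    elif family == "mean_cumulative":
        name = f"meancumdist_{span}"
    elif family == "mean_linear":
        name = f"meanlindist_{span}"
    elif family == "turning_angle":
        name = "angle"
    else:
        name = f"meanangle_w{span}"
    return MetricSpec(family, direction, span, name)


def metric_catalog(interval: float, horizon: float = 300.0, *, dedup: bool = True) -> list[MetricSpec]:
    """Enumerate the full multi-scale metric catalog for a fix interval.

    Parameters
    ----------
    interval : float
        Fix interval Δ in seconds.
    horizon : float
        Temporal reach of the metrics on each side of a position [s];
        must be a positive multiple of Δ.  H = horizon/Δ spans are built.
    dedup : bool
        Remove the three span-1 definitional duplicates (backward linear ≡
        backward cumulative, forward linear ≡ forward cumulative, mean
        linear ≡ mean cumulative).  ``dedup=False`` returns the raw
        enumeration (6·H distance specs).

    Returns
    -------
    list of MetricSpec
        Distance specs first, then the raw turning angle and the centered
        angle-mean windows 3, 5, ..., 2H−1.
    """
    h = horizon / interval
    if horizon <= 0 or abs(h - round(h)) > 1e-9:
        raise ValueError(f"horizon ({horizon}s) must be a positive multiple of the interval ({interval}s)")
    h = int(round(h))
    specs: list[MetricSpec] = []
    for m in range(1, h + 1):
        for direction in ("backward", "forward"):
            specs.append(_make_spec("cumulative_distance", direction, m))
            if not (dedup and m == 1):
                specs.append(_make_spec("linear_distance", direction, m))
        specs.append(_make_spec("mean_cumulative", "symmetric", m))
        if not (dedup and m == 1):
            specs.append(_make_spec("mean_linear", "symmetric", m))
    specs.append(_make_spec("turning_angle", "symmetric", 1))
    for w in range(3, 2 * h, 2):
        specs.append(_make_spec("mean_turning_angle", "symmetric", w))
    return specs


# ---------------------------------------------------------------------------
# basic per-position metrics


def step_distance(a: Position | tuple, b: Position | tuple) -> float:
    """Euclidean distance [m] between two planar positions."""
    return math.hypot(b[-2] - a[-2], b[-1] - a[-1])


def turning_angle(p_prev, p_cur, p_next) -> float:
    """Signed turning angle [rad] at ``p_cur``, in (−π, π].

    Angle between the incoming step vector (p_prev→p_cur) and the
    outgoing one (p_cur→p_next); positive = left turn.  A zero-length
    step leaves the angle undefined (NaN).
    """
    v1x, v1y = p_cur[-2] - p_prev[-2], p_cur[-1] - p_prev[-1]
    v2x, v2y = p_next[-2] - p_cur[-2], p_next[-1] - p_cur[-1]
    if (v1x == 0 and v1y == 0) or (v2x == 0 and v2y == 0):
        return math.nan
    ang = math.atan2(v1x * v2y - v1y * v2x, v1x * v2x + v1y * v2y)
    return math.pi if ang == -math.pi else ang


def step_lengths(track: TrackSequence) -> np.ndarray:
    """Distances of the n−1 moves; element i is the move into position i+1."""
    return np.hypot(np.diff(track.x), np.diff(track.y))


def turning_angles(track: TrackSequence, *, signed: bool = True) -> np.ndarray:
    """Per-position turning angles, length n; NaN at both ends.

    Element i is the direction change at position i between the moves
    i−1→i and i→i+1.  Zero-length moves yield NaN.
    """
    dx, dy = np.diff(track.x), np.diff(track.y)
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    zero = ((dx[:-1] == 0) & (dy[:-1] == 0)) | ((dx[1:] == 0) & (dy[1:] == 0))
    ang = np.arctan2(cross, dot)
    ang[ang == -np.pi] = np.pi
    ang[zero] = np.nan
    out = np.full(len(track), np.nan)
    out[1:-1] = ang
    return out if signed else np.abs(out)


# ---------------------------------------------------------------------------
# vectorized per-track metric columns

def _distance_column(track: TrackSequence, family: str, direction: str, m: int) -> np.ndarray:
    n = len(track)
    out = np.full(n, np.nan)
    if family == "cumulative_distance":
        cs = np.concatenate([[0.0], np.cumsum(step_lengths(track))])  # path length to position i
        if direction == "backward":
            if m < n:
                out[m:] = cs[m:] - cs[:-m]
        else:
            if m < n:
                out[: n - m] = cs[m:] - cs[:-m]
    elif family == "linear_distance":
        if m < n:
            d = np.hypot(track.x[m:] - track.x[:-m], track.y[m:] - track.y[:-m])
            if direction == "backward":
                out[m:] = d
            else:
                out[: n - m] = d
    else:
        base = "cumulative_distance" if family == "mean_cumulative" else "linear_distance"
        bwd = _distance_column(track, base, "backward", m)
        fwd = _distance_column(track, base, "forward", m)
        out = 0.5 * (bwd + fwd)
    return out


def _mean_angle_column(track: TrackSequence, w: int) -> np.ndarray:
    absang = turning_angles(track, signed=False)
    if w == 1:
        return absang
    s = pd.Series(absang)
    return s.rolling(window=w, center=True, min_periods=w).mean().to_numpy()


def metric_column(track: TrackSequence, spec: MetricSpec) -> np.ndarray:
    """Evaluate one metric for every position of a track (NaN = missing)."""
    if spec.family in ("cumulative_distance", "linear_distance", "mean_cumulative", "mean_linear"):
        return _distance_column(track, spec.family, spec.direction, spec.span_steps)
    if spec.family == "turning_angle":
        return turning_angles(track, signed=False)
    return _mean_angle_column(track, spec.span_steps)


# scalar wrappers -----------------------------------------------------------

def cumulative_distance(track: TrackSequence, i: int, span: int, direction: Direction) -> float:
    """Sum of the ``span`` consecutive step distances ending (backward) or
    starting (forward) at position ``i``; NaN if neighbors are missing."""
    return float(_distance_column(track, "cumulative_distance", direction, span)[i])


def linear_distance(track: TrackSequence, i: int, span: int, direction: Direction) -> float:
    """Straight-line distance between position ``i`` and the position
    ``span`` steps away in the given direction; NaN if out of range."""
    return float(_distance_column(track, "linear_distance", direction, span)[i])


def mean_distance(track: TrackSequence, i: int, span: int, family: str = "cumulative") -> float:
    """Mean of the backward and forward distance at the same span; NaN if
    either side is missing."""
    fam = "mean_cumulative" if family.startswith("cum") else "mean_linear"
    return float(_distance_column(track, fam, "symmetric", span)[i])


def mean_turning_angle(track: TrackSequence, i: int, window: int) -> float:
    """Mean absolute turning angle over ``window`` positions centered at
    ``i``; NaN unless the full window of defined angles is available."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    return float(_mean_angle_column(track, window)[i])


# ---------------------------------------------------------------------------
# feature tables


def build_feature_table(track: TrackSequence, catalog: Iterable[MetricSpec]) -> pd.DataFrame:
    """Per-position predictor matrix for one track.

    One row per position, one column per catalog metric (canonical
    names), plus the behavior label column.  Positions whose span
    exceeds the available neighbors carry NaN in the affected columns.
    """
    catalog = list(catalog)
    data = {spec.name: metric_column(track, spec) for spec in catalog}
    table = pd.DataFrame(data)
    table[LABEL_COLUMN] = track.labels
    table.index.name = "position"
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as tab-separated text with a header line."""
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table.index.name = "position"
    return table
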