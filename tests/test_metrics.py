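"""Movement metrics: basic distances/angles, the multi-scale catalog, and
feature tables, against naive brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from grazetrack import TrackSequence, build_feature_table, metric_catalog
from grazetrack.metrics import (
    cumulative_distance,
    linear_distance,
    mean_distance,
    mean_turning_angle,
    metric_column,
    step_distance,
    turning_angle,
    turning_angles,
)


class TestStepDistance:
    def test_identical_points(self):
        assert step_distance((0.0, 0.0), (0.0, 0.0)) == 0.0

    def test_pythagoras(self):
        assert step_distance((0.0, 0.0), (3.0, 4.0)) == pytest.approx(5.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.normal(size=2), rng.normal(size=2)
            assert step_distance(a, b) == pytest.approx(step_distance(b, a))


class TestTurningAngle:
    def test_collinear_continuation(self):
        assert turning_angle((0, 0), (1, 0), (2, 0)) == 0.0

    def test_reversal(self):
        assert abs(turning_angle((0, 0), (1, 0), (0, 0))) == pytest.approx(math.pi)

    def test_left_turn_positive(self):
        assert turning_angle((0, 0), (1, 0), (1, 1)) == pytest.approx(math.pi / 2)

    def test_zero_step_undefined(self):
        assert math.isnan(turning_angle((0, 0), (0, 0), (1, 1)))


def _straight(n=10, step=5.0):
    return TrackSequence("s", 20.0, 20.0 * np.arange(n), step * np.arange(n), np.zeros(n))


class TestDistanceMetrics:
    def test_backward_span1_is_step_distance(self, random_track):
        for i in range(1, len(random_track)):
            expected = math.hypot(
                random_track.x[i] - random_track.x[i - 1],
                random_track.y[i] - random_track.y[i - 1],
            )
            assert cumulative_distance(random_track, i, 1, "backward") == pytest.approx(expected)

    def test_straight_line_arithmetic(self):
        t = _straight()
        assert cumulative_distance(t, 5, 3, "backward") == pytest.approx(15.0)
        assert linear_distance(t, 5, 3, "forward") == pytest.approx(15.0)

    def test_closed_loop_linear_zero(self):
        x = np.array([0, 1, 1, 0, 0, 1], dtype=float)
        y = np.array([0, 0, 1, 1, 0, 0], dtype=float)
        t = TrackSequence("sq", 20.0, 20.0 * np.arange(6), x, y)
        assert linear_distance(t, 4, 4, "backward") == pytest.approx(0.0)

    def test_linear_equals_cumulative_at_span1(self, random_track):
        raw = {s.name: s for s in metric_catalog(20, 300, dedup=False)}
        lin = metric_column(random_track, raw["lindist_bwd_1"])
        cum = metric_column(random_track, raw["cumdist_bwd_1"])
        np.testing.assert_allclose(lin, cum)

    def test_triangle_inequality(self, random_track):
        for m in (2, 5, 9):
            for direction in ("backward", "forward"):
                cum = np.array([cumulative_distance(random_track, i, m, direction) for i in range(len(random_track))])
                lin = np.array([linear_distance(random_track, i, m, direction) for i in range(len(random_track))])
                ok = np.isfinite(cum)
                assert np.array_equal(ok, np.isfinite(lin))
                assert (cum[ok] >= lin[ok] - 1e-9).all()

    def test_mean_distance(self):
        # backward step 4 m, forward step 6 m around the middle position
        t = TrackSequence("m", 20.0, [0, 20, 40], [0.0, 4.0, 10.0], [0, 0, 0])
        assert mean_distance(t, 1, 1, "cumulative") == pytest.approx(5.0)

    def test_mean_missing_side(self):
        t = _straight(5)
        assert math.isnan(mean_distance(t, 0, 1, "cumulative"))
        assert math.isnan(mean_distance(t, 4, 1, "linear"))


class TestMeanTurningAngle:
    def test_window_one_is_abs_angle(self, random_track):
        ang = turning_angles(random_track, signed=False)
        for i in (1, 10, 30):
            assert mean_turning_angle(random_track, i, 1) == pytest.approx(ang[i])

    def test_arithmetic_mean(self):
        # turns of +90, +90, 0 degrees at the three interior vertices
        x = np.array([0, 1, 1, 0, -1], dtype=float)
        y = np.array([0, 0, 1, 1, 1], dtype=float)
        t = TrackSequence("w", 20.0, 20.0 * np.arange(5), x, y)
        assert mean_turning_angle(t, 2, 3) == pytest.approx(math.pi / 3)

    def test_collinear_track_zero(self):
        t = _straight(12)
        for w in (1, 3, 5):
            assert mean_turning_angle(t, 6, w) == pytest.approx(0.0)

    def test_incomplete_window_missing(self):
        t = _straight(8)
        assert math.isnan(mean_turning_angle(t, 1, 3))  # window touches position 0
        assert math.isnan(mean_turning_angle(t, 0, 1))

    def test_even_window_rejected(self, random_track):
        with pytest.raises(ValueError):
            mean_turning_angle(random_track, 5, 4)


class TestCatalog:
    def test_counts_by_interval(self):
        for interval, n_dist, n_ang in ((20.0, 87, 15), (60.0, 27, 5)):
            cat = metric_catalog(interval, 300.0)
            dist = [s for s in cat if "angle" not in s.family]
            ang = [s for s in cat if "angle" in s.family]
            assert (len(dist), len(ang)) == (n_dist, n_ang)

    def test_duplicates_removed_are_definitional(self, random_track):
        raw = metric_catalog(20.0, 300.0, dedup=False)
        kept = {s.name for s in metric_catalog(20.0, 300.0)}
        removed = [s for s in raw if s.name not in kept]
        assert len(removed) == 3
        assert {s.span_steps for s in removed} == {1}
        # each removed spec is numerically identical to a kept cumulative twin
        for spec in removed:
            twin_family = "cumulative_distance" if spec.family == "linear_distance" else "mean_cumulative"
            twin = next(s for s in raw if s.family == twin_family and s.direction == spec.direction and s.span_steps == 1)
            np.testing.assert_allclose(
                metric_column(random_track, spec), metric_column(random_track, twin)
            )

    def test_no_other_pair_is_equivalent(self, random_track):
        cat = metric_catalog(20.0, 300.0)
        cols = {s.name: metric_column(random_track, s) for s in cat}
        names = list(cols)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                va, vb = cols[a], cols[b]
                both = np.isfinite(va) & np.isfinite(vb)
                assert not (both.any() and np.allclose(va[both], vb[both])), (a, b)

    def test_bad_horizon(self):
        with pytest.raises(ValueError):
            metric_catalog(20.0, 310.0)


def _naive_feature_value(track, spec, i):
    """Independent per-position re-implementation using plain loops."""
    n = len(track)
    pts = list(zip(track.x, track.y))

    def step(a, b):
        return math.hypot(pts[b][0] - pts[a][0], pts[b][1] - pts[a][1])

    def angle(j):
        if j < 1 or j > n - 2:
            return math.nan
        return abs(turning_angle(pts[j - 1], pts[j], pts[j + 1]))

    m = spec.span_steps
    if spec.family == "cumulative_distance":
        if spec.direction == "backward":
            if i - m < 0:
                return math.nan
            return sum(step(j - 1, j) for j in range(i - m + 1, i + 1))
        if i + m > n - 1:
            return math.nan
        return sum(step(j, j + 1) for j in range(i, i + m))
    if spec.family == "linear_distance":
        j = i - m if spec.direction == "backward" else i + m
        return step(min(i, j), max(i, j)) if 0 <= j <= n - 1 else math.nan
    if spec.family in ("mean_cumulative", "mean_linear"):
        fam = spec.family.replace("mean_", "") + "_distance"
        b = _naive_feature_value(track, type(spec)(fam, "backward", m, "b"), i)
        f = _naive_feature_value(track, type(spec)(fam, "forward", m, "f"), i)
        return 0.5 * (b + f)
    if spec.family == "turning_angle":
        return angle(i)
    half = (m - 1) // 2
    vals = [angle(j) for j in range(i - half, i + half + 1)]
    if any(math.isnan(v) for v in vals):
        return math.nan
    return sum(vals) / m


class TestFeatureTable:
    def test_against_naive_oracle(self, random_track):
        cat = metric_catalog(20.0, 100.0)  # H=5 keeps the oracle affordable
        table = build_feature_table(random_track, cat)
        for spec in cat:
            expected = np.array([_naive_feature_value(random_track, spec, i) for i in range(len(random_track))])
            np.testing.assert_allclose(table[spec.name].to_numpy(), expected, atol=1e-9, err_msg=spec.name)

    def test_constant_speed_interior(self):
        t = _straight(40)
        cat = metric_catalog(20.0, 300.0)
        table = build_feature_table(t, cat)
        i = 20
        for m in (1, 5, 15):
            assert table.loc[i, f"cumdist_bwd_{m}"] == pytest.approx(5.0 * m)

    def test_first_position_backward_missing(self, random_track):
        table = build_feature_table(random_track, metric_catalog(20.0, 300.0))
        backward = [c for c in table.columns if "bwd" in c]
        assert table.loc[0, backward].isna().all()

    def test_label_column_copied(self, sim_track):
        table = build_feature_table(sim_track, metric_catalog(20.0, 300.0))
        assert list(table["label"]) == list(sim_track.labels)

    def test_subsampled_equals_native_60s(self, sim_track):
        from grazetrack import subsample

        thin = subsample(sim_track, 3)
        native = TrackSequence(thin.sequence_id, 60.0, thin.times, thin.x, thin.y, thin.labels)
        cat = metric_catalog(60.0, 300.0)
        pd.testing.assert_frame_equal(build_feature_table(thin, cat), build_feature_table(native, cat))
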