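"""Unit and property tests for per-track migration metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pouchtrack as pt
from pouchtrack import Track
from pouchtrack.errors import InputValidationError
from pouchtrack.tracks import compute_track_metrics, pooled_group_angles

from conftest import random_track


def make_track(points, track_id="t", group="g"):
    t, x, y = zip(*points)
    return Track(track_id, group, np.array(t), np.array(x), np.array(y))


class TestTrackValidation:
    def test_rejects_single_point(self):
        with pytest.raises(InputValidationError, match="at least 2"):
            Track("t", "g", [0.0], [0.0], [0.0])

    def test_rejects_non_monotone_time(self):
        with pytest.raises(InputValidationError, match="strictly increasing"):
            make_track([(0, 0, 0), (10, 1, 1), (5, 2, 2)])

    def test_rejects_non_finite(self):
        with pytest.raises(InputValidationError, match="non-finite"):
            make_track([(0, 0, 0), (10, np.nan, 1)])


class TestPathVelocityPersistence:
    def test_path_length_345_triangle(self):
        assert pt.path_length(make_track([(0, 0, 0), (10, 3, 4)])) == pytest.approx(5.0)

    def test_path_length_two_segments(self):
        tr = make_track([(0, 0, 0), (10, 0, 5), (20, 0, 10)])
        assert pt.path_length(tr) == pytest.approx(10.0)

    def test_velocity_345_triangle(self):
        assert pt.velocity(make_track([(0, 0, 0), (10, 3, 4)])) == pytest.approx(0.5)

    def test_velocity_homogeneous_in_coordinates(self, rng):
        tr = random_track(rng)
        scaled = Track("t", "g", tr.t_min, 2 * tr.x_um, 2 * tr.y_um)
        assert pt.velocity(scaled) == pytest.approx(2 * pt.velocity(tr), rel=1e-12)

    def test_persistence_straight_line(self):
        tr = make_track([(0, 0, 0), (5, 1, 1), (17, 3, 3), (30, 7, 7)])
        assert pt.persistence(tr) == pytest.approx(1.0)

    def test_persistence_closed_loop_is_zero(self):
        square = [(0, 0, 0), (10, 1, 0), (20, 1, 1), (30, 0, 1), (40, 0, 0)]
        assert pt.persistence(make_track(square)) == pytest.approx(0.0)

    def test_persistence_hand_example_five_sevenths(self):
        tr = make_track([(0, 0, 0), (7, 3, 0), (19, 3, 4)])
        assert pt.persistence(tr) == pytest.approx(5 / 7)

    def test_stationary_track_flagged_and_excluded(self, caplog):
        tr = make_track([(0, 1, 1), (10, 1, 1), (20, 1, 1)])
        assert math.isnan(pt.persistence(tr))
        m = compute_track_metrics(tr)
        assert not m.persistence_defined
        summary = pt.summarize_group_metrics(
            [m, compute_track_metrics(random_track(np.random.default_rng(0)))]
        )
        assert summary["g"]["n_persistence_excluded"] == 1
        assert summary["g"]["persistence"]["n"] == 1


class TestDeviationAngles:
    def test_collinear_steps_give_zero(self):
        tr = make_track([(0, 0, 0), (10, 1, 0), (20, 2, 0), (30, 3, 0)])
        assert pt.deviation_angles(tr) == pytest.approx([0.0, 0.0])

    def test_left_turn_is_plus_ninety(self):
        tr = make_track([(0, 0, 0), (10, 1, 0), (20, 1, 1)])
        assert pt.deviation_angles(tr) == pytest.approx([90.0])

    def test_reversal_is_plus_180(self):
        tr = make_track([(0, 0, 0), (10, 1, 0), (20, 0, 0)])
        assert pt.deviation_angles(tr) == pytest.approx([180.0])

    def test_two_points_give_empty(self):
        assert pt.deviation_angles(make_track([(0, 0, 0), (10, 1, 1)])).size == 0

    def test_zero_displacement_triples_skipped_and_counted(self):
        tr = make_track([(0, 0, 0), (10, 1, 0), (20, 1, 0), (30, 1, 1)])
        m = compute_track_metrics(tr)
        assert m.n_valid_steps == 0
        assert m.n_skipped_triples == 2

    def test_matches_atan2_difference_oracle(self, rng):
        """Angles equal the wrapped difference of successive segment bearings."""
        for _ in range(50):
            tr = random_track(rng, n_points=20)
            got = pt.deviation_angles(tr)
            bearing = np.degrees(
                np.arctan2(np.diff(tr.y_um), np.diff(tr.x_um))
            )
            expected = np.diff(bearing)
            expected = (expected + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
            expected[expected == -180.0] = 180.0
            np.testing.assert_allclose(got, expected, atol=1e-9)


class TestRigidMotionInvariance:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-math.pi, math.pi),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
        seed=st.integers(0, 2**16),
    )
    def test_metrics_invariant_under_rotation_translation(self, angle, tx, ty, seed):
        tr = random_track(np.random.default_rng(seed), n_points=12)
        c, s = math.cos(angle), math.sin(angle)
        moved = Track(
            "t", "g", tr.t_min,
            c * tr.x_um - s * tr.y_um + tx,
            s * tr.x_um + c * tr.y_um + ty,
        )
        assert pt.velocity(moved) == pytest.approx(pt.velocity(tr), abs=1e-9)
        assert pt.persistence(moved) == pytest.approx(pt.persistence(tr), abs=1e-9)
        a0, a1 = pt.deviation_angles(tr), pt.deviation_angles(moved)
        diff = (a1 - a0 + 180.0) % 360.0 - 180.0  # wrap-aware comparison
        np.testing.assert_allclose(diff, 0.0, atol=1e-7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(2, 30))
    def test_persistence_bounded_by_triangle_inequality(self, seed, n):
        tr = random_track(np.random.default_rng(seed), n_points=n)
        p = pt.persistence(tr)
        assert 0.0 <= p <= 1.0


class TestFilterCompleteTracks:
    def test_spanning_track_retained(self):
        t = np.arange(0, 370, 10.0)
        tr = Track("t", "g", t, np.zeros_like(t), t.copy())
        kept = pt.filter_complete_tracks([tr], 0, 360)
        assert len(kept) == 1
        assert kept[0].t_min[-1] == 360.0

    def test_truncated_track_dropped(self):
        t = np.arange(0, 210, 10.0)
        tr = Track("t", "g", t, np.zeros_like(t), t.copy())
        assert pt.filter_complete_tracks([tr], 0, 360) == []

    def test_track_with_internal_gap_dropped(self):
        t = np.array([0.0, 10, 20, 50, 60, 100])
        tr = Track("t", "g", t, np.zeros_like(t), t.copy())
        # nominal dt forced to 10: the 30-min gap exceeds 1.5 x 10
        assert pt.filter_complete_tracks([tr], 0, 100, nominal_dt_min=10.0) == []

    def test_empty_input_gives_empty_output(self):
        assert pt.filter_complete_tracks([], 0, 360) == []

    def test_cropping_to_window(self):
        t = np.arange(-20, 400, 10.0)
        tr = Track("t", "g", t, t.copy(), np.zeros_like(t))
        kept = pt.filter_complete_tracks([tr], 0, 360)
        assert kept[0].t_min[0] == 0.0 and kept[0].t_min[-1] == 360.0

    def test_retained_count_matches_span_recount_oracle(self):
        cfg = pt.SimulationConfig("wt", n_cells=100, dropout_prob=0.3, seed=77)
        tracks = pt.simulate_tracks(cfg)
        kept = pt.filter_complete_tracks(tracks, 0, 360)
        expected = sum(
            1 for tr in tracks if tr.t_min[0] <= 0 and tr.t_min[-1] >= 360
        )
        assert 0 < len(kept) < 100
        assert len(kept) == expected


class TestBinAngles:
    def test_all_zero_angles_fill_one_bin(self):
        h = pt.bin_angles(np.zeros(17), 8)
        assert h.total == 17
        # 0 lies on the edge between (-45, 0] and (0, 45]: it closes (-45, 0]
        assert h.counts[3] == 17
        assert (np.delete(h.counts, 3) == 0).all()

    def test_count_conservation(self, rng):
        a = rng.uniform(-179.9, 180.0, 1000)
        assert pt.bin_angles(a, 8).total == 1000

    def test_boundary_goes_to_closing_bin(self):
        h = pt.bin_angles([-135.0, 180.0], 8)
        assert h.counts[0] == 1 and h.counts[-1] == 1

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(InputValidationError, match="outside"):
            pt.bin_angles([-180.0], 8)
        with pytest.raises(InputValidationError, match="outside"):
            pt.bin_angles([200.0], 8)

    def test_bad_bin_count_rejected(self):
        with pytest.raises(InputValidationError, match="n_bins"):
            pt.bin_angles([0.0], 7)

    def test_uniform_angles_pass_chi_square_calibration(self):
        """Binned uniform angles stay below the 0.999 chi-square quantile."""
        from scipy import stats as sps

        crit = sps.chi2.ppf(0.999, 7)
        rng = np.random.default_rng(31)
        below = 0
        n_reps = 100
        for _ in range(n_reps):
            a = rng.uniform(-180.0, 180.0, 10_000)
            a[a == -180.0] = 180.0
            counts = pt.bin_angles(a, 8).counts
            stat = ((counts - 1250.0) ** 2 / 1250.0).sum()
            below += stat < crit
        assert below >= 0.99 * n_reps


class TestGroupSummaries:
    def test_constant_persistence_sem_zero(self):
        ms = [
            pt.TrackMetrics(f"t{i}", "g", 0.5, 1.0, np.empty(0), 0)
            for i in range(3)
        ]
        s = pt.summarize_group_metrics(ms)["g"]["persistence"]
        assert s["mean"] == pytest.approx(1.0) and s["sem"] == pytest.approx(0.0)

    def test_two_values_mean_and_sem(self):
        ms = [
            pt.TrackMetrics("a", "g", 0.1, 0.0, np.empty(0), 0),
            pt.TrackMetrics("b", "g", 0.3, 1.0, np.empty(0), 0),
        ]
        s = pt.summarize_group_metrics(ms)["g"]["persistence"]
        assert s["mean"] == pytest.approx(0.5) and s["sem"] == pytest.approx(0.5)

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.uniform(0, 1, 17)
        ms = [
            pt.TrackMetrics(f"t{i}", "g", v, v, np.empty(0), 0)
            for i, v in enumerate(vals)
        ]
        s = pt.summarize_group_metrics(ms)["g"]["velocity"]
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        assert s["mean"] == pytest.approx(mean, rel=1e-12)
        assert s["sem"] == pytest.approx(sd / math.sqrt(len(vals)), rel=1e-12)

    def test_single_track_group_flagged(self):
        ms = [pt.TrackMetrics("a", "g", 0.1, 0.5, np.empty(0), 0)]
        s = pt.summarize_group_metrics(ms)["g"]
        assert not s["sem_defined"]
        assert math.isnan(s["velocity"]["sem"])

    def test_absolute_mode_merges_turn_signs(self):
        h = pt.bin_angles([-90.0, 90.0, 10.0, -10.0, 0.0], 4, absolute=True)
        assert h.bin_edges_deg[0] == 0.0 and h.bin_edges_deg[-1] == 180.0
        assert list(h.counts) == [3, 2, 0, 0]

    def test_per_cell_mean_pooling_yields_one_angle_per_track(self):
        cfg = pt.SimulationConfig("wt", n_cells=10, seed=6)
        ms = [compute_track_metrics(t) for t in pt.simulate_tracks(cfg)]
        per_cell = pooled_group_angles(ms, per_cell_mean=True)["wt"]
        assert per_cell.size == 10
        assert np.all((per_cell > -180.0) & (per_cell <= 180.0))
        # the circular mean of a straight track's angles is 0
        straight = compute_track_metrics(
            make_track([(0, 0, 0), (10, 1, 0), (20, 2, 0), (30, 3, 0)])
        )
        assert pooled_group_angles([straight], per_cell_mean=True)["g"] == (
            pytest.approx([0.0])
        )

    def test_angle_conservation_after_pooling(self):
        cfg = pt.SimulationConfig("wt", n_cells=20, seed=5)
        ms = [compute_track_metrics(t) for t in pt.simulate_tracks(cfg)]
        pooled = pooled_group_angles(ms)["wt"]
        assert pooled.size == sum(m.n_valid_steps for m in ms)
        assert pt.bin_angles(pooled, 8).total == pooled.size
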