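"""Tracking statistics: swimmer filtering, velocity fits, segmentation,
drift, directional runs and spreading bias."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import runtumble as rt
from runtumble.trackstats import (
    Segment,
    Segmentation,
    Trajectory,
    diffusivity_statistic,
    drift_and_bias,
    filter_swimmers,
    local_velocity,
    run_direction_analysis,
    segment_motility,
    spreading_bias,
    spreading_bias_replicates,
    summarize_motility,
)

F = 50.0


def make_track(x, y, tid=0):
    return Trajectory(traj_id=tid, x=np.asarray(x, float),
                      y=np.asarray(y, float), frame_rate=F)


def straight_track(speed=20.0, duration=5.0, heading=0.0, tid=0):
    n = int(duration * F) + 1
    t = np.arange(n) / F
    return make_track(speed * t * math.cos(heading),
                      speed * t * math.sin(heading), tid)


class TestSwimmerFilter:
    def test_straight_swimmer_statistic(self):
        """A 20 µm/s straight 5 s sweep has positional variance rate far
        above the 0.61 µm²/s cutoff (uniform-sweep variance L²/12 / T)."""
        tr = straight_track(20.0, 5.0)
        expected = (20.0 * 5.0) ** 2 / 12.0 / 5.0
        assert diffusivity_statistic(tr) == pytest.approx(expected, rel=0.02)
        part = filter_swimmers([tr])
        assert part.swimmers == [tr]

    def test_stationary_non_swimmer(self):
        tr = make_track(np.full(251, 3.0), np.full(251, 4.0))
        assert diffusivity_statistic(tr) == 0.0
        part = filter_swimmers([tr])
        assert part.non_swimmers == [tr]

    def test_short_track_discarded(self):
        tr = straight_track(20.0, 0.8)  # 0.8 s at 50 fps
        part = filter_swimmers([tr])
        assert part.discarded == [tr]

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_track([0.0, np.nan, 2.0], [0.0, 1.0, 2.0])


class TestLocalVelocity:
    def test_exact_linear_fit(self):
        tr = make_track(2.0 * np.arange(100) / F, np.zeros(100))
        ann = local_velocity(tr)
        np.testing.assert_allclose(ann.speed, 2.0, rtol=1e-12)
        np.testing.assert_allclose(ann.vx, 2.0, rtol=1e-12)
        np.testing.assert_allclose(ann.vy, 0.0, atol=1e-12)

    def test_stationary_track_zero(self):
        tr = make_track(np.zeros(50), np.zeros(50))
        ann = local_velocity(tr)
        assert np.all(ann.speed == 0.0)
        assert np.all(ann.mean_step == 0.0)

    def test_too_short_raises(self):
        tr = make_track(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError, match="shorter"):
            local_velocity(tr)

    def test_matches_per_window_least_squares_oracle(self, rng):
        """Vectorised sliding fit equals an independent per-window polyfit
        to numerical precision on random tracks (including circular ones)."""
        for rep in range(20):
            n = int(rng.integers(12, 120))
            if rep == 0:  # circular path: chord-averaged speed below R*omega
                t = np.arange(n) / F
                x, y = 30 * np.cos(3 * t), 30 * np.sin(3 * t)
            else:
                x = np.cumsum(rng.normal(0, 1, n))
                y = np.cumsum(rng.normal(0, 1, n))
            tr = make_track(x, y, tid=rep)
            ann = local_velocity(tr)
            for i in range(n):
                s = int(np.clip(i - 4, 0, n - 10))
                tt = np.arange(s, s + 10) / F
                cx = np.polyfit(tt, x[s:s + 10], 1)[0]
                cy = np.polyfit(tt, y[s:s + 10], 1)[0]
                assert ann.vx[i] == pytest.approx(cx, rel=1e-10, abs=1e-10)
                assert ann.vy[i] == pytest.approx(cy, rel=1e-10, abs=1e-10)
            if rep == 0:
                assert np.all(ann.speed[5:-5] < 90.0)  # R*omega = 90 µm/s


class TestSegmentation:
    def test_constant_velocity_single_run(self):
        tr = straight_track(25.0, 2.0)
        seg = segment_motility(local_velocity(tr), noise_sigma2=0.0)
        interior = seg.ballisticity[5:-5]
        np.testing.assert_allclose(interior, 1.0, rtol=1e-9)
        assert all(s.kind == "run" for s in seg.segments)
        assert len(seg.segments) == 1

    def test_reversal_is_tumble(self):
        """An instantaneous 180-degree reversal at constant speed gives
        near-zero fitted velocity in windows spanning it."""
        n_half = 50
        fwd = 25.0 * np.arange(n_half) / F
        back = fwd[-1] - 25.0 * np.arange(1, n_half) / F
        tr = make_track(np.concatenate([fwd, back]), np.zeros(2 * n_half - 1))
        seg = segment_motility(local_velocity(tr), noise_sigma2=0.0)
        assert not seg.is_run[n_half - 1]
        assert any(s.kind == "tumble" for s in seg.segments)

    def test_run_pause_run_boundaries(self, rng):
        """A constructed run/pause/run track is labelled with boundaries
        within +-2 frames of the truth."""
        run1 = int(1.0 * F)
        pause = int(0.3 * F)
        x = np.concatenate([
            25.0 * np.arange(run1) / F,
            np.full(pause, 25.0 * (run1 - 1) / F),
            25.0 * (run1 - 1) / F + 25.0 * np.arange(1, run1) / F,
        ])
        y = rng.normal(0, 0.05, x.size)  # slight jitter in the pause
        tr = make_track(x, y)
        seg = segment_motility(local_velocity(tr), noise_sigma2=0.0)
        tumble_frames = np.flatnonzero(~seg.is_run)
        assert tumble_frames.size > 0
        assert abs(tumble_frames.min() - run1) <= 2
        assert abs(tumble_frames.max() - (run1 + pause - 1)) <= 2

    def test_partition_property(self, rng):
        """Every frame gets exactly one label; segment durations sum to the
        trajectory duration."""
        for rep in range(5):
            n = int(rng.integers(15, 200))
            tr = make_track(np.cumsum(rng.normal(0, 0.5, n)),
                            np.cumsum(rng.normal(0, 0.5, n)), tid=rep)
            seg = segment_motility(local_velocity(tr))
            total = sum(s.duration for s in seg.segments)
            assert total == pytest.approx(tr.duration, abs=1e-9)
            covered = sum(s.n_frames for s in seg.segments)
            assert covered == n


class TestSummaries:
    def _fake_segmentation(self, bias, duration, tid):
        n = int(duration * F) + 1
        tr = straight_track(25.0, duration, tid=tid)
        is_run = np.ones(n, dtype=bool)
        is_run[: int(round(bias * (n - 1)))] = False  # tumble dwell fraction
        return Segmentation(traj=tr, ballisticity=np.ones(n), is_run=is_run,
                            segments=[], noise_sigma2_used=0.0,
                            speed=np.full(n, 25.0))

    def test_all_run_bias_zero(self):
        seg = self._fake_segmentation(0.0, 2.0, 0)
        assert seg.tumbling_bias == 0.0

    def test_pooled_bias_duration_weighting(self):
        """Pooled bias (0.1 over 10 s) + (0.4 over 2 s) = 0.15."""
        segs = [self._fake_segmentation(0.1, 10.0, 0),
                self._fake_segmentation(0.4, 2.0, 1)]
        summary = summarize_motility(segs)
        assert summary.tumbling_bias == pytest.approx(0.15, abs=1e-6)
        np.testing.assert_allclose(summary.per_traj_bias, [0.1, 0.4], atol=1e-6)

    def test_mean_run_speed(self):
        segs = [self._fake_segmentation(0.0, 2.0, 0)]
        assert summarize_motility(segs).mean_run_speed == pytest.approx(25.0)


class TestDrift:
    def test_mirrored_ensemble_zero(self, rng):
        tracks = []
        for i in range(10):
            y = np.cumsum(rng.normal(0.3, 1.0, 60))
            x = np.cumsum(rng.normal(0, 1.0, 60))
            tracks.append(make_track(x, y, tid=2 * i))
            tracks.append(make_track(x, -y, tid=2 * i + 1))
        est = drift_and_bias(tracks)
        assert est.v_chem == pytest.approx(0.0, abs=1e-12)

    def test_chemotaxis_bias_ratio(self):
        tr = make_track(np.zeros(101), 10.0 * np.arange(101) / F)
        est = drift_and_bias([tr, tr], mean_run_speed=25.0)
        assert est.v_chem == pytest.approx(10.0)
        assert est.chemotaxis_bias == pytest.approx(0.4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            drift_and_bias([])


class TestRunDirections:
    def _run(self, dx, dy, n_frames=10):
        return Segment(traj_id=0, kind="run", start=0, end=n_frames - 1,
                       n_frames=n_frames, duration=n_frames / F, dx=dx, dy=dy)

    def test_classification(self):
        res = run_direction_analysis([
            self._run(0.0, 5.0),      # alpha = 0 -> up
            self._run(0.0, -5.0),     # alpha = pi -> down
            self._run(5.0, 5.0),      # alpha = pi/4 -> transverse (boundary)
            self._run(5.0, 0.0),      # alpha = pi/2 -> transverse
        ])
        assert res.up_durations.size == 1
        assert res.down_durations.size == 1
        assert res.transverse_durations.size == 2

    def test_short_runs_removed(self):
        res = run_direction_analysis([self._run(0.0, 5.0, n_frames=4)])
        assert res.up_durations.size == 0
        assert res.transverse_durations.size == 0

    def test_zero_displacement_flagged_transverse(self):
        res = run_direction_analysis([self._run(0.0, 0.0)])
        assert res.n_zero_displacement == 1
        assert res.transverse_durations.size == 1

    def test_tumbles_ignored(self):
        seg = Segment(traj_id=0, kind="tumble", start=0, end=9, n_frames=10,
                      duration=0.2, dx=0.0, dy=5.0)
        res = run_direction_analysis([seg])
        assert res.up_durations.size == 0


class TestSpreadingBias:
    def test_ratio(self):
        assert spreading_bias(2.0, 1.0) == 2.0
        assert spreading_bias(3.0, 3.0) == 1.0

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            spreading_bias(1.0, 0.0)

    def test_degenerate_replicates_cannot_reject(self):
        mean, sem, p = spreading_bias_replicates([1.0, 1.0, 1.0])
        assert mean == 1.0 and sem == 0.0 and p == 1.0

    def test_biased_replicates_significant(self):
        mean, sem, p = spreading_bias_replicates([1.5, 1.6, 1.4, 1.55])
        assert mean > 1.0 and p < 0.01
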