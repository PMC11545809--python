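"""Metrics: frame/stage aggregates, track burst features, rate recovery."""

import math

import numpy as np
import pytest

from burstquant import (TrackingParams, dispersion_stats,
                        estimate_switching_rates, frame_metrics, link_frames,
                        simulate_telegraph, stage_metrics, track_features,
                        track_features_table)
from burstquant.detection import DotObservation


def dot(r=10.0, c=10.0, frame=0, area=4, bright=100.0):
    return DotObservation(frame=frame, centroid=(r, c), area_px=area,
                          mean_brightness=bright, stage_label="nc14")


def presence_track(frames, track_id=0):
    obs = [dot(frame=f) for f in sorted(frames)]
    from burstquant.tracking import Track
    return Track(track_id=track_id, observations=obs)


class TestFrameMetrics:
    def test_arithmetic(self):
        fm = frame_metrics([[dot(area=4, bright=100.0), dot(area=6, bright=200.0)]])
        f = fm[0]
        assert (f.n_dots, f.mean_size_px, f.total_size_px, f.mean_brightness) == \
            (2, 5.0, 10, 150.0)

    def test_empty_frame(self):
        f = frame_metrics([[]])[0]
        assert f.n_dots == 0 and f.total_size_px == 0
        assert math.isnan(f.mean_size_px) and math.isnan(f.mean_brightness)

    def test_conservation_against_tracks(self, rng):
        frames = []
        for t in range(30):
            frames.append([dot(r=rng.uniform(0, 90), c=rng.uniform(0, 90), frame=t)
                           for _ in range(rng.integers(0, 4))])
        fm = frame_metrics(frames)
        tracks = link_frames(frames, TrackingParams())
        assert sum(f.n_dots for f in fm) == \
            sum(len(t.observations) for t in tracks)
        assert sum(f.total_size_px for f in fm) == \
            sum(o.area_px for t in tracks for o in t.observations)


class TestStageMetrics:
    def _frames_from_counts(self, counts):
        frames = []
        for t, n in enumerate(counts):
            frames.append([dot(r=10 * i, c=10 * i, frame=t, area=2, bright=100.0)
                           for i in range(n)])
        return frames

    def test_hand_evaluated_example(self):
        """n_dots [0,1,3,2,3] at 1 s cadence: first dot at 1 s, first (w=1)
        peak at 2 s, saturation at 2 s, max 3."""
        frames = self._frames_from_counts([0, 1, 3, 2, 3])
        fm = frame_metrics(frames)
        tracks = link_frames(frames, TrackingParams())
        sm = stage_metrics(fm, tracks, frame_interval_s=1.0, smooth_w=1)
        assert sm.t_first_dot_s == 1.0
        assert sm.t_first_peak_s == 2.0
        assert sm.t_all_dots_s == 2.0
        assert sm.max_n_dots == 3

    def test_monotone_series_peak_equals_saturation(self):
        frames = self._frames_from_counts([0, 1, 2, 3, 4])
        fm = frame_metrics(frames)
        sm = stage_metrics(fm, [], frame_interval_s=2.0, smooth_w=1)
        assert sm.t_first_peak_s == sm.t_all_dots_s == 8.0

    def test_full_init_window_covers_stage(self):
        frames = self._frames_from_counts([0, 2, 1, 2, 2, 1])
        fm = frame_metrics(frames)
        tracks = link_frames(frames, TrackingParams())
        sm = stage_metrics(fm, tracks, 1.0, init_window_frac=1.0)
        assert sm.init_total_pixels == sum(f.total_size_px for f in fm)
        assert sm.init_active_nuclei == len(tracks)

    def test_zero_dot_stage(self):
        sm = stage_metrics(frame_metrics([[], [], []]), [], 1.0)
        assert sm.max_n_dots == 0
        assert math.isnan(sm.t_first_dot_s)

    def test_peak_sd_is_sd_of_track_maxima(self):
        tracks = []
        for tid, peaks in enumerate([[50.0, 80.0], [120.0], [90.0, 100.0]]):
            obs = [dot(frame=f, bright=b) for f, b in enumerate(peaks)]
            from burstquant.tracking import Track
            tracks.append(Track(track_id=tid, observations=obs))
        fm = frame_metrics([[dot()]])
        sm = stage_metrics(fm, tracks, 1.0)
        assert sm.intensity_peak_sd == pytest.approx(np.std([80, 120, 100], ddof=1))


class TestTrackFeatures:
    def test_run_length_encoding_by_hand(self):
        """Present frames {10..13, 16..20}: 2 bursts of 4 and 5 frames,
        one 2-frame gap, 2 transitions."""
        tf = track_features(presence_track(list(range(10, 14)) +
                                           list(range(16, 21))), 1.77)
        assert tf.n_bursts == 2
        assert tf.on_run_durations_s == pytest.approx([4 * 1.77, 5 * 1.77])
        assert tf.off_gap_durations_s == pytest.approx([2 * 1.77])
        assert tf.n_transitions == 2
        assert tf.start_time_s == pytest.approx(10 * 1.77)

    def test_always_on_track(self):
        tf = track_features(presence_track(range(8)), 1.0)
        assert tf.n_bursts == 1 and tf.n_transitions == 0
        assert tf.off_gap_durations_s == []

    def test_table_schema(self):
        table = track_features_table([presence_track([0, 1, 5], 0),
                                      presence_track([2], 1)], 1.0)
        assert list(table.track_id) == [0, 1]
        assert list(table.n_bursts) == [2, 1]
        assert math.isnan(table.mean_off_gap_s[1])


class TestDispersion:
    def test_formula(self):
        sd, sem, n = dispersion_stats([2.0, 4.0, 6.0])
        assert sd == pytest.approx(2.0)
        assert sem == pytest.approx(2.0 / math.sqrt(3))
        assert n == 3

    def test_constant_values(self):
        sd, sem, _ = dispersion_stats([5.0] * 10)
        assert sd == 0.0 and sem == 0.0

    def test_single_value_flagged(self):
        sd, sem, n = dispersion_stats([3.0])
        assert math.isnan(sd) and math.isnan(sem) and n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dispersion_stats([])


class TestRateRecovery:
    def test_switching_rate_estimator_consistent(self, sim_config_factory):
        """The sampled-chain inversion recovers k_on/k_off from discretized
        state sequences despite sub-frame runs being invisible."""
        cfg = sim_config_factory(k_on=0.03, k_off=0.06, frame_interval_s=1.77,
                                 n_frames_per_stage=3000, seed=17)
        truth = simulate_telegraph(cfg, nucleus_count=10)
        est = estimate_switching_rates(truth.states, cfg.frame_interval_s)
        assert est["mean_on_s"] == pytest.approx(1 / 0.06, rel=0.15)
        assert est["mean_off_s"] == pytest.approx(1 / 0.03, rel=0.15)

    def test_presence_run_mean_recovers_truth_when_runs_long(self,
                                                             sim_config_factory):
        """With dwell times much longer than the frame interval the naive
        mean of presence-run durations matches the realized ground-truth
        mean ON duration within 2 SE."""
        cfg = sim_config_factory(k_on=0.02, k_off=0.01, frame_interval_s=1.0,
                                 n_frames_per_stage=20_000, seed=23)
        truth = simulate_telegraph(cfg, nucleus_count=5)
        durations = []
        for s in truth.states:
            padded = np.diff(np.concatenate([[0], s.astype(int), [0]]))
            starts, ends = np.where(padded == 1)[0], np.where(padded == -1)[0]
            durations.extend((ends - starts) * cfg.frame_interval_s)
        durations = np.asarray(durations)
        se = durations.std(ddof=1) / np.sqrt(len(durations))
        assert abs(durations.mean() - 1 / cfg.k_off) < 2 * se + cfg.frame_interval_s

    def test_more_bursts_when_k_off_raised(self, sim_config_factory):
        """Raising k_off shortens bursts and increases bursts per unit time."""
        counts = {}
        for k_off in (0.02, 0.2):
            n_runs = 0
            for seed in range(5):
                cfg = sim_config_factory(k_on=0.05, k_off=k_off,
                                         frame_interval_s=1.0,
                                         n_frames_per_stage=2000, seed=seed)
                truth = simulate_telegraph(cfg, nucleus_count=8)
                for s in truth.states:
                    n_runs += int(np.sum(np.diff(s.astype(int)) == 1))
            counts[k_off] = n_runs
        assert counts[0.2] > counts[0.02]

    def test_rate_estimator_needs_both_states(self):
        with pytest.raises(ValueError):
            estimate_switching_rates([np.ones(50, dtype=bool)], 1.0)
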