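"""Simulator: telegraph kinetics, rendering forward model, fixture I/O."""

import numpy as np
import pytest

from burstquant import (SimConfig, read_fixture, render_movie, simulate_movie,
                        simulate_telegraph, write_fixture)


class TestTelegraphKinetics:
    def test_absorbing_off_when_k_on_zero(self, sim_config_factory):
        truth = simulate_telegraph(sim_config_factory(k_on=0.0, seed=3))
        assert not truth.states.any()
        assert truth.transcripts.sum() == 0

    def test_always_on_when_k_off_zero_and_started_on(self, sim_config_factory):
        """With no OFF switching the dot stays ON; the nascent-transcript count
        settles at loading_rate * dwell (mean of a Poisson window count)."""
        cfg = sim_config_factory(k_off=0.0, p_init_on=1.0, loading_rate=0.5,
                                 transcript_dwell_s=30.0, frame_interval_s=1.0,
                                 n_frames_per_stage=12_000, seed=7)
        truth = simulate_telegraph(cfg, nucleus_count=1)
        assert truth.states.all()
        counts = truth.transcripts[0, 100:]  # past the dwell-window fill-in
        expected = cfg.loading_rate * cfg.transcript_dwell_s
        se = counts.std(ddof=1) / np.sqrt(len(counts) / 30.0)  # ~dwell-correlated
        assert abs(counts.mean() - expected) < max(3 * se, 0.05 * expected)

    def test_stationary_on_fraction(self, sim_config_factory):
        """Long-run ON occupancy converges to k_on / (k_on + k_off)."""
        cfg = sim_config_factory(k_on=0.04, k_off=0.08, frame_interval_s=2.0,
                                 n_frames_per_stage=4000, seed=11)
        truth = simulate_telegraph(cfg, nucleus_count=20)
        states = truth.states[:, 500:]  # discard burn-in from the OFF start
        frac = states.mean()
        expected = cfg.k_on / (cfg.k_on + cfg.k_off)
        # binomial SE on the effective number of independent dwell periods
        n_eff = states.size * cfg.frame_interval_s * (cfg.k_on * cfg.k_off /
                                                      (cfg.k_on + cfg.k_off))
        se = np.sqrt(expected * (1 - expected) / n_eff)
        assert abs(frac - expected) < 3 * se

    def test_mean_on_run_matches_rate(self, sim_config_factory):
        """Mean ON-run length in frames ~ 1/(k_off dt) when k_off dt << 1."""
        cfg = sim_config_factory(k_on=0.05, k_off=0.01, frame_interval_s=0.5,
                                 n_frames_per_stage=40_000, seed=13)
        truth = simulate_telegraph(cfg, nucleus_count=4)
        runs = []
        for s in truth.states:
            padded = np.diff(np.concatenate([[0], s.astype(int), [0]]))
            starts, ends = np.where(padded == 1)[0], np.where(padded == -1)[0]
            runs.extend(ends - starts)
        runs = np.asarray(runs, dtype=float)
        expected = 1.0 / (cfg.k_off * cfg.frame_interval_s)
        assert abs(runs.mean() - expected) < 3 * runs.std(ddof=1) / np.sqrt(len(runs))

    def test_mitotic_reset_at_stage_boundaries(self, sim_config_factory):
        cfg = sim_config_factory(stage_labels=("nc12", "nc13", "nc14"),
                                 k_on=5.0, k_off=0.0, n_frames_per_stage=20,
                                 frame_interval_s=1.0, seed=2)
        truth = simulate_telegraph(cfg, nucleus_count=6)
        # with k_off=0 every chain turns ON quickly and stays ON within a stage,
        # but the transcript clock restarts from OFF at each boundary
        for _, f0, _ in truth.stage_bounds:
            assert truth.transcripts[:, f0].max() <= truth.transcripts[:, f0 + 15].max()

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            SimConfig(k_on=-0.1)
        with pytest.raises(ValueError):
            SimConfig(k_off=float("nan"))

    def test_same_seed_reproduces_truth(self, sim_config_factory):
        a = simulate_telegraph(sim_config_factory(seed=42))
        b = simulate_telegraph(sim_config_factory(seed=42))
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.transcripts, b.transcripts)
        assert np.array_equal(a.centroids, b.centroids)


class TestRendering:
    def test_no_transcripts_gives_flat_background(self, sim_config_factory):
        cfg = sim_config_factory(k_on=0.0, background_level=17.0)
        movie, _ = simulate_movie(cfg)
        green = movie.pixels[..., 0]
        assert np.all(green == 17)

    def test_peak_pixel_matches_transcript_count(self, sim_config_factory):
        """A 5-transcript dot peaks at ~background + 5*amp (PSF discretization)."""
        cfg = sim_config_factory(loading_rate=0.0, amp_per_transcript=30.0,
                                 background_level=10.0)
        truth = simulate_telegraph(cfg, nucleus_count=1)
        truth.transcripts[:] = 5
        truth.centroids[:] = 64.0  # pixel-centered so the peak is exact
        movie = render_movie(truth, cfg)
        peak = int(movie.pixels[0, 0, :, :, 0].max())
        assert abs(peak - (10 + 5 * 30)) <= 2

    def test_bleach_halves_amplitude_at_halflife(self, sim_config_factory):
        cfg = sim_config_factory(n_frames_per_stage=51, frame_interval_s=1.0,
                                 bleach_halflife_s=50.0, loading_rate=0.0,
                                 background_level=0.0, amp_per_transcript=100.0)
        truth = simulate_telegraph(cfg, nucleus_count=1)
        truth.transcripts[:] = 1
        truth.centroids[:] = 64.0
        movie = render_movie(truth, cfg)
        first = movie.pixels[0, 0, :, :, 0].max()
        last = movie.pixels[50, 0, :, :, 0].max()
        assert abs(last - first / 2) <= 1

    def test_rendering_linear_in_amplitude(self, sim_config_factory):
        kin = dict(k_on=0.1, loading_rate=0.1, transcript_dwell_s=20.0,
                   background_level=5.0, seed=5)  # keeps peaks far below 255
        base = sim_config_factory(amp_per_transcript=8.0, **kin)
        dbl = sim_config_factory(amp_per_transcript=16.0, **kin)
        m1, _ = simulate_movie(base)
        m2, _ = simulate_movie(dbl)
        g1 = m1.pixels[..., 0].astype(int) - 5
        g2 = m2.pixels[..., 0].astype(int) - 5
        # doubling the per-transcript amplitude doubles signal-background
        # (up to the +/-1 rounding of each independently quantized render)
        assert np.all(np.abs(g2 - 2 * g1) <= 3)

    def test_field_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_telegraph(SimConfig(field_size_px=10, n_nuclei_side=5,
                                         psf_sigma_px=2.0))


class TestFixtureIO:
    def test_round_trip_is_lossless(self, sim_config_factory, tmp_path):
        cfg = sim_config_factory(noise_sd=2.0, seed=9)
        movie, truth = simulate_movie(cfg)
        write_fixture(movie, truth, tmp_path)
        movie2, table, partition, cfg2 = read_fixture(tmp_path)
        assert np.array_equal(movie.pixels, movie2.pixels)
        assert len(table) == truth.n_nuclei * truth.n_frames
        assert partition.labels == list(cfg.stage_labels)
        assert cfg2.seed == cfg.seed

    def test_fixed_seed_writes_identical_bytes(self, sim_config_factory, tmp_path):
        cfg = sim_config_factory(noise_sd=1.5, seed=21)
        for d in ("a", "b"):
            movie, truth = simulate_movie(cfg)
            write_fixture(movie, truth, tmp_path / d)
        for name in ("movie.tif", "truth.csv", "stages.csv", "bleach.csv",
                     "config.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
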