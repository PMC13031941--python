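"""Synthetic-scene generator: pulse structure, scheduling, ground truth."""

import numpy as np
import pytest
from scipy.signal import periodogram, stft

import finpulse as fp
from finpulse.scenes import GroundTruthEvent


class TestWhalePulse:
    def test_downsweep_ridge_descends(self):
        pulse = fp.synth_whale_pulse(23.0, 18.0, 1.0, 200.0)
        f, _, Z = stft(pulse, fs=200.0, nperseg=64, noverlap=48)
        mag = np.abs(Z)
        # columns with real energy only (taper kills the edges)
        cols = mag.sum(axis=0) > 0.2 * mag.sum(axis=0).max()
        ridge = f[mag[:, cols].argmax(axis=0)]
        assert np.all(np.diff(ridge) <= 1e-9)

    def test_zero_duration_is_empty(self):
        assert fp.synth_whale_pulse(23.0, 18.0, 0.0, 200.0).size == 0

    def test_energy_concentrated_in_sweep_band(self):
        pulse = fp.synth_whale_pulse(23.0, 18.0, 1.0, 200.0)
        f, P = periodogram(pulse, fs=200.0)
        band = (f >= 18.0) & (f <= 23.0)
        assert P[band].sum() / P.sum() >= 0.9

    @pytest.mark.parametrize("f_start,f_end", [(100.0, 18.0), (23.0, 100.0), (120.0, 110.0)])
    def test_rejects_frequencies_at_or_above_nyquist(self, f_start, f_end):
        with pytest.raises(ValueError):
            fp.synth_whale_pulse(f_start, f_end, 1.0, 200.0)

    def test_rejects_inverted_sweep(self):
        with pytest.raises(ValueError):
            fp.synth_whale_pulse(18.0, 23.0, 1.0, 200.0)


class TestSimulateScene:
    def test_identical_seed_bit_identical(self):
        cfg = fp.SceneConfig(duration_s=120.0, airgun_active=True, seed=9)
        w1, e1 = fp.simulate_scene(cfg)
        w2, e2 = fp.simulate_scene(cfg)
        assert np.array_equal(w1, w2) and e1 == e2

    def test_zero_pulse_rate_gives_no_whale_events(self):
        cfg = fp.SceneConfig(duration_s=300.0, pulse_rate_per_min=0.0, seed=1)
        _, events = fp.simulate_scene(cfg)
        assert all(e.kind != "whale_pulse" for e in events)

    def test_airgun_count_on_fixed_cycle(self):
        cfg = fp.SceneConfig(duration_s=3600.0, airgun_active=True, airgun_interval_s=16.0, seed=2)
        _, events = fp.simulate_scene(cfg)
        shots = [e for e in events if e.kind == "airgun_shot"]
        assert len(shots) == 225  # shots at t = 0, 16, ..., 3584

    def test_mask_durations_lie_in_range(self):
        cfg = fp.SceneConfig(duration_s=1600.0, airgun_active=True, seed=3)
        _, events = fp.simulate_scene(cfg)
        durs = [e.duration_s for e in events if e.kind == "airgun_shot"]
        lo, hi = cfg.airgun_mask_range_s
        assert all(lo <= d <= hi for d in durs)

    def test_mask_duration_mean_matches_target(self):
        # pool shots from many short scenes to reach n = 10,000 draws
        durs = []
        seed = 0
        while len(durs) < 10_000:
            cfg = fp.SceneConfig(
                duration_s=3600.0, airgun_active=True, pulse_rate_per_min=0.0,
                noise_level=0.0, seed=seed,
            )
            _, events = fp.simulate_scene(cfg)
            durs += [e.duration_s for e in events if e.kind == "airgun_shot"]
            seed += 1
        durs = np.array(durs[:10_000])
        se = durs.std(ddof=1) / np.sqrt(durs.size)
        assert abs(durs.mean() - 5.5) <= 3 * se + 0.01

    def test_events_sorted_and_inside_scene(self):
        cfg = fp.SceneConfig(duration_s=600.0, airgun_active=True, seed=4)
        _, events = fp.simulate_scene(cfg)
        onsets = [e.onset_s for e in events]
        assert onsets == sorted(onsets)
        assert all(e.onset_s >= 0 for e in events)


class TestFrameLabels:
    def test_no_whale_events_all_zero(self):
        events = [GroundTruthEvent("airgun_shot", 10.0, 5.0)]
        assert fp.frame_labels(events, 300.0).sum() == 0

    def test_pulse_straddling_boundary_labels_both_frames(self):
        events = [GroundTruthEvent("whale_pulse", 29.5, 1.0)]
        labels = fp.frame_labels(events, 90.0)
        assert list(labels) == [1, 1, 0]

    def test_one_pulse_per_frame_gives_120_positives(self):
        events = [GroundTruthEvent("whale_pulse", 30.0 * k + 10.0, 1.0) for k in range(120)]
        assert fp.frame_labels(events, 3600.0).sum() == 120

    def test_matches_bruteforce_interval_overlap(self):
        rng = np.random.default_rng(12)
        events = [
            GroundTruthEvent("whale_pulse", float(o), float(d))
            for o, d in zip(rng.uniform(0, 590, 40), rng.uniform(0.5, 3.0, 40))
        ]
        labels = fp.frame_labels(events, 600.0, frame_len_s=30.0)
        for k in range(20):
            lo, hi = 30.0 * k, 30.0 * (k + 1)
            expect = any(e.onset_s < hi and e.end_s > lo for e in events)
            assert bool(labels[k]) == expect

    def test_label_conservation(self):
        rng = np.random.default_rng(3)
        events = [
            GroundTruthEvent("whale_pulse", float(o), 1.0) for o in rng.uniform(0, 3500, 60)
        ]
        labels = fp.frame_labels(events, 3600.0)
        assert labels.sum() <= 2 * len(events)  # a pulse can straddle 2 frames
        assert len(events) <= labels.sum() * 120  # capacity bound


class TestCountSimulator:
    def test_poisson_limit_variance_ratio(self):
        beta = {p.name: float(np.log(30.0)) for p in fp.DEFAULT_PERIODS}
        cfg = fp.CountSimConfig(
            beta=beta, sigma_instrument=0.0, sigma_day=0.0, theta=1e6,
            n_instruments=2, seed=0,
        )
        counts = fp.simulate_counts(cfg)["count"].to_numpy()
        ratio = counts.var() / counts.mean()
        assert abs(ratio - 1.0) < 0.1

    def test_marginal_mean_matches_quiet_emm(self):
        beta = {p.name: float(np.log(64.6)) for p in fp.DEFAULT_PERIODS}
        cfg = fp.CountSimConfig(
            beta=beta, sigma_instrument=0.0, sigma_day=0.0, n_instruments=4, seed=1
        )
        counts = fp.simulate_counts(cfg)["count"].to_numpy()[:5000]
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 64.6) <= 3 * se

    def test_nb2_marginal_variance(self):
        mu, theta = 30.0, 6.22
        beta = {p.name: float(np.log(mu)) for p in fp.DEFAULT_PERIODS}
        cfg = fp.CountSimConfig(
            beta=beta, sigma_instrument=0.0, sigma_day=0.0, theta=theta,
            n_instruments=10, seed=2,
        )
        counts = fp.simulate_counts(cfg)["count"].to_numpy()
        expected_var = mu + mu**2 / theta
        assert abs(counts.var() / expected_var - 1.0) < 0.1

    def test_same_seed_identical_tables(self):
        a = fp.simulate_counts(fp.CountSimConfig(seed=5))
        b = fp.simulate_counts(fp.CountSimConfig(seed=5))
        assert a.equals(b)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            fp.CountSimConfig(theta=0.0)
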