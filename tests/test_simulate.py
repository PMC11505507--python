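import numpy as np
import pytest
from scipy import signal as sps

from fogcue.simulate import (
    CHANNEL_GROUPS,
    ConfigurationError,
    Episode,
    SimConfig,
    generate_recording,
    make_activity_schedule,
    synthesize_channels,
)


def fog_share(schedule):
    total = schedule[-1].end
    return sum(ep.n_samples for ep in schedule if ep.kind == "fog") / total


class TestSchedule:
    def test_tiles_interval_contiguously(self):
        sched = make_activity_schedule(SimConfig(duration_s=60, seed=1))
        assert sched[0].start == 0
        assert sched[-1].end == 60 * 40
        for a, b in zip(sched, sched[1:]):
            assert a.end == b.start

    def test_patient_like_prevalence_and_episode_count(self):
        # heaviest observed per-patient load: 15.4% FoG across 13 episodes
        cfg = SimConfig(
            duration_s=350, fog_prevalence=0.154, n_fog_episodes=13, seed=11
        )
        sched = make_activity_schedule(cfg)
        assert sum(ep.kind == "fog" for ep in sched) == 13
        assert abs(fog_share(sched) - 0.154) <= 0.031

    @pytest.mark.parametrize("prevalence,n_ep", [(0.015, 3), (0.047, 6), (0.086, 10), (0.154, 13)])
    def test_prevalence_recovery_over_seeds(self, prevalence, n_ep):
        for seed in range(10):
            cfg = SimConfig(
                duration_s=600,
                fog_prevalence=prevalence,
                n_fog_episodes=n_ep,
                fog_duration_s_range=(1.0, 6.0),
                seed=seed,
            )
            share = fog_share(make_activity_schedule(cfg))
            assert abs(share - prevalence) / prevalence <= 0.2

    def test_fog_episodes_separated_by_at_least_one_second(self):
        cfg = SimConfig(duration_s=200, fog_prevalence=0.15, n_fog_episodes=8, seed=3)
        sched = make_activity_schedule(cfg)
        fog = [ep for ep in sched if ep.kind == "fog"]
        for a, b in zip(fog, fog[1:]):
            assert b.start - a.end >= 40

    def test_zero_episodes_means_zero_fog(self):
        cfg = SimConfig(duration_s=30, fog_prevalence=0.0, n_fog_episodes=0, seed=0)
        sched = make_activity_schedule(cfg)
        assert fog_share(sched) == 0.0
        rec = synthesize_channels(sched, cfg)
        assert rec.labels.sum() == 0

    def test_same_seed_reproduces_schedule(self):
        cfg = SimConfig(duration_s=90, seed=42)
        assert make_activity_schedule(cfg) == make_activity_schedule(cfg)

    def test_infeasible_fog_demand_raises(self):
        with pytest.raises(ConfigurationError):
            make_activity_schedule(
                SimConfig(duration_s=10, fog_prevalence=0.5, n_fog_episodes=9, seed=0)
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(fog_prevalence=0.7)
        with pytest.raises(ConfigurationError):
            SimConfig(activity_mix={"walk": 0.5, "stand": 0.2, "turn": 0.2})
        with pytest.raises(ConfigurationError):
            SimConfig(fog_duration_s_range=(5.0, 2.0))


class TestSignals:
    def test_stand_only_channels_are_zero_mean_noise(self):
        cfg = SimConfig(duration_s=100, fog_prevalence=0.0, n_fog_episodes=0, seed=5)
        sched = [Episode(0, cfg.n_samples, "stand")]
        rec = synthesize_channels(sched, cfg)
        t = rec.n_samples
        for grp, idx in CHANNEL_GROUPS.items():
            sd = cfg.noise_sd[grp]
            means = np.abs(rec.signals[:, list(idx)].mean(axis=0))
            assert (means < 3 * sd / np.sqrt(t)).all()

    def test_walk_spectrum_peaks_at_gait_fundamental(self):
        cfg = SimConfig(
            duration_s=100, fog_prevalence=0.0, n_fog_episodes=0,
            noise_sd={"ACC": 1e-6, "GYRO": 1e-6, "CF": 1e-6, "MA": 1e-6}, seed=2,
        )
        rec = synthesize_channels([Episode(0, cfg.n_samples, "walk")], cfg)
        for ch in CHANNEL_GROUPS["ACC"]:
            f, pxx = sps.periodogram(rec.signals[:, ch].astype(np.float64), fs=40.0)
            assert abs(f[np.argmax(pxx)] - 1.0) <= 0.2

    def test_fog_has_more_tremor_band_power_than_walk(self):
        cfg = SimConfig(duration_s=100, fog_prevalence=0.4, n_fog_episodes=1,
                        fog_duration_s_range=(40.0, 40.0), seed=4)
        half = cfg.n_samples // 2
        sched = [Episode(0, half, "walk"), Episode(half, cfg.n_samples, "fog")]
        rec = synthesize_channels(sched, cfg)

        def band_power(x):
            f, pxx = sps.periodogram(x.astype(np.float64), fs=40.0)
            return pxx[(f >= 3.0) & (f <= 8.0)].sum()

        for ch in CHANNEL_GROUPS["ACC"]:
            assert band_power(rec.signals[half:, ch]) > band_power(rec.signals[:half, ch])


class TestRecording:
    def test_sample_count_matches_duration(self):
        # a 237 s session at 40 Hz must give 9480 samples
        cfg = SimConfig(duration_s=237, fog_prevalence=0.062, n_fog_episodes=7, seed=9)
        assert generate_recording(cfg).n_samples == 9480
        assert generate_recording(SimConfig(duration_s=1, fog_prevalence=0, n_fog_episodes=0)).n_samples == 40

    def test_labels_match_fog_activity(self, small_recording):
        assert ((small_recording.activity == "fog") == (small_recording.labels == 1)).all()
        assert small_recording.signals.dtype == np.float32
        assert np.isfinite(small_recording.signals).all()

    def test_deterministic_given_seed_and_distinct_across_seeds(self):
        cfg = SimConfig(duration_s=20, seed=3, n_fog_episodes=2, fog_prevalence=0.1)
        a = generate_recording(cfg)
        b = generate_recording(cfg)
        assert np.array_equal(a.signals, b.signals)
        assert np.array_equal(a.labels, b.labels)
        c = generate_recording(SimConfig(duration_s=20, seed=4, n_fog_episodes=2, fog_prevalence=0.1))
        assert not np.array_equal(a.signals, c.signals)
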