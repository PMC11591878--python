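"""MUA extraction, layer rates, onset increments and recovery."""

import numpy as np
import pytest

from csdwave import spikes, synthgen
from csdwave.core import AnalysisConfig, DomainError, ProbeGeometry, assign_layers
from conftest import make_session

CFG = AnalysisConfig()


def _train_set(events_by_channel, duration=100.0):
    return spikes.SpikeTrainSet(
        events={ch: np.asarray(t, float) for ch, t in events_by_channel.items()},
        thresholds={ch: -0.5 for ch in events_by_channel},
        noise_sd={ch: 0.1 for ch in events_by_channel},
        band=(300.0, 3000.0),
        dead_time_ms=1.0,
        duration=duration,
    )


class TestDetection:
    def test_zero_signal_yields_zero_events(self):
        s = make_session(np.zeros((3, 64000)), 16000.0, kcl_time=3.0)
        trains = spikes.detect_mua(s, CFG)
        assert all(t.size == 0 for t in trains.events.values())

    def test_false_positive_rate_on_pure_noise(self):
        """5-SD threshold on Gaussian noise: far below 1 event/s/channel.

        Oracle: the Gaussian tail P(x < -5sd) ~ 2.9e-7 per sample puts the
        expected crossing rate near 0.005/s at 16 kHz; assert the
        Monte-Carlo rate stays an order of magnitude under 1/s."""
        cfg = synthgen.GeneratorConfig(
            duration=30.0, sample_rate=16000.0, kcl_time=29.0, n_sites=3,
            site_spacing=100.0, tip_depth=1700.0,
            noise_sd=0.1, drift_sd=0.0, seed=13,
        )
        s = synthgen.generate_session(cfg)
        trains = spikes.detect_mua(s, CFG)
        for t in trains.events.values():
            assert t.size / 30.0 < 1.0

    def test_rendered_spikes_recovered_with_submillisecond_timing(self):
        rate, dur = 20.0, 30.0
        cfg = synthgen.GeneratorConfig(
            duration=dur, sample_rate=16000.0, kcl_time=29.0,
            background_rate=rate, noise_sd=0.1, drift_sd=0.0, seed=14,
        )
        s = synthgen.generate_session(cfg)
        trains = spikes.detect_mua(s, CFG)
        for ch, gt in s.ground_truth["spike_times"].items():
            gt = np.asarray(gt)
            det = trains.events[int(ch)]
            err = np.abs(det[:, None] - gt[None, :]).min(axis=0)
            assert np.mean(err < 0.0005) >= 0.99

    def test_threshold_scales_with_noise_sd(self):
        mk = lambda sd: synthgen.generate_session(synthgen.GeneratorConfig(
            duration=10.0, sample_rate=16000.0, kcl_time=9.0, n_sites=3,
            noise_sd=sd, drift_sd=0.0, seed=15,
        ))
        t1 = spikes.detect_mua(mk(0.1), CFG)
        t2 = spikes.detect_mua(mk(0.2), CFG)
        for ch in range(3):
            assert t2.thresholds[ch] / t1.thresholds[ch] == pytest.approx(
                2.0, rel=0.05
            )
            assert t1.thresholds[ch] == pytest.approx(
                -CFG.mua_threshold_sd * t1.noise_sd[ch]
            )

    def test_dead_time_monotonicity(self):
        cfg = synthgen.GeneratorConfig(
            duration=20.0, sample_rate=16000.0, kcl_time=19.0,
            background_rate=40.0, noise_sd=0.1, drift_sd=0.0, seed=16,
        )
        s = synthgen.generate_session(cfg)
        counts = []
        for dead in (0.5, 1.0, 2.0, 4.0):
            trains = spikes.detect_mua(
                s, AnalysisConfig(mua_dead_time_ms=dead)
            )
            counts.append(sum(t.size for t in trains.events.values()))
        assert counts == sorted(counts, reverse=True)

    def test_low_sample_rate_rejected(self):
        s = make_session(np.zeros((3, 1000)), 1000.0)
        with pytest.raises(DomainError):
            spikes.detect_mua(s, CFG)


class TestRates:
    def test_layer_rate_averages_channels(self, layers):
        # two L4 channels (sites 5, 6) at 10/s and 30/s over 10 s
        trains = _train_set({5: np.arange(0, 10, 0.1),
                             6: np.arange(0, 10, 1 / 30)})
        r = spikes.layer_rate(trains, layers, (0.0, 10.0))
        assert r["L4"] == pytest.approx(20.0)

    def test_empty_layer_is_missing_not_zero(self, layers):
        trains = _train_set({5: [1.0, 2.0]})
        r = spikes.layer_rate(trains, layers, (0.0, 10.0))
        assert r["L2/3"] is None
        assert r["L4"] == pytest.approx(0.2)

    def test_no_spikes_is_zero_rate(self, layers):
        trains = _train_set({5: []})
        assert spikes.layer_rate(trains, layers, (0.0, 10.0))["L4"] == 0.0

    def test_increment_restricted_to_bursting_layer(self):
        """Burst confined to L2/3: other layers' increments stay near 0."""
        cfg = synthgen.hhcy_preset(
            duration=140.0, sample_rate=16000.0, seed=17, n_waves=1,
            first_onset=60.0, period_min=0.0, kcl_time=40.0, drift_sd=0.0,
            propagation_delay_per_site=0.0, sep_amplitude_uv=None,
            background_rate=20.0,
            onset_burst_rate={"L2/3": 100.0, "L4": 0.0, "L5/6": 0.0},
            suppression_fraction=0.0,
        )
        s = synthgen.generate_session(cfg)
        trains = spikes.detect_mua(s, CFG)
        front = min(
            s.ground_truth["waves"][0]["channel_fronts"][ch]
            for ch in s.layers.sites("L2/3")
        )
        inc = spikes.onset_increment(trains, front, s.layers)
        assert inc["L2/3"] == pytest.approx(100.0, abs=15.0)
        assert abs(inc["L4"]) < 10.0
        assert abs(inc["L5/6"]) < 10.0

    def test_constant_rate_increment_near_zero(self):
        rng = np.random.default_rng(0)
        times = synthgen.generate_spike_train(20.0, 0.0, 100.0, rng)
        trains = _train_set({5: times}, duration=100.0)
        layers = assign_layers(ProbeGeometry())
        inc = spikes.onset_increment(trains, 50.0, layers)
        assert abs(inc["L4"]) < 3 * np.sqrt(2 * 20.0 / 10.0)

    def test_sep_window_rates_recover_generator_extras(self):
        """Stimulus-locked rates in the 0-20 / 20-520 ms windows."""
        stims = np.arange(10.0, 610.0, 6.0)
        cfg = synthgen.GeneratorConfig(
            duration=620.0, sample_rate=8000.0, kcl_time=615.0,
            n_sites=4, site_spacing=300.0, tip_depth=1700.0,
            stim_times=stims, noise_sd=0.1, drift_sd=0.0, seed=18,
            sep_during_extra={"L2/3": 0.0, "L4": 8.05, "L5/6": 0.0},
            sep_after_extra={"L2/3": 0.0, "L4": 50.02, "L5/6": 0.0},
        )
        s = synthgen.generate_session(cfg)  # site 0 is the only L4 channel
        trains = spikes.detect_mua(s, CFG)
        during, after = spikes.sep_spike_rates(
            trains, stims, s.layers, sep_onset_ms=0.0
        )
        n = stims.size
        se_d = np.sqrt(8.05 / (n * 0.02))
        se_a = np.sqrt(50.02 / (n * 0.5))
        assert during["L4"] == pytest.approx(8.05, abs=3 * se_d)
        assert after["L4"] == pytest.approx(50.02, abs=3 * se_a)

    def test_sep_rates_require_stimuli(self, layers):
        with pytest.raises(DomainError):
            spikes.sep_spike_rates(_train_set({5: []}), [], layers)

    def test_spikes_outside_windows_give_zero_rates(self, layers):
        trains = _train_set({5: [4.0, 9.0]})
        during, after = spikes.sep_spike_rates(
            trains, [5.0], layers, sep_onset_ms=0.0
        )
        assert during["L4"] == 0.0 and after["L4"] == 0.0


class TestRecovery:
    def test_no_suppression_recovers_to_hundred_percent(self):
        cfg = synthgen.GeneratorConfig(
            duration=200.0, sample_rate=8000.0, kcl_time=100.0, n_sites=4,
            site_spacing=300.0, tip_depth=1700.0,
            background_rate=30.0, noise_sd=0.1, drift_sd=0.0, seed=19,
        )
        s = synthgen.generate_session(cfg)
        trains = spikes.detect_mua(s, CFG)
        rf = spikes.recovery_fraction(
            trains, s.layers, (10.0, 90.0), (120.0, 200.0)
        )
        assert rf["L4"] == pytest.approx(100.0, abs=10.0)

    def test_zero_reference_rate_is_missing(self, layers):
        trains = _train_set({5: [50.0]})
        rf = spikes.recovery_fraction(trains, layers, (0.0, 10.0), (40.0, 60.0))
        assert rf["L4"] is None

    def test_strong_suppression_lands_in_reported_band(self):
        """Suppression 0.9 with very slow recovery: 5-20 % at +5 min."""
        cfg = synthgen.hhcy_preset(
            duration=500.0, sample_rate=8000.0, seed=20, n_waves=1,
            first_onset=100.0, period_min=0.0, kcl_time=80.0, drift_sd=0.0,
            propagation_delay_per_site=0.0, sep_amplitude_uv=None,
            background_rate={"L2/3": 10.0, "L4": 32.0, "L5/6": 30.0},
            onset_burst_rate=0.0,
        )
        s = synthgen.generate_session(cfg)
        trains = spikes.detect_mua(s, CFG)
        last = s.ground_truth["waves"][0]["t_start"]
        rf = spikes.recovery_fraction(
            trains, s.layers, (10.0, 70.0), (last + 300.0, last + 360.0)
        )
        for lay in ("L4", "L5/6"):
            assert 5.0 <= rf[lay] <= 20.0
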