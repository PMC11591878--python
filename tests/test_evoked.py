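"""Evoked potentials: averaging, depth profile, CSD maps, recovery."""

import logging

import numpy as np
import pytest

from csdwave import csd_events, evoked, synthgen
from csdwave.core import AnalysisConfig, DomainError, ProbeGeometry, assign_layers
from conftest import make_session


def _sep_session(n_stims=20, noise=0.0, seed=30, fs=2000.0, **overrides):
    stims = np.arange(5.0, 5.0 + 6.0 * n_stims, 6.0)
    cfg = synthgen.control_preset(
        duration=float(stims[-1] + 10.0), sample_rate=fs, seed=seed,
        n_waves=0, kcl_time=float(stims[-1] + 5.0),
        noise_sd=noise, drift_sd=0.0, stim_times=stims,
        background_rate=0.0, onset_burst_rate=0.0,
    )
    cfg.waves = []
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return synthgen.generate_session(cfg), stims


class TestAveraging:
    def test_deterministic_template_average_equals_template(self):
        s, stims = _sep_session(n_stims=10)
        ac = AnalysisConfig(dc_rate=2000.0)
        avg = evoked.average_sep(s, stims, ac)
        one = evoked.average_sep(s, stims[:1], ac)
        np.testing.assert_allclose(avg.data, one.data, atol=1e-9)
        assert avg.n_stimuli == 10

    def test_constant_offset_removed_by_baseline_subtraction(self):
        s, stims = _sep_session(n_stims=5)
        s_off = make_session(s.signal - 4.0, s.sample_rate,
                             kcl_time=s.kcl_time, stim_times=stims)
        ac = AnalysisConfig(dc_rate=2000.0)
        a = evoked.average_sep(s, stims, ac)
        b = evoked.average_sep(s_off, stims, ac)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)
        pre = a.times_ms < 0
        assert abs(np.mean(b.data[:, pre])) < 1e-6

    def test_residual_shrinks_as_sqrt_n(self):
        """Average residual SD at N=25 vs N=100 shrinks by ~2."""
        s, stims = _sep_session(n_stims=100, noise=0.05, seed=31)
        clean, _ = _sep_session(n_stims=100, noise=0.0, seed=31)
        ac = AnalysisConfig(dc_rate=2000.0)
        ref = evoked.average_sep(clean, stims[:1], ac).data

        def resid(n):
            avg = evoked.average_sep(s, stims[:n], ac)
            return float(np.std(avg.data - ref))

        ratio = resid(25) / resid(100)
        assert 1.5 < ratio < 2.7

    def test_excluded_stimuli_are_counted(self):
        s, stims = _sep_session(n_stims=10)
        avg = evoked.average_sep(
            s, stims, AnalysisConfig(dc_rate=2000.0),
            exclude_spans=[(stims[0] - 1, stims[2] + 1)],
        )
        assert avg.n_excluded == 3
        assert avg.n_stimuli == 7

    def test_requires_stimuli(self):
        s, _ = _sep_session(n_stims=3)
        with pytest.raises(DomainError):
            evoked.average_sep(s, [], AnalysisConfig(dc_rate=2000.0))


class TestProfile:
    def test_latency_and_amplitude_recover_template(self):
        s, stims = _sep_session(n_stims=20)
        ac = AnalysisConfig(dc_rate=2000.0)
        prof = evoked.measure_sep(evoked.average_sep(s, stims, ac),
                                  s.layers, ac)
        ls = prof.layer_stats

        def get(layer, metric):
            return ls[(ls.layer == layer) & (ls.metric == metric)]["mean"].item()

        assert get("L4", "latency_ms") == pytest.approx(10.24, abs=0.5)
        assert get("L5/6", "amplitude_uv") == pytest.approx(962.56, rel=0.01)
        assert get("L2/3", "latency_ms") == pytest.approx(11.55, abs=0.5)
        for c in prof.channels:
            assert c.responsive
            assert c.onset_ms < c.peak_latency_ms <= 100.0

    def test_flat_channel_marked_non_responsive(self, layers):
        data = np.zeros((16, 1101))
        data[4] = -0.5 * np.exp(-((np.arange(1101) - 1010) / 5.0) ** 2)
        avg = evoked.EvokedAverage(
            data=data, times_ms=np.arange(1101) - 1000.0, dc_rate=1000.0,
            n_stimuli=10, n_excluded=0,
        )
        prof = evoked.measure_sep(avg, layers)
        assert prof.channels[4].responsive
        assert not prof.channels[0].responsive
        assert prof.channels[0].amplitude_uv is None

    def test_profile_invariant_to_channel_dc_offset(self):
        s, stims = _sep_session(n_stims=10)
        offs = s.signal + np.linspace(-3, 3, 16)[:, None].astype(np.float32)
        s2 = make_session(offs, s.sample_rate, kcl_time=s.kcl_time,
                          stim_times=stims)
        ac = AnalysisConfig(dc_rate=2000.0)
        p1 = evoked.measure_sep(evoked.average_sep(s, stims, ac), s.layers, ac)
        p2 = evoked.measure_sep(evoked.average_sep(s2, stims, ac), s2.layers, ac)
        for a, b in zip(p1.channels, p2.channels):
            # float32 storage of the offset signal limits the match
            assert a.amplitude_uv == pytest.approx(b.amplitude_uv, abs=0.01)
            assert a.peak_latency_ms == b.peak_latency_ms


class TestPrincipalWhisker:
    def test_amplitude_wins_conflict_with_logged_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            best = evoked.principal_whisker(
                {"A": (1200.0, 11.0), "B": (800.0, 9.0)}
            )
        assert best == "A"
        assert any("conflict" in r.message for r in caplog.records)

    def test_single_candidate_is_itself(self):
        assert evoked.principal_whisker({"C2": (500.0, 10.0)}) == "C2"

    def test_equal_amplitudes_fall_back_to_latency(self):
        best = evoked.principal_whisker(
            {"A": (900.0, 11.0), "B": (900.0, 9.0)}
        )
        assert best == "B"


class TestSourceDensity:
    def test_depth_linear_profile_maps_to_zero(self):
        rng = np.random.default_rng(2)
        z = ProbeGeometry().site_depths[:, None]
        a, b = rng.normal(size=(2, 1, 200))
        m = evoked.source_density(a * z + b, 100.0)
        np.testing.assert_allclose(m.data, 0.0, atol=1e-9)
        assert m.data.shape[0] == 14  # interior sites only

    def test_quadratic_profile_gives_constant_curvature(self):
        z = np.arange(16, dtype=float)[:, None]  # depth in units of h
        v = z**2 * np.ones((1, 5))
        sink_neg = evoked.source_density(v, 1000.0)  # h = 1 mm
        np.testing.assert_allclose(sink_neg.data, -2.0, atol=1e-12)
        plain = evoked.source_density(v, 1000.0, sink_negative=False)
        np.testing.assert_allclose(plain.data, 2.0, atol=1e-12)

    def test_supragranular_sink_localised_in_l23(self, probe, layers):
        depths = probe.site_depths
        t = np.sin(np.pi * np.linspace(0, 1, 60))[None, :]
        lfp = -np.exp(-(((depths[:, None] - 400.0) / 150.0) ** 2)) * t
        m = evoked.source_density(lfp, probe.site_spacing)
        i, _ = np.unravel_index(np.argmin(m.data), m.data.shape)
        assert layers.layer_of(int(m.interior_sites[i])) == "L2/3"

    def test_too_few_sites_rejected(self):
        with pytest.raises(DomainError):
            evoked.source_density(np.zeros((2, 10)), 100.0)


class TestRecoveryTimeline:
    def _session_with_wave(self, sep_suppression, tau, seed=33):
        cfg = synthgen.control_preset(
            duration=1100.0, sample_rate=1000.0, seed=seed, n_waves=1,
            first_onset=240.0, period_min=0.0, kcl_time=200.0,
            noise_sd=0.01, drift_sd=0.0,
            background_rate=0.0, onset_burst_rate=0.0,
            sep_suppression_fraction=sep_suppression, sep_recovery_tau=tau,
        )
        s = synthgen.generate_session(cfg)
        waves = csd_events.detect_csd_waves(s, AnalysisConfig(dc_rate=100.0))
        return s, waves

    def test_full_recovery_reaches_reference_band(self):
        s, waves = self._session_with_wave(1.0, 60.0)
        tl = evoked.sep_recovery_timeline(
            s, waves, config=AnalysisConfig(dc_rate=1000.0),
            checkpoints_min=(5.0, 10.0),
        )
        for lay in ("L4", "L5/6"):
            assert 90.0 <= tl.checkpoints[10.0][lay] <= 110.0

    def test_permanent_suppression_stays_near_zero(self):
        s, waves = self._session_with_wave(1.0, 1.0e7)
        tl = evoked.sep_recovery_timeline(
            s, waves, config=AnalysisConfig(dc_rate=1000.0),
            checkpoints_min=(5.0, 10.0),
        )
        for c in (5.0, 10.0):
            assert tl.checkpoints[c]["L4"] < 10.0

    def test_identical_pre_post_templates_are_hundred_percent(self):
        s, waves = self._session_with_wave(0.0, 60.0)
        tl = evoked.sep_recovery_timeline(
            s, waves, config=AnalysisConfig(dc_rate=1000.0),
            checkpoints_min=(5.0,),
        )
        assert tl.checkpoints[5.0]["L4"] == pytest.approx(100.0, abs=3.0)

    def test_missing_pre_kcl_stimuli_is_an_error(self):
        s, waves = self._session_with_wave(0.0, 60.0)
        s.kcl_time = 1.0  # no stimulus precedes it
        with pytest.raises(DomainError):
            evoked.sep_recovery_timeline(
                s, waves, config=AnalysisConfig(dc_rate=1000.0)
            )
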