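"""Generator contracts: call statistics, waveform structure, scene mixing,
LFP modulation closed forms, spike-rate gains, sync arithmetic."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import get_window

from callcortex._rng import substream
from callcortex.errors import ContractError, InvalidConfigError
from callcortex.synth import (
    SynthConfig,
    generate_acoustic_scene,
    generate_call_sequence,
    generate_lfp,
    generate_spike_trains,
    generate_sync,
    synthesize_call_waveform,
)
from callcortex.synth.calls import twitter_syllable_onsets
from callcortex.synth.config import BetaModulation, WindowGains
from callcortex.types import CallEvent, CallType

from conftest import make_trills, make_twitter


class TestCallSequence:
    def test_zero_rates_give_empty_list(self, config):
        config.call_rates_per_min = {ct: 0.0 for ct in CallType}
        assert generate_call_sequence(config, 600.0, seed=0) == []

    def test_negative_duration_rejected(self, config):
        with pytest.raises(InvalidConfigError):
            generate_call_sequence(config, -1.0, seed=0)

    def test_negative_rate_rejected(self, config):
        config.call_rates_per_min[CallType.TRILL] = -1.0
        with pytest.raises(InvalidConfigError):
            generate_call_sequence(config, 10.0, seed=0)

    def test_twitter_zero_jitter_deterministic_grid(self):
        onsets = twitter_syllable_onsets(1.0, 7.0, 0.0, 0.05)
        np.testing.assert_allclose(onsets, np.arange(7) / 7.0)

    def test_trill_counts_follow_poisson_process(self, config):
        # rate 6/min over 3600 s -> mean 360; averaged over 200 seeds the
        # empirical mean must sit within 3 standard errors.  The check
        # runs on the unpruned (non-target) path: target events are
        # additionally thinned to enforce non-overlap.
        config.call_rates_per_min = {ct: 0.0 for ct in CallType}
        config.call_rates_per_min[CallType.TRILL] = 6.0
        counts = [
            len(generate_call_sequence(config, 3600.0, seed=s, is_target=False))
            for s in range(200)
        ]
        se = np.sqrt(360.0 / 200)
        assert abs(np.mean(counts) - 360.0) < 3 * se

    def test_target_events_never_overlap(self, config):
        events = generate_call_sequence(config, 1200.0, seed=5)
        for a, b in zip(events, events[1:]):
            assert b.onset_s >= a.offset_s


class TestCallWaveforms:
    def test_trill_zero_fm_depth_is_pure_tone(self, config):
        config.trill_fm_depth_hz = 0.0
        ev = CallEvent(onset_s=0.0, offset_s=0.5, call_type=CallType.TRILL)
        w = synthesize_call_waveform(ev, 48000.0, config)
        spec = np.abs(np.fft.rfft(w * np.hanning(w.size)))
        f_peak = np.fft.rfftfreq(w.size, 1 / 48000.0)[np.argmax(spec)]
        assert f_peak == pytest.approx(config.carrier_hz, abs=10.0)

    def test_twitter_envelope_has_one_burst_per_syllable(self, config):
        ev = make_twitter(0.0, duration=0.75)  # 5 syllables at 7 Hz
        assert ev.n_syllables == 5
        w = synthesize_call_waveform(ev, 48000.0, config)
        env = np.abs(w)
        # burst count via threshold crossings of the smoothed envelope
        kernel = np.ones(96) / 96  # 2 ms
        smooth = np.convolve(env, kernel, mode="same")
        above = (smooth > 0.2 * smooth.max()).astype(int)
        n_bursts = np.sum(np.diff(above) == 1) + above[0]
        assert n_bursts == 5

    def test_phee_peak_frequency_drifts_linearly(self, config):
        ev = CallEvent(onset_s=0.0, offset_s=2.0, call_type=CallType.PHEE)
        w = synthesize_call_waveform(ev, 48000.0, config)
        win = get_window("hann", 1024)
        sft = ShortTimeFFT(win, hop=512, fs=48000.0)
        S = np.abs(sft.stft(w))
        freqs, times = sft.f, sft.t(w.size)
        keep = (times > 0.1) & (times < 1.9)
        track = freqs[np.argmax(S[:, keep], axis=0)]
        slope = np.polyfit(times[keep], track, 1)[0]
        assert slope == pytest.approx(config.phee_fm_slope_hz_per_s, rel=0.05)
        assert np.all(np.diff(track) >= -freqs[1])  # monotone within bin width

    def test_fundamental_above_5khz(self, config):
        for ct in CallType:
            assert config.carrier_hz > 5000.0 or ct is CallType.TWITTER
        assert config.twitter_sweep_lo_hz > 5000.0

    def test_aliasing_rejected(self, config):
        ev = CallEvent(onset_s=0.0, offset_s=0.5, call_type=CallType.TRILL)
        with pytest.raises(ContractError):
            synthesize_call_waveform(ev, 8000.0, config)


def _band_energy(x, fs, lo, hi):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[(freqs >= lo) & (freqs <= hi)].sum()


class TestAcousticScene:
    def test_noise_only_channels_balanced(self, config):
        scene = generate_acoustic_scene([], [], config, seed=0, duration_s=2.0)
        ratio = 10 * np.log10(np.mean(scene.parabolic**2) / np.mean(scene.reference**2))
        assert abs(ratio) < 0.5

    def test_target_gain_20db_in_band(self, config):
        ev = CallEvent(onset_s=0.5, offset_s=1.5, call_type=CallType.PHEE)
        scene = generate_acoustic_scene([ev], [], config, seed=1, duration_s=3.0)
        fs = scene.sample_rate_hz
        i0, i1 = int(0.5 * fs), int(1.5 * fs)
        lo, hi = config.carrier_hz - 500, config.carrier_hz + 1500
        ratio = 10 * np.log10(
            _band_energy(scene.parabolic[i0:i1], fs, lo, hi)
            / _band_energy(scene.reference[i0:i1], fs, lo, hi)
        )
        assert ratio == pytest.approx(20.0, abs=1.0)

    def test_nontarget_cancels(self, config):
        ev = CallEvent(onset_s=0.5, offset_s=1.5, call_type=CallType.PHEE,
                       is_target=False)
        scene = generate_acoustic_scene([], [ev], config, seed=2, duration_s=3.0)
        fs = scene.sample_rate_hz
        i0, i1 = int(0.5 * fs), int(1.5 * fs)
        lo, hi = config.carrier_hz - 500, config.carrier_hz + 1500
        ratio = 10 * np.log10(
            _band_energy(scene.parabolic[i0:i1], fs, lo, hi)
            / _band_energy(scene.reference[i0:i1], fs, lo, hi)
        )
        assert abs(ratio) < 0.5

    def test_overlapping_targets_rejected(self, config):
        a = CallEvent(onset_s=0.5, offset_s=1.5, call_type=CallType.PHEE)
        b = CallEvent(onset_s=1.0, offset_s=2.0, call_type=CallType.PHEE)
        with pytest.raises(ContractError):
            generate_acoustic_scene([a, b], [], config, seed=0, duration_s=3.0)

    def test_energy_superposition(self, config):
        # with noise silenced, adding one call adds exactly its energy
        # (x gain^2 + 1 across the two channels)
        config.noise_rms = 0.0
        config.mic_noise_rms = 0.0
        ev = CallEvent(onset_s=0.5, offset_s=1.0, call_type=CallType.TRILL)
        scene = generate_acoustic_scene([ev], [], config, seed=0, duration_s=2.0)
        wave = synthesize_call_waveform(ev, scene.sample_rate_hz, config)
        e_call = np.sum(wave**2)
        gain = 10 ** (config.target_gain_db / 20.0)
        total = np.sum(scene.parabolic**2) + np.sum(scene.reference**2)
        assert total == pytest.approx((gain**2 + 1) * e_call, rel=1e-9)


class TestLfpGenerator:
    def test_depth_zero_power_flat(self, null_config, trill_events):
        from callcortex.lfp import BETA, band_power_timecourse

        dur = trill_events[-1].offset_s + 6
        lfp = generate_lfp(trill_events, null_config, seed=4, duration_s=dur,
                          n_channels=1)
        power = band_power_timecourse(lfp, trill_events, 0, BETA)
        m = power.window_mask((-0.1, 0.2))
        assert power.values[:, m].mean() == pytest.approx(1.0, abs=0.05)

    def test_depth_has_closed_form_power_ratio(self, config):
        # depth is a power fraction: relative beta power ~ 1 - depth
        from callcortex.lfp import BETA, band_power_timecourse

        config.beta = {ct: BetaModulation(0.3, -0.5) for ct in CallType}
        events = make_trills(200, spacing=8.0, duration=1.0)
        dur = events[-1].offset_s + 6
        lfp = generate_lfp(events, config, seed=11, duration_s=dur, n_channels=1)
        power = band_power_timecourse(lfp, events, 0, BETA)
        m = power.window_mask((-0.1, 0.2))
        assert power.values[:, m].mean() == pytest.approx(0.7, abs=0.04)

    def test_invalid_depth_rejected(self, config):
        with pytest.raises(InvalidConfigError):
            config.beta[CallType.PHEE] = BetaModulation(1.5, 0.0)
            config.validate()

    def test_degenerate_kappa_locks_exactly_at_trough(self, config):
        from callcortex.phaselock import instantaneous_phase, phases_at_onsets

        config.theta_kappa = 1e9
        config.twitter_syllable_jitter_s = 0.0
        events = [make_twitter(10.0 + 4 * i) for i in range(20)]
        dur = events[-1].offset_s + 5
        lfp = generate_lfp(events, config, seed=6, duration_s=dur, n_channels=1)
        phase = instantaneous_phase(lfp.samples[0], lfp.sample_rate_hz)
        onsets = np.array([t for e in events for t in e.syllable_onsets_s])
        pset = phases_at_onsets(phase, lfp.sample_rate_hz, onsets)
        spread = np.abs(np.angle(np.exp(1j * (pset.phases - np.pi))))
        assert np.median(spread) < 0.25  # tightly clustered at the trough

    def test_bit_identical_given_seed(self, config, trill_events):
        dur = trill_events[-1].offset_s + 6
        a = generate_lfp(trill_events, config, seed=9, duration_s=dur, n_channels=2)
        b = generate_lfp(trill_events, config, seed=9, duration_s=dur, n_channels=2)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSpikeGenerator:
    def test_all_gains_one_gives_exponential_isis(self, null_config):
        spikes = generate_spike_trains([], null_config, seed=0, duration_s=600.0,
                                       n_units=1)
        isi = np.diff(spikes.trains["u000"])
        # KS against the exponential with the configured rate
        d, p = stats.kstest(isi, "expon", args=(0, 1 / null_config.baseline_rate_hz))
        assert p > 0.01

    def test_pre_window_gain_recovered(self, config):
        config.spike_gains = {ct: WindowGains(pre=3.0) for ct in CallType}
        config.baseline_rate_hz = 5.0
        events = make_trills(100, spacing=25.0)
        dur = events[-1].offset_s + 15
        spikes = generate_spike_trains(events, config, seed=5, duration_s=dur,
                                       n_units=1)
        times = spikes.trains["u000"]
        counts = [
            np.sum((times >= e.onset_s - 0.5) & (times < e.onset_s)) for e in events
        ]
        rate = np.mean(counts) / 0.5
        se = np.sqrt(15.0 / (100 * 0.5))
        assert abs(rate - 15.0) < 3 * se

    def test_zero_gain_silences_window(self, config):
        config.spike_gains = {ct: WindowGains(during=0.0) for ct in CallType}
        events = make_trills(50, spacing=20.0, duration=1.0)
        dur = events[-1].offset_s + 15
        spikes = generate_spike_trains(events, config, seed=6, duration_s=dur,
                                       n_units=1)
        times = spikes.trains["u000"]
        for e in events:
            assert not np.any((times >= e.onset_s) & (times < e.onset_s + 0.8))

    def test_negative_gain_rejected(self, config):
        with pytest.raises(InvalidConfigError):
            config.spike_gains[CallType.TRILL] = WindowGains(pre=-1.0)
            config.validate()


class TestSync:
    def test_pulse_count_and_period(self):
        audio, neural = generate_sync(10.0, drift_ppm=0.0, seed=0, offset_s=0.0)
        assert audio.n_pulses == 5
        np.testing.assert_allclose(audio.times, neural.times)

    def test_drift_arithmetic(self):
        audio, neural = generate_sync(3600.0, drift_ppm=100.0, seed=0, offset_s=0.0)
        assert neural.times[-1] - audio.times[-1] == pytest.approx(
            100e-6 * audio.times[-1]
        )

    def test_alignment_round_trip(self):
        from callcortex.acoustics import align_clocks

        audio, neural = generate_sync(600.0, drift_ppm=80.0, seed=2,
                                      offset_s=1.234, jitter_s=1e-4)
        cmap = align_clocks(audio, neural)
        assert cmap.offset_s == pytest.approx(1.234, abs=1e-3)
        assert cmap.drift == pytest.approx(80e-6, abs=5e-6)
        t = np.array([10.0, 300.0, 599.0])
        np.testing.assert_allclose(cmap.neural_to_audio(cmap.audio_to_neural(t)),
                                   t, atol=1e-3)


class TestDeterminism:
    def test_named_substreams_are_independent(self):
        a1 = substream(7, "calls").normal(size=4)
        a2 = substream(7, "calls").normal(size=4)
        b = substream(7, "noise").normal(size=4)
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)

    def test_sequence_reproducible(self, config):
        e1 = generate_call_sequence(config, 300.0, seed=3)
        e2 = generate_call_sequence(config, 300.0, seed=3)
        assert [(e.onset_s, e.call_type) for e in e1] == [
            (e.onset_s, e.call_type) for e in e2
        ]
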