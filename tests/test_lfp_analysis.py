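"""Band power, modulation tests, start times, profiles and embeddings."""

import numpy as np
import pytest

from callcortex.errors import ContractError, DegenerateInputError, EmptyInputError
from callcortex.lfp import (
    BETA,
    BandDefinition,
    ONSET_WINDOW,
    TrialAlignedPower,
    band_power_timecourse,
    beta_profile,
    bootstrap_baseline_sd,
    compare_across_call_types,
    embed_beta_profiles,
    extract_peak_features,
    find_modulation_start_time,
    morlet_tfr,
    within_between_distance,
)
from callcortex.lfp import test_window_modulation as window_modulation_test
from callcortex.synth import generate_lfp
from callcortex.synth.config import BetaModulation
from callcortex.types import CallEvent, CallType, LfpChannelSet

from conftest import make_trills


def _noise_lfp(n_channels=1, duration=260.0, seed=0, fs=1000.0):
    rng = np.random.default_rng(seed)
    return LfpChannelSet(samples=rng.normal(0, 10, (n_channels, int(duration * fs))),
                         sample_rate_hz=fs)


def _aligned_power(values, rate=200.0, window=(-3.5, 3.5), durations=None):
    i0, i1 = int(window[0] * rate), int(window[1] * rate)
    times = np.arange(i0, i1) / rate
    assert values.shape[1] == times.size
    if durations is None:
        durations = np.full(values.shape[0], 0.5)
    return TrialAlignedPower(values=values, times_s=times, durations_s=durations,
                             band=BETA)


class TestBandPower:
    def test_baseline_mean_exactly_one_per_trial(self, trill_events):
        lfp = _noise_lfp(duration=trill_events[-1].offset_s + 6)
        power = band_power_timecourse(lfp, trill_events, 0, BETA)
        base = power.values[:, power.baseline_mask()].mean(axis=1)
        np.testing.assert_allclose(base, 1.0, atol=1e-12)

    def test_scaling_channel_leaves_power_unchanged(self, trill_events):
        lfp = _noise_lfp(duration=trill_events[-1].offset_s + 6)
        p1 = band_power_timecourse(lfp, trill_events, 0, BETA)
        lfp2 = LfpChannelSet(samples=lfp.samples * 37.5,
                             sample_rate_hz=lfp.sample_rate_hz)
        p2 = band_power_timecourse(lfp2, trill_events, 0, BETA)
        np.testing.assert_allclose(p1.values, p2.values, rtol=1e-9)

    def test_short_calls_excluded(self):
        events = make_trills(20) + [
            CallEvent(onset_s=300.0, offset_s=300.15, call_type=CallType.TRILL)
        ]
        lfp = _noise_lfp(duration=320.0)
        power = band_power_timecourse(lfp, events, 0, BETA)
        assert power.n_trials == 20
        assert power.n_excluded == 1

    def test_all_excluded_raises(self):
        lfp = _noise_lfp(duration=20.0)
        ev = [CallEvent(onset_s=1.0, offset_s=1.5, call_type=CallType.TRILL)]
        with pytest.raises(EmptyInputError):
            band_power_timecourse(lfp, ev, 0, BETA)  # no -3.5 s context

    def test_invalid_band_rejected(self):
        with pytest.raises(ContractError):
            BandDefinition("bad", 30.0, 12.0).validate(1000.0)


class TestMorletTfr:
    def test_stationary_noise_ratio_one(self, trill_events):
        lfp = _noise_lfp(duration=trill_events[-1].offset_s + 6, seed=3)
        power, times, freqs = morlet_tfr(lfp, trill_events, 0,
                                         freqs_hz=np.arange(10, 41, 5))
        inner = (times > -2.8) & (times < 2.8)
        assert abs(power[:, inner].mean() - 1.0) < 0.1

    def test_injected_beta_burst_localized(self, trill_events):
        lfp = _noise_lfp(duration=trill_events[-1].offset_s + 6, seed=4)
        fs = lfp.sample_rate_hz
        tt = np.arange(int(0.5 * fs)) / fs
        burst = 12 * np.sin(2 * np.pi * 20.0 * tt)
        for ev in trill_events:
            i0 = int((ev.onset_s + 0.1) * fs)
            lfp.samples[0, i0:i0 + burst.size] += burst
        power, times, freqs = morlet_tfr(lfp, trill_events, 0,
                                         freqs_hz=np.arange(8, 45, 4))
        post = (times > 0.15) & (times < 0.55)
        at20 = power[np.argmin(np.abs(freqs - 20.0))][post].mean()
        at40 = power[np.argmin(np.abs(freqs - 40.0))][post].mean()
        assert at20 > 1.5
        assert at40 < 1.3

    def test_single_trial_equals_average(self):
        lfp = _noise_lfp(duration=30.0, seed=5)
        ev = [CallEvent(onset_s=15.0, offset_s=15.5, call_type=CallType.TRILL)]
        power, _, _ = morlet_tfr(lfp, ev, 0, freqs_hz=np.array([15.0, 25.0]))
        assert power.shape[0] == 2  # averaging over one trial is the trial


class TestBootstrapSd:
    def test_constant_power_gives_zero_sd(self):
        power = _aligned_power(np.ones((40, 1400)))
        assert bootstrap_baseline_sd(power, seed=0) == 0.0

    def test_sd_scales_inverse_sqrt_n_draw(self):
        rng = np.random.default_rng(6)
        power = _aligned_power(1.0 + 0.2 * rng.normal(size=(500, 1400)))
        sd50 = bootstrap_baseline_sd(power, n_draw=50, reps=400, seed=1)
        sd200 = bootstrap_baseline_sd(power, n_draw=200, reps=400, seed=2)
        assert sd50 / sd200 == pytest.approx(2.0, rel=0.2)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(7)
        power = _aligned_power(1.0 + 0.1 * rng.normal(size=(30, 1400)))
        assert bootstrap_baseline_sd(power, seed=42) == bootstrap_baseline_sd(
            power, seed=42
        )


class TestWindowModulation:
    def test_window_equal_baseline_is_null(self):
        rng = np.random.default_rng(8)
        power = _aligned_power(1.0 + 0.1 * rng.normal(size=(60, 1400)))
        sd = bootstrap_baseline_sd(power, seed=0)
        res = window_modulation_test(power, (-3.0, -1.0), sd)
        assert res.direction == "none"
        assert not res.significant

    def test_suppression_detected(self, config):
        config.beta = {ct: BetaModulation(0.3, -0.5) for ct in CallType}
        events = make_trills(200, spacing=8.0, duration=1.0)
        lfp = generate_lfp(events, config, seed=12,
                           duration_s=events[-1].offset_s + 6, n_channels=1)
        power = band_power_timecourse(lfp, events, 0, BETA)
        sd = bootstrap_baseline_sd(power, seed=3)
        res = window_modulation_test(power, ONSET_WINDOW, sd)
        assert res.significant
        assert res.direction == "suppression"

    def test_flags_invariant_to_trial_order(self):
        rng = np.random.default_rng(9)
        vals = 1.0 + 0.1 * rng.normal(size=(50, 1400))
        vals[:, 800:] *= 0.8
        power = _aligned_power(vals)
        sd = bootstrap_baseline_sd(power, seed=0)
        res1 = window_modulation_test(power, (1.0, 2.0), sd)
        perm = rng.permutation(50)
        power2 = _aligned_power(vals[perm])
        res2 = window_modulation_test(power2, (1.0, 2.0), sd)
        assert res1.significant == res2.significant
        assert res1.p == pytest.approx(res2.p)


class TestStartTime:
    def test_step_change_point_recovered(self):
        rng = np.random.default_rng(10)
        vals = 1.0 + 0.15 * rng.normal(size=(300, 1400))
        times = np.arange(-700, 700) / 200.0
        vals[:, times >= -0.5] -= 0.25
        power = _aligned_power(vals)
        sd = bootstrap_baseline_sd(power, seed=1)
        res = find_modulation_start_time(power, sd, "suppression")
        assert res.found
        assert -0.55 <= res.start_time_s <= -0.40

    def test_null_trace_rarely_found_with_abundant_trials(self):
        """The 2-SD gate uses a fixed 200-trial bootstrap, so with
        abundant trials (the study's regime: thousands of trills) the
        sliding search almost never fires on null data."""
        from callcortex.synth import SynthConfig, generate_lfp

        found = 0
        n = 10
        for s in range(n):
            cfg = SynthConfig.null()
            calls = make_trills(600, start=5.0, spacing=7.2)
            lfp = generate_lfp(calls, cfg, seed=4100 + s,
                               duration_s=calls[-1].offset_s + 6, n_channels=1)
            power = band_power_timecourse(lfp, calls, 0, BETA)
            sd = bootstrap_baseline_sd(power, reps=200, seed=s)
            if find_modulation_start_time(power, sd, "suppression").found:
                found += 1
        assert found <= 1

    def test_direction_must_be_fixed(self):
        power = _aligned_power(np.ones((20, 1400)))
        with pytest.raises(ContractError):
            find_modulation_start_time(power, 0.1, "maybe")


class TestCrossTypeComparison:
    def test_identical_distributions_rarely_significant(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n = 100
        for _ in range(n):
            groups = {k: rng.normal(size=40) for k in "abcd"}
            if compare_across_call_types(groups).p < 0.05:
                rejections += 1
        assert rejections / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)

    def test_disjoint_supports_extreme(self):
        res = compare_across_call_types(
            {"lo": np.arange(40.0), "hi": 1000.0 + np.arange(40.0)}
        )
        assert res.p < 1e-6
        assert res.pairwise_p[("lo", "hi")] < 1e-6

    def test_label_permutation_destroys_separation(self):
        rng = np.random.default_rng(12)
        lo, hi = rng.normal(0, 1, 50), rng.normal(5, 1, 50)
        assert compare_across_call_types({"a": lo, "b": hi}).p < 1e-6
        pooled = np.concatenate([lo, hi])
        perm = rng.permutation(pooled)
        res = compare_across_call_types({"a": perm[:50], "b": perm[50:]})
        assert res.p > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ContractError):
            compare_across_call_types({"a": np.arange(10.0)})


class TestProfilesAndEmbedding:
    def _profiles(self, sep=1.0, noise=0.05, m=6, seed=13):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 40)
        templates = {
            "phee": 1 - sep * 0.5 * np.exp(-((t - 0.3) ** 2) / 0.02),
            "trill": 1 - sep * 0.2 * np.exp(-((t - 0.5) ** 2) / 0.01),
            "twitter": 1 - sep * 0.35 * np.exp(-((t - 0.4) ** 2) / 0.05),
        }
        profiles, labels = [], []
        for name, tpl in templates.items():
            for _ in range(m):
                profiles.append(tpl + noise * rng.normal(size=t.size))
                labels.append(name)
        return np.asarray(profiles), labels

    def test_within_smaller_than_between(self):
        profiles, labels = self._profiles()
        emb = embed_beta_profiles(profiles, labels)
        within, between, z, p = within_between_distance(emb)
        assert np.median(within) < np.median(between)
        assert p < 1e-6

    def test_pair_counts(self):
        profiles, labels = self._profiles(m=5)
        emb = embed_beta_profiles(profiles, labels)
        within, between, _, _ = within_between_distance(emb)
        k, m = 3, 5
        assert within.size == k * m * (m - 1) // 2
        assert between.size == k * m * m * (k - 1) // 2

    def test_explained_variance_non_increasing(self):
        profiles, labels = self._profiles()
        emb = embed_beta_profiles(profiles, labels)
        assert np.all(np.diff(emb.explained_variance) <= 1e-12)
        assert np.all((emb.explained_variance >= 0)
                      & (emb.explained_variance <= 1))

    def test_constant_profiles_degenerate(self):
        with pytest.raises(DegenerateInputError):
            embed_beta_profiles(np.ones((6, 40)), ["a"] * 3 + ["b"] * 3)

    def test_beta_profile_shape_10hz(self):
        power = _aligned_power(np.ones((10, 1400)))
        prof = beta_profile(power)
        assert prof.size == 40  # 4 s window at 10 Hz


class TestPeakFeatures:
    def test_v_shape_minimum_located(self):
        times = np.arange(-700, 700) / 200.0
        vals = np.tile(1.0 - 0.5 * np.exp(-((times - 0.3) ** 2) / 0.01), (5, 1))
        power = _aligned_power(vals)
        peak = extract_peak_features(power, "suppression")
        assert peak.time_s == pytest.approx(0.3, abs=0.01)
        assert peak.magnitude == pytest.approx(0.5, abs=0.01)

    def test_late_vs_early_suppression_ordered(self):
        times = np.arange(-700, 700) / 200.0
        early = _aligned_power(
            np.tile(1 - 0.4 * np.exp(-((times - 0.1) ** 2) / 0.02), (5, 1)))
        late = _aligned_power(
            np.tile(1 - 0.4 * np.exp(-((times - 0.9) ** 2) / 0.02), (5, 1)))
        t_early = extract_peak_features(early, "suppression").time_s
        t_late = extract_peak_features(late, "suppression").time_s
        assert t_early < t_late

    def test_flat_trace_degenerate(self):
        power = _aligned_power(np.ones((5, 1400)))
        assert extract_peak_features(power, "suppression").degenerate
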