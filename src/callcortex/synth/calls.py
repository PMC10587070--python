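"""Synthetic call sequences, call waveforms, and two-channel scenes."""

from __future__ import annotations

import numpy as np

from callcortex._rng import substream, as_generator
from callcortex.errors import ContractError, InvalidConfigError
from callcortex.synth.config import SynthConfig
from callcortex.types import AcousticScene, CallEvent, CallType

__all__ = [
    "generate_call_sequence",
    "twitter_syllable_onsets",
    "synthesize_call_waveform",
    "generate_acoustic_scene",
]


def twitter_syllable_onsets(
    duration_s: float,
    rate_hz: float,
    jitter_s: float,
    syllable_dur_s: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Relative syllable-onset times for a twitter-like call.

    Onsets lie on a 1/rate grid (first at 0, un-jittered: it defines the
    vocal onset); later onsets get independent uniform +/- jitter.  The
    last syllable is the latest grid point whose sweep still fits inside
    ``duration_s``.
    """
    n = int(np.floor((duration_s - syllable_dur_s) * rate_hz)) + 1
    n = max(n, 1)
    onsets = np.arange(n) / rate_hz
    if jitter_s > 0 and n > 1:
        rng = as_generator(rng)
        onsets[1:] += rng.uniform(-jitter_s, jitter_s, size=n - 1)
    return onsets


def _make_event(
    call_type: CallType,
    onset: float,
    cfg: SynthConfig,
    rng: np.random.Generator,
    is_target: bool,
) -> CallEvent:
    lo, hi = cfg.duration_ranges_s[call_type]
    duration = rng.uniform(lo, hi)
    if call_type is CallType.TWITTER:
        rel = twitter_syllable_onsets(
            duration,
            cfg.twitter_syllable_rate_hz,
            cfg.twitter_syllable_jitter_s,
            cfg.twitter_syllable_dur_s,
            rng,
        )
        while rel.size < 3:  # twitter needs >= 3 syllables
            duration += 1.0 / cfg.twitter_syllable_rate_hz
            rel = twitter_syllable_onsets(
                duration,
                cfg.twitter_syllable_rate_hz,
                cfg.twitter_syllable_jitter_s,
                cfg.twitter_syllable_dur_s,
                rng,
            )
        offset = onset + rel[-1] + cfg.twitter_syllable_dur_s
        syl = [onset + float(t) for t in rel]
    elif call_type is CallType.COMPOUND:
        # heterogeneous syllables; spacing in whole cycles of the ~7 Hz
        # rhythm (occasionally skipping a cycle), so longer elements can
        # span multiple oscillation periods yet start near the trough
        period = 1.0 / cfg.twitter_syllable_rate_hz
        n_elem = int(rng.integers(3, 7))
        syl_rel = [0.0]
        for _ in range(n_elem - 1):
            cycles = 2 if rng.random() < 0.3 else 1
            syl_rel.append(syl_rel[-1] + cycles * period)
        offset = onset + syl_rel[-1] + 0.15
        syl = [onset + s for s in syl_rel]
    else:
        offset = onset + duration
        syl = [onset]
    return CallEvent(
        onset_s=onset,
        offset_s=offset,
        call_type=call_type,
        syllable_onsets_s=syl,
        is_target=is_target,
    )


def generate_call_sequence(
    config: SynthConfig,
    duration_s: float,
    seed: int | np.random.Generator,
    is_target: bool = True,
) -> list[CallEvent]:
    """Draw a call sequence from independent Poisson processes per type.

    Target events are made non-overlapping (greedy pass keeping earlier
    calls, minimum gap ``config.min_call_gap_s``); non-targets may
    overlap anything.
    """
    if duration_s <= 0:
        raise InvalidConfigError(f"duration_s must be > 0, got {duration_s}")
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "calls")

    candidates: list[CallEvent] = []
    max_dur = max(hi for _, hi in config.duration_ranges_s.values())
    for call_type, rate in sorted(
        config.call_rates_per_min.items(), key=lambda kv: kv[0].value
    ):
        if rate == 0:
            continue
        n = rng.poisson(rate * duration_s / 60.0)
        onsets = np.sort(rng.uniform(0.0, max(duration_s - max_dur - 0.5, 0.0), size=n))
        for onset in onsets:
            candidates.append(_make_event(call_type, float(onset), config, rng, is_target))
    candidates.sort(key=lambda e: e.onset_s)
    if not is_target:
        return candidates

    kept: list[CallEvent] = []
    t_free = -np.inf
    for ev in candidates:
        if ev.onset_s >= t_free:
            kept.append(ev)
            t_free = ev.offset_s + config.min_call_gap_s
    return kept


def _ramp_envelope(n: int, fs: float, ramp_s: float) -> np.ndarray:
    env = np.ones(n)
    n_ramp = min(int(round(ramp_s * fs)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _tone_from_freq(freq: np.ndarray, fs: float) -> np.ndarray:
    """Cosine with the given instantaneous-frequency track (Hz)."""
    phase = 2 * np.pi * np.cumsum(freq) / fs
    return np.cos(phase)


def _sweep(lo: float, hi: float, dur: float, fs: float, ramp_s: float) -> np.ndarray:
    n = max(int(round(dur * fs)), 2)
    t = np.arange(n) / fs
    freq = lo + (hi - lo) * t / dur
    return _tone_from_freq(freq, fs) * _ramp_envelope(n, fs, ramp_s)


def synthesize_call_waveform(
    event: CallEvent, sample_rate_hz: float, config: SynthConfig
) -> np.ndarray:
    """Render one call as a pressure waveform (relative to call onset).

    phee: slow linear upward FM; trill: sinusoidal FM; trillphee:
    trill-like first half fading into phee-like linear FM; twitter:
    short upward sweeps at the syllable onsets separated by silence;
    compound: alternating trill-like and phee-like syllable elements.
    """
    fs = float(sample_rate_hz)
    if fs < 2 * config.max_instantaneous_freq_hz():
        raise ContractError(
            f"sample rate {fs} Hz below 2x the maximum instantaneous "
            f"frequency {config.max_instantaneous_freq_hz():.0f} Hz (aliasing)"
        )
    dur = event.duration_s
    n = int(round(dur * fs))
    if n < 1:
        raise ContractError("call duration shorter than one sample")
    t = np.arange(n) / fs
    amp = config.amplitudes[event.call_type]
    ct = event.call_type

    if ct is CallType.PHEE:
        freq = config.carrier_hz + config.phee_fm_slope_hz_per_s * t
        wave = _tone_from_freq(freq, fs) * _ramp_envelope(n, fs, config.edge_ramp_s)
    elif ct is CallType.TRILL:
        freq = config.carrier_hz + config.trill_fm_depth_hz * np.cos(
            2 * np.pi * config.trill_fm_rate_hz * t
        )
        wave = _tone_from_freq(freq, fs) * _ramp_envelope(n, fs, config.edge_ramp_s)
    elif ct is CallType.TRILLPHEE:
        # sinusoidal FM depth fades out around mid-call; linear FM takes over
        fade = np.clip((0.55 * dur - t) / (0.10 * dur), 0.0, 1.0)
        freq = (
            config.carrier_hz
            + fade * config.trill_fm_depth_hz * np.cos(2 * np.pi * config.trill_fm_rate_hz * t)
            + (1 - fade) * config.phee_fm_slope_hz_per_s * np.clip(t - 0.5 * dur, 0, None)
        )
        wave = _tone_from_freq(freq, fs) * _ramp_envelope(n, fs, config.edge_ramp_s)
    elif ct in (CallType.TWITTER, CallType.COMPOUND):
        wave = np.zeros(n)
        rel_onsets = [s - event.onset_s for s in event.syllable_onsets_s]
        for k, rel in enumerate(rel_onsets):
            if ct is CallType.TWITTER:
                syl = _sweep(
                    config.twitter_sweep_lo_hz,
                    config.twitter_sweep_hi_hz,
                    config.twitter_syllable_dur_s,
                    fs,
                    config.edge_ramp_s,
                )
            elif k % 2 == 0:  # compound: trill-like element
                m = int(round(0.12 * fs))
                tt = np.arange(m) / fs
                f = config.carrier_hz + config.trill_fm_depth_hz * np.cos(
                    2 * np.pi * config.trill_fm_rate_hz * tt
                )
                syl = _tone_from_freq(f, fs) * _ramp_envelope(m, fs, config.edge_ramp_s)
            else:  # compound: phee-like element
                m = int(round(0.12 * fs))
                tt = np.arange(m) / fs
                f = config.carrier_hz + config.phee_fm_slope_hz_per_s * tt
                syl = _tone_from_freq(f, fs) * _ramp_envelope(m, fs, config.edge_ramp_s)
            i0 = int(round(rel * fs))
            i1 = min(i0 + syl.size, n)
            if i0 < n:
                wave[i0:i1] += syl[: i1 - i0]
    else:  # pragma: no cover - exhaustive over CallType
        raise ContractError(f"unknown call type {ct}")
    return amp * wave


def generate_acoustic_scene(
    targets: list[CallEvent],
    nontargets: list[CallEvent],
    config: SynthConfig,
    seed: int | np.random.Generator,
    duration_s: float | None = None,
) -> AcousticScene:
    """Mix calls and noise into a parabolic/reference channel pair.

    Target calls enter the parabolic channel with ``target_gain_db``
    extra amplitude; non-target calls and the shared room noise enter
    both channels at equal level, so they cancel in the spectrogram
    difference.  A small independent sensor-noise floor is added per
    microphone.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "noise")
    fs = config.sample_rate_audio_hz
    events = list(targets) + list(nontargets)
    if duration_s is None:
        if not events:
            raise ContractError("need events or an explicit duration_s")
        duration_s = max(e.offset_s for e in events) + 1.0
    n = int(round(duration_s * fs))

    srt = sorted(targets, key=lambda e: e.onset_s)
    for a, b in zip(srt, srt[1:]):
        if b.onset_s < a.offset_s:
            raise ContractError(
                f"overlapping target events at {a.onset_s:.3f}s and {b.onset_s:.3f}s"
            )
    for e in events:
        if e.onset_s < 0 or e.offset_s > duration_s:
            raise ContractError(f"event at {e.onset_s:.3f}s outside the scene")

    shared = rng.normal(0.0, config.noise_rms, size=n)
    parabolic = shared + rng.normal(0.0, config.mic_noise_rms, size=n)
    reference = shared + rng.normal(0.0, config.mic_noise_rms, size=n)

    gain = 10.0 ** (config.target_gain_db / 20.0)
    for ev in events:
        wave = synthesize_call_waveform(ev, fs, config)
        i0 = int(round(ev.onset_s * fs))
        i1 = min(i0 + wave.size, n)
        seg = wave[: i1 - i0]
        if ev.is_target:
            parabolic[i0:i1] += gain * seg
            reference[i0:i1] += seg
        else:
            parabolic[i0:i1] += seg
            reference[i0:i1] += seg

    return AcousticScene(
        parabolic=parabolic,
        reference=reference,
        sample_rate_hz=fs,
        truth_target=sorted(targets, key=lambda e: e.onset_s),
        truth_nontarget=sorted(nontargets, key=lambda e: e.onset_s),
    )
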