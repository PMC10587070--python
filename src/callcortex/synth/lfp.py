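"""Synthetic LFP: 1/f background, beta-band suppression, locked theta.

The generated signal is the sum of three components per channel:

* pink (1/f) background noise — exercises the baseline normalization;
* narrowband beta (12-30 Hz) noise whose amplitude envelope is
  multiplied by ``sqrt(1 - depth)`` from ``onset + start_offset`` to the
  call offset, per call type, so relative beta POWER during suppression
  equals ``1 - depth`` in closed form;
* a theta burst for every multi-syllable call whose phase at the k-th
  syllable onset is ``pi + delta(t_k)`` (cosine convention: trough =
  pi), where ``delta`` is the channel's phase-jitter process.

The jitter ``delta(t)`` is a smooth stochastic process with a von
Mises(0, kappa) marginal: low-pass filtered Gaussian noise mapped
through the normal CDF and the von Mises quantile function.  A smooth
process is required — independent per-syllable jitter at a ~7 Hz
syllable rate would put the phase modulation outside the 5-10 Hz
measurement band, and no band-limited phase estimate could recover its
distribution.  The marginal is what vector strength measures, and it is
preserved exactly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal, stats

from callcortex._rng import substream, as_generator
from callcortex.synth.config import SynthConfig
from callcortex.types import CallEvent, LfpChannelSet

__all__ = ["generate_lfp", "pink_noise", "vonmises_marginal_process"]

#: kappa above this is treated as a point mass at the trough.
_KAPPA_DEGENERATE = 1e6
#: bandwidth (Hz) of the smooth phase-jitter process.
_JITTER_BANDWIDTH_HZ = 1.0


def pink_noise(n: int, rng: np.random.Generator, rms: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, normalised to ``rms``."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    x = np.fft.irfft(spec, n=n)
    return x * (rms / np.std(x))


def _narrowband_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator, rms: float
) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.normal(size=n))
    return x * (rms / np.std(x))


@lru_cache(maxsize=32)
def _vonmises_quantile_grid(kappa: float, ngrid: int = 4097) -> tuple[np.ndarray, np.ndarray]:
    q = np.linspace(1e-6, 1.0 - 1e-6, ngrid)
    return q, stats.vonmises.ppf(q, kappa)


def vonmises_marginal_process(
    n: int, fs: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth process with an exact von Mises(0, kappa) marginal.

    Low-pass Gaussian noise -> probability-integral transform -> von
    Mises quantile (grid-interpolated).  Correlation time is set by the
    low-pass bandwidth (~1 Hz), a few syllable periods.
    """
    if kappa >= _KAPPA_DEGENERATE:
        return np.zeros(n)
    sos = signal.butter(2, _JITTER_BANDWIDTH_HZ, btype="low", fs=fs, output="sos")
    g = signal.sosfiltfilt(sos, rng.normal(size=n))
    sd = g.std()
    if sd == 0:
        return np.zeros(n)
    g /= sd
    q, vals = _vonmises_quantile_grid(float(kappa))
    return np.interp(stats.norm.cdf(g), q, vals)


def generate_lfp(
    calls: list[CallEvent],
    config: SynthConfig,
    seed: int | np.random.Generator,
    duration_s: float,
    n_channels: int | None = None,
) -> LfpChannelSet:
    """Generate a multi-channel LFP recording for the given call events."""
    config.validate()
    if n_channels is None:
        n_channels = config.n_lfp_channels
    fs = config.sample_rate_lfp_hz
    n = int(round(duration_s * fs))
    master = seed if isinstance(seed, np.random.Generator) else substream(seed, "lfp")
    child_seeds = master.spawn(n_channels)

    calls = sorted(calls, key=lambda e: e.onset_s)
    multi = [ev for ev in calls if ev.n_syllables >= 2]
    rate = config.twitter_syllable_rate_hz
    samples = np.empty((n_channels, n))
    for ch in range(n_channels):
        rng = as_generator(child_seeds[ch])
        x = pink_noise(n, rng, config.pink_amp_uv)

        beta = _narrowband_noise(n, fs, (12.0, 30.0), rng, config.beta_amp_uv)
        env = np.ones(n)
        for ev in calls:
            mod = config.beta.get(ev.call_type)
            if mod is None or mod.depth == 0.0:
                continue
            i0 = max(int(round((ev.onset_s + mod.start_offset_s) * fs)), 0)
            i1 = min(int(round(ev.offset_s * fs)), n)
            if i1 > i0:
                env[i0:i1] = np.sqrt(1.0 - mod.depth)
        x += beta * env

        if config.theta_amp_uv > 0 and multi:
            delta = vonmises_marginal_process(n, fs, config.theta_kappa, rng)
            for ev in multi:
                s0 = ev.syllable_onsets_s[0]
                t0 = max(s0 - 0.5 / rate, 0.0)
                t1 = min(ev.offset_s + 0.05, duration_s)
                i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
                if i1 <= i0:
                    continue
                tt = np.arange(i0, i1) / fs
                phase = 2 * np.pi * rate * (tt - s0) + np.pi + delta[i0:i1]
                burst = config.theta_amp_uv * np.cos(phase)
                n_ramp = min(int(round(0.05 * fs)), burst.size // 2)
                if n_ramp > 0:
                    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
                    burst[:n_ramp] *= ramp
                    burst[-n_ramp:] *= ramp[::-1]
                x[i0:i1] += burst
        samples[ch] = x

    side = int(np.ceil(np.sqrt(n_channels)))
    xy = np.array([[0.5 * (i % side), 0.5 * (i // side)] for i in range(n_channels)])
    return LfpChannelSet(samples=samples, sample_rate_hz=fs, site_xy_mm=xy)
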