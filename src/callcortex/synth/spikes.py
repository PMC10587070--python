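"""Inhomogeneous-Poisson spike trains with peri-call window gains.

The firing rate of every unit is ``baseline * gain`` inside each of the
four peri-call analysis windows (early, pre, during, post — see
:class:`callcortex.synth.config.WindowGains`) of each call, and
``baseline`` elsewhere.  Sampling uses exact thinning, so a gain of 0
silences its window exactly.
"""

from __future__ import annotations

import numpy as np

from callcortex._rng import substream
from callcortex.errors import InvalidConfigError
from callcortex.synth.config import SynthConfig
from callcortex.types import CallEvent, SpikeTrainSet

__all__ = ["generate_spike_trains", "peri_call_windows", "rate_at"]


def peri_call_windows(event: CallEvent) -> dict[str, tuple[float, float]]:
    """Absolute (start, stop) of the four analysis windows for one call."""
    d = event.duration_s
    on = event.onset_s
    return {
        "early": (on - 2.0, on - 0.5),
        "pre": (on - 0.5, on),
        "during": (on, on + 0.8 * d),
        "post": (on + 0.8 * d, on + d + 0.5),
    }


def rate_at(
    times: np.ndarray,
    calls: list[CallEvent],
    config: SynthConfig,
) -> np.ndarray:
    """Exact instantaneous rate (Hz) at each query time.

    Later calls take precedence where extended windows of adjacent calls
    overlap (target calls themselves never overlap).
    """
    gains = np.ones_like(times, dtype=float)
    for ev in sorted(calls, key=lambda e: e.onset_s):
        wg = config.spike_gains.get(ev.call_type)
        if wg is None:
            continue
        for name, (lo, hi) in peri_call_windows(ev).items():
            g = getattr(wg, name)
            if g != 1.0:
                mask = (times >= lo) & (times < hi)
                gains[mask] = g
    return config.baseline_rate_hz * gains


def generate_spike_trains(
    calls: list[CallEvent],
    config: SynthConfig,
    seed: int | np.random.Generator,
    duration_s: float,
    n_units: int | None = None,
) -> SpikeTrainSet:
    """Thinning-based inhomogeneous Poisson sampler, one train per unit."""
    config.validate()
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be > 0")
    if n_units is None:
        n_units = config.n_units
    master = seed if isinstance(seed, np.random.Generator) else substream(seed, "spikes")
    child = master.spawn(n_units)

    max_gain = 1.0
    for wg in config.spike_gains.values():
        max_gain = max(max_gain, wg.early, wg.pre, wg.during, wg.post)
    rate_max = config.baseline_rate_hz * max_gain

    trains: dict[str, np.ndarray] = {}
    unit_channel: dict[str, int] = {}
    for u in range(n_units):
        rng = np.random.default_rng(child[u])
        n_cand = rng.poisson(rate_max * duration_s)
        cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
        keep = rng.uniform(0.0, rate_max, size=n_cand) < rate_at(cand, calls, config)
        times = np.unique(cand[keep])
        trains[f"u{u:03d}"] = times
        unit_channel[f"u{u:03d}"] = u % max(config.n_lfp_channels, 1)
    return SpikeTrainSet(trains=trains, unit_channel=unit_channel, duration_s=duration_s)
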