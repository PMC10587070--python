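"""Sync-pulse trains relating the audio and neural device clocks."""

from __future__ import annotations

import numpy as np

from callcortex._rng import substream
from callcortex.errors import ContractError
from callcortex.types import SyncPulseTrain

__all__ = ["generate_sync"]


def generate_sync(
    duration_s: float,
    drift_ppm: float = 0.0,
    seed: int | np.random.Generator = 0,
    period_s: float = 2.0,
    offset_s: float | None = None,
    jitter_s: float = 0.0,
) -> tuple[SyncPulseTrain, SyncPulseTrain]:
    """Generate matched pulse trains on the audio and neural clocks.

    The neural clock reads ``offset + (1 + drift_ppm * 1e-6) * t_audio``.
    ``offset_s=None`` draws a uniform offset in [0, 1) s; ``jitter_s``
    adds independent timestamping noise per pulse on each device.
    """
    if duration_s < period_s:
        raise ContractError("duration must cover at least one pulse period")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "sync")
    if offset_s is None:
        offset_s = float(rng.uniform(0.0, 1.0))
    audio = np.arange(0.0, duration_s, period_s)
    neural = offset_s + (1.0 + drift_ppm * 1e-6) * audio
    if jitter_s > 0:
        audio = audio + rng.normal(0.0, jitter_s, size=audio.size)
        neural = neural + rng.normal(0.0, jitter_s, size=neural.size)
    return (
        SyncPulseTrain(times=audio, nominal_period_s=period_s),
        SyncPulseTrain(times=neural, nominal_period_s=period_s),
    )
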