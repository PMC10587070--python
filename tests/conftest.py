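"""Shared fixtures: small synthetic recordings built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from callcortex.synth import SynthConfig
from callcortex.synth.calls import twitter_syllable_onsets
from callcortex.types import CallEvent, CallType


@pytest.fixture
def config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture
def null_config() -> SynthConfig:
    return SynthConfig.null()


def make_twitter(onset: float, duration: float = 0.8, rate: float = 7.0,
                 jitter: float = 0.0, rng: np.random.Generator | None = None) -> CallEvent:
    """A twitter event on a known syllable grid."""
    rel = twitter_syllable_onsets(duration, rate, jitter, 0.05, rng)
    return CallEvent(
        onset_s=onset,
        offset_s=onset + float(rel[-1]) + 0.05,
        call_type=CallType.TWITTER,
        syllable_onsets_s=[onset + float(t) for t in rel],
    )


def make_trills(n: int, start: float = 10.0, spacing: float = 8.0,
                duration: float = 0.5) -> list[CallEvent]:
    """Regularly spaced trill events with full baseline context."""
    return [
        CallEvent(onset_s=start + spacing * i, offset_s=start + spacing * i + duration,
                  call_type=CallType.TRILL)
        for i in range(n)
    ]


@pytest.fixture
def trill_events() -> list[CallEvent]:
    return make_trills(30)
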