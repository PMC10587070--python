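"""Shared data model.

All times are in seconds, zero-based from the start of the recording;
intervals are half-open ``[onset, offset)``.  Audio is stored as float
pressure waveforms in arbitrary units; LFP in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from callcortex.errors import ContractError

__all__ = [
    "CallType",
    "CallEvent",
    "AcousticScene",
    "LfpChannelSet",
    "SpikeTrainSet",
    "SyncPulseTrain",
]

#: Absolute slack (s) allowed when checking time-ordering invariants.
_TIME_EPS = 1e-9


class CallType(str, Enum):
    """The four major marmoset call types plus compound calls.

    phee      — long, loud, tone-like call with slow linear FM;
    trill     — short, soft call with sinusoidal FM;
    twitter   — wideband call of >=3 short upward FM sweeps (~7 Hz);
    trillphee — trill-like sinusoidal FM turning into phee-like linear FM;
    compound  — concatenation of heterogeneous simple-call syllables.
    """

    PHEE = "phee"
    TRILL = "trill"
    TWITTER = "twitter"
    TRILLPHEE = "trillphee"
    COMPOUND = "compound"


#: Call types whose syllable structure is analysed for phase locking.
MULTI_SYLLABLE_TYPES = (CallType.TWITTER, CallType.COMPOUND)


@dataclass
class CallEvent:
    """One detected or simulated vocalization.

    ``syllable_onsets_s`` lists the onset of every discrete phrase
    (syllable); the first entry equals ``onset_s``, which is time zero
    of all peri-event alignments ("vocal onset").
    """

    onset_s: float
    offset_s: float
    call_type: CallType
    syllable_onsets_s: list[float] = field(default_factory=list)
    is_target: bool = True

    def __post_init__(self) -> None:
        self.call_type = CallType(self.call_type)
        if not self.syllable_onsets_s:
            self.syllable_onsets_s = [self.onset_s]
        if not self.offset_s > self.onset_s:
            raise ContractError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )
        syl = np.asarray(self.syllable_onsets_s, dtype=float)
        if np.any(np.diff(syl) <= 0):
            raise ContractError("syllable onsets must be strictly increasing")
        if abs(syl[0] - self.onset_s) > _TIME_EPS:
            raise ContractError("first syllable onset must equal the call onset")
        if syl[-1] > self.offset_s + _TIME_EPS or syl[0] < self.onset_s - _TIME_EPS:
            raise ContractError("syllable onsets must lie within [onset, offset]")
        if self.call_type is CallType.TWITTER and len(syl) < 3:
            raise ContractError("a twitter call needs >= 3 syllables")
        if self.call_type is CallType.COMPOUND and len(syl) < 2:
            raise ContractError("a compound call needs >= 2 syllables")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def n_syllables(self) -> int:
        return len(self.syllable_onsets_s)

    def shifted(self, dt: float) -> "CallEvent":
        """Return a copy translated by ``dt`` seconds."""
        return CallEvent(
            onset_s=self.onset_s + dt,
            offset_s=self.offset_s + dt,
            call_type=self.call_type,
            syllable_onsets_s=[t + dt for t in self.syllable_onsets_s],
            is_target=self.is_target,
        )


@dataclass
class AcousticScene:
    """Paired parabolic/reference waveforms with (synthetic) ground truth."""

    parabolic: np.ndarray
    reference: np.ndarray
    sample_rate_hz: float = 48_000.0
    truth_target: list[CallEvent] = field(default_factory=list)
    truth_nontarget: list[CallEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parabolic = np.asarray(self.parabolic, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.parabolic.shape != self.reference.shape:
            raise ContractError("parabolic and reference channels must match in length")
        if self.parabolic.ndim != 1:
            raise ContractError("channels must be 1-D waveforms")

    @property
    def duration_s(self) -> float:
        return len(self.parabolic) / self.sample_rate_hz


@dataclass
class LfpChannelSet:
    """Multi-channel LFP (µV) at a constant sampling rate (default 1 kHz).

    ``site_xy_mm`` holds abstract 2-D electrode-array coordinates, one
    row per channel.
    """

    samples: np.ndarray  # (n_channels, n_samples)
    sample_rate_hz: float = 1000.0
    site_xy_mm: np.ndarray | None = None
    site_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(self.samples)):
            raise ContractError("LFP samples must be finite")
        if self.site_xy_mm is None:
            self.site_xy_mm = np.zeros((self.n_channels, 2))
        self.site_xy_mm = np.asarray(self.site_xy_mm, dtype=float)
        if self.site_xy_mm.shape != (self.n_channels, 2):
            raise ContractError("site_xy_mm needs one (x, y) pair per channel")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class SpikeTrainSet:
    """Sorted spike times (s) per unit, with a unit -> channel map."""

    trains: dict[str, np.ndarray]
    unit_channel: dict[str, int] = field(default_factory=dict)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for unit, times in self.trains.items():
            t = np.asarray(times, dtype=np.float64)
            if t.ndim != 1:
                raise ContractError(f"unit {unit}: spike times must be 1-D")
            if np.any(np.diff(t) <= 0):
                raise ContractError(f"unit {unit}: spike times must be strictly increasing")
            if self.duration_s is not None and t.size and (
                t[0] < 0 or t[-1] > self.duration_s
            ):
                raise ContractError(f"unit {unit}: spike times outside recording span")
            clean[str(unit)] = t
        self.trains = clean

    @property
    def units(self) -> list[str]:
        return list(self.trains)


@dataclass
class SyncPulseTrain:
    """Pulse times (s) on one device clock, nominally periodic."""

    times: np.ndarray
    nominal_period_s: float = 2.0
    drift_tolerance_s: float = 0.05

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size >= 2:
            diffs = np.diff(self.times)
            if np.any(np.abs(diffs - self.nominal_period_s) > self.drift_tolerance_s):
                raise ContractError(
                    "successive pulse intervals deviate from the nominal period "
                    "beyond the drift tolerance"
                )

    @property
    def n_pulses(self) -> int:
        return int(self.times.size)
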