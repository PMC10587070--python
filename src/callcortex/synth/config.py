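"""Generator configuration.

Defaults encode the study conditions: four call types with distinct
spectrotemporal structure (fundamental above 5 kHz), twitter syllables
repeating near 7 Hz, ~20 dB parabolic-channel gain for target calls,
type-specific beta-band suppression depth and start offset, trough-locked
theta with von Mises phase jitter, and per-window spike-rate gains.
Where the source figures give no number (per-type sound levels, LFP
effect sizes), the defaults are stated free parameters, not claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from callcortex.types import CallType
from callcortex.errors import InvalidConfigError

__all__ = ["SynthConfig", "BetaModulation", "WindowGains"]


@dataclass
class BetaModulation:
    """Call-locked suppression of the beta-band envelope.

    ``depth`` is the fractional drop in beta-band POWER (the amplitude
    envelope is multiplied by ``sqrt(1 - depth)``), so the analysis-side
    relative power during suppression has the closed form ``1 - depth``.
    ``start_offset_s`` is where suppression begins relative to vocal
    onset (negative = before); it ends at call offset.
    """

    depth: float = 0.0
    start_offset_s: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise InvalidConfigError(f"beta depth must be in [0, 1], got {self.depth}")


@dataclass
class WindowGains:
    """Multiplicative firing-rate gains in the four peri-call windows.

    Windows (relative to vocal onset, duration d): early (-2, -0.5) s,
    pre (-0.5, 0) s, during (0, 0.8 d), post (0.8 d, d + 0.5 s).
    Gain 1 = baseline rate; gains must be >= 0.
    """

    early: float = 1.0
    pre: float = 1.0
    during: float = 1.0
    post: float = 1.0

    def validate(self) -> None:
        for name, g in asdict(self).items():
            if g < 0:
                raise InvalidConfigError(f"spike gain {name!r} must be >= 0, got {g}")

    def as_dict(self) -> dict[str, float]:
        return {"early": self.early, "pre": self.pre, "during": self.during, "post": self.post}


def _default_rates() -> dict[CallType, float]:
    # calls/min; trills dominate captive repertoires, phees are sparse in
    # the colony setting.
    return {
        CallType.PHEE: 0.4,
        CallType.TRILL: 3.0,
        CallType.TWITTER: 0.8,
        CallType.TRILLPHEE: 0.6,
        CallType.COMPOUND: 0.0,
    }


def _default_durations() -> dict[CallType, tuple[float, float]]:
    # seconds (min, max); twitter/compound durations are re-derived from
    # their syllable grid so the annotated offset ends at acoustic offset.
    return {
        CallType.PHEE: (1.2, 2.5),
        CallType.TRILL: (0.3, 0.6),
        CallType.TWITTER: (0.6, 1.2),
        CallType.TRILLPHEE: (0.9, 1.6),
        CallType.COMPOUND: (1.0, 2.0),
    }


def _default_amplitudes() -> dict[CallType, float]:
    # relative pressure amplitude: phee loudest, trill softest.
    return {
        CallType.PHEE: 1.0,
        CallType.TRILL: 0.25,
        CallType.TWITTER: 0.6,
        CallType.TRILLPHEE: 0.8,
        CallType.COMPOUND: 0.6,
    }


def _default_beta() -> dict[CallType, BetaModulation]:
    # Depth (power fraction) and start offset (s) per type: phee deepest
    # and earliest (~0.5 s before onset), trill shallowest, trillphee
    # starting around the vocal onset.
    return {
        CallType.PHEE: BetaModulation(depth=0.5, start_offset_s=-0.5),
        CallType.TRILL: BetaModulation(depth=0.20, start_offset_s=-0.05),
        CallType.TWITTER: BetaModulation(depth=0.35, start_offset_s=-0.06),
        CallType.TRILLPHEE: BetaModulation(depth=0.45, start_offset_s=0.0),
        CallType.COMPOUND: BetaModulation(depth=0.3, start_offset_s=0.0),
    }


def _default_spike_gains() -> dict[CallType, WindowGains]:
    # Type-specific window gains give the decoder a real class signal:
    # trill-like pre-onset activation vs twitter-like during-suppression
    # with post-call rebound.
    return {
        CallType.PHEE: WindowGains(pre=1.5),
        CallType.TRILL: WindowGains(early=1.2, pre=2.0, during=1.5),
        CallType.TWITTER: WindowGains(during=0.5, post=2.0),
        CallType.TRILLPHEE: WindowGains(during=1.8, post=1.3),
        CallType.COMPOUND: WindowGains(),
    }


@dataclass
class SynthConfig:
    """All generator parameters; validated on construction."""

    # --- audio -----------------------------------------------------------
    sample_rate_audio_hz: float = 48_000.0
    call_rates_per_min: dict[CallType, float] = field(default_factory=_default_rates)
    duration_ranges_s: dict[CallType, tuple[float, float]] = field(
        default_factory=_default_durations
    )
    amplitudes: dict[CallType, float] = field(default_factory=_default_amplitudes)
    carrier_hz: float = 7500.0            # fundamental, above the 5 kHz floor
    phee_fm_slope_hz_per_s: float = 400.0  # slow linear FM
    trill_fm_rate_hz: float = 30.0         # sinusoidal FM rate
    trill_fm_depth_hz: float = 500.0       # sinusoidal FM depth
    twitter_sweep_lo_hz: float = 6000.0    # upward sweep start
    twitter_sweep_hi_hz: float = 11_000.0  # upward sweep end
    twitter_syllable_dur_s: float = 0.05
    twitter_syllable_rate_hz: float = 7.0
    twitter_syllable_jitter_s: float = 0.004
    edge_ramp_s: float = 0.005             # cosine on/off ramps
    target_gain_db: float = 20.0           # parabolic front gain for targets
    noise_rms: float = 0.003               # shared broadband room noise
    mic_noise_rms: float = 0.0005          # independent per-mic sensor noise
    min_call_gap_s: float = 0.25           # enforced between target calls

    # --- LFP -------------------------------------------------------------
    sample_rate_lfp_hz: float = 1000.0
    n_lfp_channels: int = 4
    pink_amp_uv: float = 10.0              # 1/f background RMS
    beta_amp_uv: float = 12.0              # beta-band narrowband noise RMS
    theta_amp_uv: float = 30.0             # call-locked theta burst amplitude
    beta: dict[CallType, BetaModulation] = field(default_factory=_default_beta)
    theta_kappa: float = 4.0               # von Mises concentration of
                                           # syllable phase about the trough

    # --- spikes ----------------------------------------------------------
    n_units: int = 8
    baseline_rate_hz: float = 5.0
    spike_gains: dict[CallType, WindowGains] = field(default_factory=_default_spike_gains)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ct, r in self.call_rates_per_min.items():
            if r < 0:
                raise InvalidConfigError(f"call rate for {ct} must be >= 0, got {r}")
        for ct, (lo, hi) in self.duration_ranges_s.items():
            if not 0 < lo <= hi:
                raise InvalidConfigError(f"bad duration range for {ct}: ({lo}, {hi})")
        if self.twitter_syllable_rate_hz <= 0:
            raise InvalidConfigError("twitter syllable rate must be > 0")
        if self.theta_kappa < 0:
            raise InvalidConfigError("theta kappa must be >= 0")
        if self.baseline_rate_hz <= 0:
            raise InvalidConfigError("baseline spike rate must be > 0")
        for mod in self.beta.values():
            mod.validate()
        for gains in self.spike_gains.values():
            gains.validate()

    # -- convenience constructors ----------------------------------------

    @classmethod
    def null(cls, **overrides) -> "SynthConfig":
        """A null generator: no LFP modulation, all spike gains 1.

        Used for type-I-error calibration; call statistics keep their
        defaults unless overridden.
        """
        cfg = cls(**overrides)
        cfg.beta = {ct: BetaModulation(0.0, 0.0) for ct in CallType}
        cfg.spike_gains = {ct: WindowGains() for ct in CallType}
        return cfg

    def max_instantaneous_freq_hz(self) -> float:
        return max(
            self.carrier_hz
            + self.phee_fm_slope_hz_per_s * max(hi for _, hi in self.duration_ranges_s.values()),
            self.carrier_hz + self.trill_fm_depth_hz,
            self.twitter_sweep_hi_hz,
        )
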