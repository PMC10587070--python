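"""Phase locking of syllable onsets to band-limited LFP oscillations.

Phase convention: the analytic phase of a cosine, so a pure cosine has
phase 0 at its peaks and pi at its troughs; syllables locked "near the
trough" therefore cluster around pi.  Locking strength is the vector
strength VS = |mean of unit phasors|; circular uniformity is tested by
the Rayleigh statistic 2*n*VS**2, which is asymptotically chi-squared
with 2 df under the null — its 0.001 critical value is 13.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from callcortex.errors import ContractError, EmptyInputError
from callcortex.types import LfpChannelSet

log = logging.getLogger(__name__)

__all__ = [
    "SyllablePhaseSet",
    "PhaseLockResult",
    "instantaneous_phase",
    "phases_at_onsets",
    "vector_strength",
    "rayleigh_test",
    "phase_lock_analysis",
    "phase_histogram",
    "DEFAULT_PHASE_BAND",
]

DEFAULT_PHASE_BAND = (5.0, 10.0)


def _wrap(phases: np.ndarray) -> np.ndarray:
    """Wrap to [-pi, pi)."""
    return np.mod(phases + np.pi, 2 * np.pi) - np.pi


@dataclass
class SyllablePhaseSet:
    """Oscillation phase at each syllable onset for one site."""

    phases: np.ndarray  # wrapped to [-pi, pi)
    site: str = ""

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(self.phases)):
            raise ContractError("phases must be finite")
        self.phases = _wrap(self.phases)

    @property
    def n(self) -> int:
        return int(self.phases.size)


@dataclass
class PhaseLockResult:
    vs: float
    rayleigh: float
    p: float
    n: int
    mean_phase: float
    site: str = ""

    @property
    def significant(self) -> bool:
        """p < 0.001, equivalently Rayleigh statistic > 13.8."""
        return self.p < 0.001


def instantaneous_phase(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_PHASE_BAND,
) -> np.ndarray:
    """Zero-phase band-pass then analytic-signal angle, wrapped."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ContractError(f"band {band} invalid for fs={fs}")
    from scipy.fft import next_fast_len

    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(x, dtype=float))
    pad = int(round(1.0 * fs))
    padded = np.pad(filt, pad, mode="reflect")
    analytic = signal.hilbert(padded, N=next_fast_len(padded.size))[pad : pad + filt.size]
    return _wrap(np.angle(analytic))


def phases_at_onsets(
    phase: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    site: str = "",
) -> SyllablePhaseSet:
    """Nearest-sample phase at each syllable onset."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size == 0:
        return SyllablePhaseSet(phases=np.array([]), site=site)
    idx = np.round(onsets_s * fs).astype(int)
    ok = (idx >= 0) & (idx < phase.size)
    if not ok.all():
        log.info("phases_at_onsets: dropped %d onsets outside recording", (~ok).sum())
    return SyllablePhaseSet(phases=phase[idx[ok]], site=site)


def vector_strength(phases: SyllablePhaseSet | np.ndarray) -> float:
    """Mean resultant length of the unit phasors; in [0, 1]."""
    ph = phases.phases if isinstance(phases, SyllablePhaseSet) else np.asarray(phases)
    if ph.size == 0:
        raise EmptyInputError("vector strength undefined for n = 0")
    return float(np.abs(np.mean(np.exp(1j * ph))))


def rayleigh_test(phases: SyllablePhaseSet | np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Statistic 2*n*VS**2; p from the asymptotic chi-squared(2) tail.
    (For very small n this tail is slightly anti-conservative; the
    analyses here use n in the hundreds-to-thousands.)
    """
    ph = phases.phases if isinstance(phases, SyllablePhaseSet) else np.asarray(phases)
    if ph.size < 2:
        raise ContractError("Rayleigh test needs n >= 2")
    vs = float(np.abs(np.mean(np.exp(1j * ph))))
    statistic = 2.0 * ph.size * vs**2
    p = float(stats.chi2.sf(statistic, df=2))
    return statistic, p


def phase_lock_analysis(
    lfp: LfpChannelSet,
    syllable_onsets_s: np.ndarray,
    channel: int,
    band: tuple[float, float] = DEFAULT_PHASE_BAND,
    site: str | None = None,
) -> PhaseLockResult:
    """End to end: filter one channel, read phases at onsets, test."""
    site = site if site is not None else f"ch{channel}"
    phase = instantaneous_phase(lfp.samples[channel], lfp.sample_rate_hz, band)
    pset = phases_at_onsets(phase, lfp.sample_rate_hz, syllable_onsets_s, site=site)
    if pset.n == 0:
        raise EmptyInputError("no syllable onsets within the recording")
    vs = vector_strength(pset)
    statistic, p = rayleigh_test(pset)
    mean_phase = float(np.angle(np.mean(np.exp(1j * pset.phases))))
    return PhaseLockResult(vs=vs, rayleigh=statistic, p=p, n=pset.n,
                           mean_phase=mean_phase, site=site)


def phase_histogram(
    phases: SyllablePhaseSet, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram over [-pi, pi) (default 18 bins of 20 degrees)."""
    counts, edges = np.histogram(phases.phases, bins=n_bins, range=(-np.pi, np.pi))
    return counts, edges
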