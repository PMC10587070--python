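"""Trial-aligned LFP band power: suppression tests, start times, profiles.

Pipeline per site and call type: zero-phase band-pass (4th-order
Butterworth, forward-backward) -> analytic amplitude via Hilbert
transform (1 s reflected edge padding) -> power -> downsample to 200 Hz
-> per-trial normalization by the mean over the baseline window
[-3, -1] s before vocal onset.  A window is "significantly modulated"
when the per-trial window means differ from the per-trial baseline
means (two-sided signed-rank) AND the trial-averaged window mean is
more than two bootstrap standard deviations away from baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import PCA

from callcortex._rng import as_generator
from callcortex.errors import (
    ContractError,
    DegenerateInputError,
    EmptyInputError,
)
from callcortex.types import CallEvent, LfpChannelSet

log = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "BETA",
    "THETA",
    "PHASE_BAND",
    "TrialAlignedPower",
    "ModulationTestResult",
    "StartTimeResult",
    "BetaProfileEmbedding",
    "band_power_timecourse",
    "morlet_tfr",
    "bootstrap_baseline_sd",
    "test_window_modulation",
    "find_modulation_start_time",
    "compare_across_call_types",
    "beta_profile",
    "embed_beta_profiles",
    "within_between_distance",
    "extract_peak_features",
]

BASELINE_WINDOW = (-3.0, -1.0)
POWER_RATE_HZ = 200.0
#: The four analysis windows used for modulation and start-time search.
ONSET_WINDOW = (-0.1, 0.2)
EXTRA_WINDOWS = ((-0.5, 0.0), (0.3, 0.9))  # plus the per-trial call duration


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band (Hz)."""

    name: str
    low_hz: float
    high_hz: float

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise ContractError(f"band {self} invalid for fs={fs}")


BETA = BandDefinition("beta", 12.0, 30.0)
THETA = BandDefinition("theta", 4.0, 8.0)
PHASE_BAND = BandDefinition("phase", 5.0, 10.0)


@dataclass
class TrialAlignedPower:
    """Per-trial baseline-normalised band power at 200 Hz.

    ``values[i]`` has mean exactly 1 over the baseline window; time 0 is
    the vocal onset of trial i.
    """

    values: np.ndarray          # (n_trials, n_times)
    times_s: np.ndarray         # relative to vocal onset
    durations_s: np.ndarray     # call duration per trial
    band: BandDefinition
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window
        return (self.times_s >= lo) & (self.times_s < hi)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        m = (self.times_s >= lo) & (self.times_s < hi)
        if not m.any():
            raise ContractError(f"window {window} outside the time axis")
        return m

    def mean_trace(self) -> np.ndarray:
        return self.values.mean(axis=0)


def _analytic(filt: np.ndarray, fs: float) -> np.ndarray:
    """Analytic signal with 1 s reflected edge padding (FFT-fast length)."""
    from scipy.fft import next_fast_len

    pad = int(round(1.0 * fs))
    padded = np.pad(filt, pad, mode="reflect")
    nfast = next_fast_len(padded.size)
    return signal.hilbert(padded, N=nfast)[pad : pad + filt.size]


def band_limited_power(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Band-pass -> analytic amplitude -> instantaneous power, full trace."""
    band.validate(fs)
    sos = signal.butter(4, (band.low_hz, band.high_hz), btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    return np.abs(_analytic(filt, fs)) ** 2


def _downsample_power(power: np.ndarray, fs: float, out_rate: float) -> np.ndarray:
    q = fs / out_rate
    if abs(q - round(q)) > 1e-9:
        raise ContractError(f"fs={fs} not an integer multiple of {out_rate} Hz")
    q = int(round(q))
    n = (power.size // q) * q
    return power[:n].reshape(-1, q).mean(axis=1)


def band_power_timecourse(
    lfp: LfpChannelSet,
    events: list[CallEvent],
    channel: int,
    band: BandDefinition = BETA,
    window: tuple[float, float] = (-3.5, 3.5),
    min_duration_s: float = 0.2,
) -> TrialAlignedPower:
    """Trial-aligned, baseline-normalised band-power time courses.

    Calls shorter than ``min_duration_s`` (200 ms) and calls without
    full epoch context inside the recording are excluded (logged).
    """
    fs = lfp.sample_rate_hz
    power = _downsample_power(band_limited_power(lfp.samples[channel], fs, band), fs, POWER_RATE_HZ)
    r = POWER_RATE_HZ
    i_lo, i_hi = int(round(window[0] * r)), int(round(window[1] * r))
    times = np.arange(i_lo, i_hi) / r

    rows, durations = [], []
    n_excluded = 0
    for ev in events:
        if ev.duration_s < min_duration_s:
            n_excluded += 1
            continue
        i_on = int(round(ev.onset_s * r))
        a, b = i_on + i_lo, i_on + i_hi
        if a < 0 or b > power.size:
            n_excluded += 1
            continue
        rows.append(power[a:b])
        durations.append(ev.duration_s)
    if not rows:
        raise EmptyInputError("all trials excluded")
    if n_excluded:
        log.info("band_power_timecourse: excluded %d of %d trials", n_excluded, len(events))

    values = np.asarray(rows)
    bmask = (times >= BASELINE_WINDOW[0]) & (times < BASELINE_WINDOW[1])
    base = values[:, bmask].mean(axis=1, keepdims=True)
    values = values / base
    return TrialAlignedPower(
        values=values,
        times_s=times,
        durations_s=np.asarray(durations),
        band=band,
        n_excluded=n_excluded,
    )


def morlet_tfr(
    lfp: LfpChannelSet,
    events: list[CallEvent],
    channel: int,
    freqs_hz: np.ndarray | None = None,
    window: tuple[float, float] = (-3.5, 3.5),
    n_cycles: float = 7.0,
    decim: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-normalised Morlet time-frequency power, trial-averaged.

    Morlet wavelets with a width (number of cycles) of 7; each frequency
    row is divided by its own mean over the baseline window.  Returns
    (power_ratio [n_freqs, n_times], times_s, freqs_hz).
    """
    from mne.time_frequency import tfr_array_morlet

    fs = lfp.sample_rate_hz
    if freqs_hz is None:
        freqs_hz = np.arange(4.0, 61.0, 2.0)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if window[0] > BASELINE_WINDOW[0]:
        raise ContractError("epoch window must include the [-3, -1] s baseline")

    i_lo, i_hi = int(round(window[0] * fs)), int(round(window[1] * fs))
    x = lfp.samples[channel]
    epochs, kept = [], 0
    for ev in events:
        i_on = int(round(ev.onset_s * fs))
        a, b = i_on + i_lo, i_on + i_hi
        if a < 0 or b > x.size:
            log.info("morlet_tfr: trial at %.2fs dropped (recording edge)", ev.onset_s)
            continue
        epochs.append(x[a:b])
        kept += 1
    if not epochs:
        raise EmptyInputError("no trials with full epoch context")
    data = np.asarray(epochs)[:, None, :]  # (n_trials, 1 ch, n_times)
    power = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs_hz, n_cycles=n_cycles, output="avg_power",
        decim=decim, verbose="error",
    )[0]  # (n_freqs, n_times)
    times = (np.arange(i_lo, i_hi) / fs)[::decim]
    bmask = (times >= BASELINE_WINDOW[0]) & (times < BASELINE_WINDOW[1])
    power /= power[:, bmask].mean(axis=1, keepdims=True)
    return power, times, freqs_hz


def bootstrap_baseline_sd(
    power: TrialAlignedPower,
    n_draw: int = 200,
    segment_s: float = 0.2,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap SD of segment-averaged baseline power of the mean trace.

    Each rep draws ``n_draw`` trials (without replacement when enough
    trials exist, with replacement otherwise), averages their baseline
    power trace, cuts it into non-overlapping ``segment_s`` windows, and
    takes the SD of the segment means; the reps are averaged.
    """
    rng = as_generator(seed)
    bmask = power.baseline_mask()
    base = power.values[:, bmask]
    n_seg_samples = int(round(segment_s * POWER_RATE_HZ))
    n_seg = base.shape[1] // n_seg_samples
    if n_seg < 1:
        raise ContractError("baseline window shorter than one segment")
    # Segment-averaging the trial-averaged trace equals trial-averaging
    # the per-trial segment means, so precompute the latter.
    seg = base[:, : n_seg * n_seg_samples].reshape(power.n_trials, n_seg, n_seg_samples)
    seg_means = seg.mean(axis=2)  # (n_trials, n_seg)
    n_trials = power.n_trials
    replace = n_trials < n_draw
    sds = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(n_trials, size=n_draw, replace=replace)
        sds[r] = seg_means[idx].mean(axis=0).std(ddof=1)
    return float(sds.mean())


@dataclass
class ModulationTestResult:
    """Outcome of the combined signed-rank + 2-SD window test."""

    window: tuple[float, float]
    median_power: float
    p: float
    baseline_sd: float
    passes_2sd: bool
    significant: bool
    direction: str  # "suppression" | "activation" | "none"
    degenerate: bool = False
    n_trials: int = 0


def _signed_rank(diffs: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired differences."""
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0, True
    return float(stats.wilcoxon(nz, alternative="two-sided").pvalue), False


def test_window_modulation(
    power: TrialAlignedPower,
    window: tuple[float, float],
    sd: float,
    alpha: float = 0.05,
) -> ModulationTestResult:
    """Signed-rank + 2-SD test of one analysis window against baseline."""
    wmask = power.window_mask(window)
    bmask = power.baseline_mask()
    w = power.values[:, wmask].mean(axis=1)
    b = power.values[:, bmask].mean(axis=1)  # == 1 per trial by construction
    p, degenerate = _signed_rank(w - b)
    avg_diff = float(w.mean() - b.mean())
    passes = bool(abs(avg_diff) > 2.0 * sd)
    significant = bool((p < alpha) and passes and not degenerate)
    med_diff = float(np.median(w) - np.median(b))
    direction = "none"
    if significant:
        direction = "suppression" if med_diff < 0 else "activation"
    return ModulationTestResult(
        window=window,
        median_power=float(np.median(w)),
        p=p,
        baseline_sd=sd,
        passes_2sd=passes,
        significant=significant,
        direction=direction,
        degenerate=degenerate,
        n_trials=power.n_trials,
    )


@dataclass
class StartTimeResult:
    """Earliest 100 ms window with significant modulation (midpoint)."""

    start_time_s: float
    direction: str
    found: bool


def default_search_span(power: TrialAlignedPower) -> tuple[float, float]:
    """Union of the four analysis windows: [-0.5, 0] + onset window +
    call duration + [0.3, 0.9] s (contiguous for >=0.2 s calls)."""
    dur = float(np.median(power.durations_s)) if power.durations_s.size else 0.0
    lo = min(EXTRA_WINDOWS[0][0], ONSET_WINDOW[0])
    hi = max(EXTRA_WINDOWS[1][1], ONSET_WINDOW[1], dur)
    return lo, hi


def find_modulation_start_time(
    power: TrialAlignedPower,
    sd: float,
    direction: str,
    span: tuple[float, float] | None = None,
    window_len_s: float = 0.1,
    step_s: float = 0.005,
    alpha: float = 0.05,
) -> StartTimeResult:
    """Slide a 100 ms window over the analysis span; return the midpoint
    of the earliest window that is signed-rank significant, >2 SD from
    baseline, and modulated in the given direction."""
    if direction not in ("suppression", "activation"):
        raise ContractError("direction must be fixed ('suppression'/'activation')")
    if span is None:
        span = default_search_span(power)
    sign = -1.0 if direction == "suppression" else 1.0
    bmask = power.baseline_mask()
    b = power.values[:, bmask].mean(axis=1)
    b_avg = float(b.mean())

    r = POWER_RATE_HZ
    n_win = int(round(window_len_s * r))
    step = max(int(round(step_s * r)), 1)
    # cumulative sum along time for fast window means
    csum = np.cumsum(power.values, axis=1)
    i0_first = int(np.searchsorted(power.times_s, span[0] - 1e-9))
    i0_last = int(np.searchsorted(power.times_s, span[1] - window_len_s + 1e-9))
    for i0 in range(i0_first, i0_last + 1, step):
        i1 = i0 + n_win
        if i1 > power.values.shape[1]:
            break
        w = (csum[:, i1 - 1] - (csum[:, i0 - 1] if i0 > 0 else 0.0)) / n_win
        diff = float(w.mean() - b_avg)
        if sign * diff <= 0 or abs(diff) <= 2.0 * sd:
            continue
        med = float(np.median(w - b))
        if sign * med <= 0:
            continue
        p, degenerate = _signed_rank(w - b)
        if not degenerate and p < alpha:
            mid = float(power.times_s[i0] + window_len_s / 2.0)
            return StartTimeResult(start_time_s=mid, direction=direction, found=True)
    return StartTimeResult(start_time_s=np.nan, direction=direction, found=False)


@dataclass
class CrossTypeComparison:
    """Kruskal-Wallis omnibus + Bonferroni-adjusted pairwise rank-sums."""

    h_statistic: float
    p: float
    pairwise_p: dict[tuple[str, str], float]


def compare_across_call_types(samples_by_type: dict[str, np.ndarray]) -> CrossTypeComparison:
    """Rank-based omnibus comparison of per-trial window powers."""
    groups = {k: np.asarray(v, dtype=float) for k, v in samples_by_type.items()}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ContractError("need >= 2 call types with >= 2 trials each")
    h, p = stats.kruskal(*groups.values())
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        _, praw = stats.ranksums(groups[a], groups[b])
        pairwise[(a, b)] = min(praw * m, 1.0)
    return CrossTypeComparison(h_statistic=float(h), p=float(p), pairwise_p=pairwise)


PROFILE_WINDOW = (-1.5, 2.5)
PROFILE_RATE_HZ = 10.0


def beta_profile(power: TrialAlignedPower) -> np.ndarray:
    """Trial-averaged relative-power profile in [-1.5, 2.5] s at 10 Hz."""
    mask = power.window_mask(PROFILE_WINDOW)
    trace = power.mean_trace()[mask]
    q = int(round(POWER_RATE_HZ / PROFILE_RATE_HZ))
    n = (trace.size // q) * q
    return trace[:n].reshape(-1, q).mean(axis=1)


@dataclass
class BetaProfileEmbedding:
    """Projection of (site, call-type) power profiles onto 3 PCs."""

    projections: np.ndarray        # (n_profiles, 3)
    explained_variance: np.ndarray  # fractions, non-increasing
    labels: list[str] = field(default_factory=list)
    sites: list[str] = field(default_factory=list)


def embed_beta_profiles(
    profiles: np.ndarray,
    labels: list[str],
    sites: list[str] | None = None,
    n_components: int = 3,
) -> BetaProfileEmbedding:
    """PCA of pooled per-(site, type) temporal profiles."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 4:
        raise ContractError("need >= 4 profiles for the embedding")
    if np.allclose(profiles.std(axis=0), 0.0):
        raise DegenerateInputError("profiles have no variance")
    n_components = min(n_components, profiles.shape[0] - 1, profiles.shape[1])
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(profiles)
    return BetaProfileEmbedding(
        projections=proj,
        explained_variance=pca.explained_variance_ratio_,
        labels=list(labels),
        sites=list(sites) if sites is not None else [""] * profiles.shape[0],
    )


def within_between_distance(
    embedding: BetaProfileEmbedding,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Pairwise Euclidean distances split within/between call type.

    Returns (within, between, rank-sum z, two-sided p).
    """
    from scipy.spatial.distance import pdist, squareform

    labels = embedding.labels
    if len(set(labels)) < 2:
        raise ContractError("need >= 2 call types")
    dmat = squareform(pdist(embedding.projections))
    n = len(labels)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(dmat[i, j])
    for lab in set(labels):
        if labels.count(lab) < 2:
            log.info("type %s has one member: no within-type pairs", lab)
    z, p = stats.ranksums(np.asarray(within), np.asarray(between))
    return np.asarray(within), np.asarray(between), float(z), float(p)


@dataclass
class PeakFeatures:
    magnitude: float
    time_s: float
    degenerate: bool = False


def extract_peak_features(
    power: TrialAlignedPower,
    direction: str,
    window: tuple[float, float] = PROFILE_WINDOW,
) -> PeakFeatures:
    """Extremum of the trial-averaged relative power and its time."""
    mask = power.window_mask(window)
    trace = power.mean_trace()[mask]
    times = power.times_s[mask]
    if np.ptp(trace) < 1e-12:
        return PeakFeatures(magnitude=float(trace[0]), time_s=np.nan, degenerate=True)
    idx = int(np.argmin(trace)) if direction == "suppression" else int(np.argmax(trace))
    return PeakFeatures(magnitude=float(trace[idx]), time_s=float(times[idx]))
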