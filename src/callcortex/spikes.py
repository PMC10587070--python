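"""Single-neuron firing-rate modulation around vocal onset.

Spikes are re-referenced to each vocal onset over a [-10, +10] s span,
binned at 50 ms, and z-scored per trial over the full 20 s span.  Rates
in four analysis windows — early (-2, -0.5) s, pre (-0.5, 0) s, during
(0, 0.8 d), post (0.8 d, d + 0.5) s with d the per-trial call duration —
are compared against the baseline window (-8, -4) s by a two-sided
signed-rank test combined with a 2-SD criterion (bootstrap SD of the
baseline using 500 ms segments).  A unit is "tested" for a call type
only when >= 15 calls survive the exclusions; "modulated" when any
window is significant.  Circular-shift shuffles provide the null
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from callcortex._rng import as_generator
from callcortex.errors import ContractError
from callcortex.types import CallEvent, SpikeTrainSet

log = logging.getLogger(__name__)

__all__ = [
    "ANALYSIS_WINDOW_NAMES",
    "RASTER_SPAN",
    "BASELINE_WINDOW",
    "MIN_CALLS_TESTED",
    "Raster",
    "NormalizedRateProfile",
    "WindowOutcome",
    "NeuronModulationProfile",
    "build_raster",
    "normalize_rates",
    "bootstrap_baseline_rate_sd",
    "test_spike_modulation",
    "shuffle_control",
    "tally_modulation",
    "venn_difference_proportion",
    "TallyResult",
]

ANALYSIS_WINDOW_NAMES = ("early", "pre", "during", "post")
RASTER_SPAN = (-10.0, 10.0)
BASELINE_WINDOW = (-8.0, -4.0)
MIN_CALLS_TESTED = 15
BIN_S = 0.05


def window_bounds(name: str, duration_s: float) -> tuple[float, float]:
    """Analysis-window bounds (s relative to vocal onset) for one trial."""
    d = duration_s
    return {
        "early": (-2.0, -0.5),
        "pre": (-0.5, 0.0),
        "during": (0.0, 0.8 * d),
        "post": (0.8 * d, d + 0.5),
    }[name]


@dataclass
class Raster:
    """Peri-event spike times, one row per surviving call."""

    trials: list[np.ndarray]       # spike times relative to vocal onset
    durations_s: np.ndarray        # call duration per trial
    span: tuple[float, float] = RASTER_SPAN
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def build_raster(
    spikes: SpikeTrainSet,
    events: list[CallEvent],
    unit: str,
    span: tuple[float, float] = RASTER_SPAN,
    min_duration_s: float = 0.2,
) -> Raster:
    """Align one unit's spikes to each vocal onset.

    Calls shorter than ``min_duration_s`` (200 ms) are excluded; whether
    a unit reaches the 15-call testing threshold is decided downstream.
    """
    times = spikes.trains[unit]
    trials, durations = [], []
    n_excluded = 0
    for ev in sorted(events, key=lambda e: e.onset_s):
        if ev.duration_s < min_duration_s:
            n_excluded += 1
            continue
        lo, hi = ev.onset_s + span[0], ev.onset_s + span[1]
        seg = times[np.searchsorted(times, lo) : np.searchsorted(times, hi)]
        trials.append(seg - ev.onset_s)
        durations.append(ev.duration_s)
    if n_excluded:
        log.info("build_raster[%s]: excluded %d short calls", unit, n_excluded)
    return Raster(
        trials=trials,
        durations_s=np.asarray(durations),
        span=span,
        n_excluded=n_excluded,
    )


@dataclass
class NormalizedRateProfile:
    """Per-trial z-scored binned firing rates (50 ms bins)."""

    z: np.ndarray                # (n_trials, n_bins)
    bin_centers_s: np.ndarray
    durations_s: np.ndarray
    bin_s: float = BIN_S
    degenerate_trials: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.z.mean(axis=0)

    def sem_trace(self) -> np.ndarray:
        return self.z.std(axis=0, ddof=1) / np.sqrt(self.n_trials)

    def window_means(self, name: str) -> np.ndarray:
        """Per-trial mean z over one (duration-dependent) window."""
        out = np.empty(self.n_trials)
        for i, d in enumerate(self.durations_s):
            lo, hi = window_bounds(name, float(d))
            m = (self.bin_centers_s >= lo) & (self.bin_centers_s < hi)
            out[i] = self.z[i, m].mean() if m.any() else 0.0
        return out

    def baseline_means(self) -> np.ndarray:
        lo, hi = BASELINE_WINDOW
        m = (self.bin_centers_s >= lo) & (self.bin_centers_s < hi)
        return self.z[:, m].mean(axis=1)


def normalize_rates(raster: Raster, bin_s: float = BIN_S) -> NormalizedRateProfile:
    """Bin each trial at 50 ms and z-score it over the whole 20 s span.

    Zero-variance trials (e.g. a silent unit) get z = 0 and are flagged
    rather than dropped, so trial counts keep matching call counts.
    """
    if raster.n_trials < 1:
        raise ContractError("raster has no trials")
    lo, hi = raster.span
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    z = np.empty((raster.n_trials, centers.size))
    degenerate = []
    for i, spikes_rel in enumerate(raster.trials):
        rate = np.histogram(spikes_rel, bins=edges)[0] / bin_s
        sd = rate.std()
        if sd == 0:
            z[i] = 0.0
            degenerate.append(i)
        else:
            z[i] = (rate - rate.mean()) / sd
    return NormalizedRateProfile(
        z=z,
        bin_centers_s=centers,
        durations_s=raster.durations_s,
        bin_s=bin_s,
        degenerate_trials=np.asarray(degenerate, dtype=int),
    )


def bootstrap_baseline_rate_sd(
    profile: NormalizedRateProfile,
    segment_s: float = 0.5,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    n_draw: int | None = None,
) -> float:
    """Bootstrap SD of segment-averaged baseline z of the mean trace.

    Mirrors the LFP procedure with 500 ms segments; draws are with
    replacement, capped at the available trial count.
    """
    rng = as_generator(seed)
    lo, hi = BASELINE_WINDOW
    m = (profile.bin_centers_s >= lo) & (profile.bin_centers_s < hi)
    base = profile.z[:, m]
    n_per_seg = int(round(segment_s / profile.bin_s))
    n_seg = base.shape[1] // n_per_seg
    if n_seg < 1:
        raise ContractError("baseline window shorter than one segment")
    seg_means = base[:, : n_seg * n_per_seg].reshape(
        profile.n_trials, n_seg, n_per_seg
    ).mean(axis=2)
    if n_draw is None:
        n_draw = profile.n_trials
    idx = rng.integers(0, profile.n_trials, size=(reps, n_draw))
    sds = seg_means[idx].mean(axis=1).std(axis=1, ddof=1)
    return float(sds.mean())


@dataclass
class WindowOutcome:
    direction: str       # "activated" | "suppressed" | "none"
    p: float
    passes_2sd: bool
    significant: bool
    mean_z: float


@dataclass
class NeuronModulationProfile:
    """Per-window modulation verdicts for one (unit, call type)."""

    unit: str
    call_type: str
    n_trials: int
    tested: bool
    windows: dict[str, WindowOutcome] = field(default_factory=dict)
    baseline_sd: float = np.nan

    @property
    def modulated(self) -> bool:
        return self.tested and any(w.significant for w in self.windows.values())

    def significant_windows(self) -> frozenset[str]:
        return frozenset(k for k, w in self.windows.items() if w.significant)

    def directions(self) -> dict[str, str]:
        return {k: w.direction for k, w in self.windows.items()}

    @property
    def overall_direction(self) -> str:
        """'activated'/'suppressed' from the earliest significant window."""
        for name in ANALYSIS_WINDOW_NAMES:
            w = self.windows.get(name)
            if w is not None and w.significant:
                return w.direction
        return "none"


def _signed_rank(diffs: np.ndarray) -> tuple[float, bool]:
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0, True
    return float(stats.wilcoxon(nz, alternative="two-sided").pvalue), False


def test_spike_modulation(
    profile: NormalizedRateProfile,
    unit: str = "",
    call_type: str = "",
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    sd_reps: int = 1000,
    min_calls: int = MIN_CALLS_TESTED,
) -> NeuronModulationProfile:
    """Combined signed-rank + 2-SD test in all four analysis windows."""
    n = profile.n_trials
    if n < min_calls:
        return NeuronModulationProfile(
            unit=unit, call_type=call_type, n_trials=n, tested=False
        )
    sd = bootstrap_baseline_rate_sd(profile, reps=sd_reps, seed=seed)
    base = profile.baseline_means()
    windows: dict[str, WindowOutcome] = {}
    for name in ANALYSIS_WINDOW_NAMES:
        w = profile.window_means(name)
        p, degenerate = _signed_rank(w - base)
        diff = float(w.mean() - base.mean())
        passes = bool(abs(diff) > 2.0 * sd)
        significant = bool(p < alpha and passes and not degenerate)
        direction = "none"
        if significant:
            direction = "suppressed" if np.median(w - base) < 0 else "activated"
        windows[name] = WindowOutcome(
            direction=direction, p=p, passes_2sd=passes,
            significant=significant, mean_z=float(w.mean()),
        )
    return NeuronModulationProfile(
        unit=unit, call_type=call_type, n_trials=n, tested=True,
        windows=windows, baseline_sd=sd,
    )


def shuffle_control(
    raster: Raster,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    sd_reps: int = 200,
) -> dict[str, float]:
    """Expected per-window modulation proportions under the null.

    Each rep circularly shifts every trial's spikes by an independent
    uniform offset over the raster span and re-runs the full test;
    returns the fraction of reps flagging each window.
    """
    if raster.n_trials == 0:
        raise ContractError("raster is empty")
    rng = as_generator(seed)
    lo, hi = raster.span
    span_len = hi - lo
    flagged = {name: 0 for name in ANALYSIS_WINDOW_NAMES}
    for _ in range(reps):
        shifts = rng.uniform(0.0, span_len, size=raster.n_trials)
        shifted = [
            np.sort(((t - lo + s) % span_len) + lo)
            for t, s in zip(raster.trials, shifts)
        ]
        sh_raster = Raster(
            trials=shifted, durations_s=raster.durations_s, span=raster.span
        )
        prof = normalize_rates(sh_raster)
        result = test_spike_modulation(prof, seed=rng, alpha=alpha, sd_reps=sd_reps)
        for name in ANALYSIS_WINDOW_NAMES:
            if result.tested and result.windows[name].significant:
                flagged[name] += 1
    return {name: count / reps for name, count in flagged.items()}


@dataclass
class TallyResult:
    """Venn bookkeeping for neurons tested on two call types."""

    a_only: int
    b_only: int
    both_same: int
    both_different: int
    n_tested_both: int

    @property
    def modulated(self) -> int:
        return self.a_only + self.b_only + self.both_same + self.both_different

    @property
    def difference_proportion(self) -> float:
        """(A-only + B-only + both-different) / modulated."""
        if self.modulated == 0:
            return np.nan
        return (self.a_only + self.b_only + self.both_different) / self.modulated


def venn_difference_proportion(
    a_only: int, b_only: int, both: int, both_different: int
) -> float:
    """Worked-example arithmetic on printed Venn counts."""
    modulated = a_only + b_only + both
    if modulated == 0:
        return np.nan
    return (a_only + b_only + both_different) / modulated


def tally_modulation(
    profiles_a: dict[str, NeuronModulationProfile],
    profiles_b: dict[str, NeuronModulationProfile],
) -> TallyResult:
    """Count A-only / B-only / both-same / both-different neurons.

    Only neurons tested on BOTH call types enter.  "Both-different"
    means modulated by both with differing direction in any window or a
    differing set of significant windows.
    """
    a_only = b_only = both_same = both_diff = 0
    tested_both = 0
    for unit in sorted(set(profiles_a) & set(profiles_b)):
        pa, pb = profiles_a[unit], profiles_b[unit]
        if not (pa.tested and pb.tested):
            continue
        tested_both += 1
        if pa.modulated and not pb.modulated:
            a_only += 1
        elif pb.modulated and not pa.modulated:
            b_only += 1
        elif pa.modulated and pb.modulated:
            if (pa.significant_windows() != pb.significant_windows()) or (
                pa.directions() != pb.directions()
            ):
                both_diff += 1
            else:
                both_same += 1
    return TallyResult(
        a_only=a_only,
        b_only=b_only,
        both_same=both_same,
        both_different=both_diff,
        n_tested_both=tested_both,
    )
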