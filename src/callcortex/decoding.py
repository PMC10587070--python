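"""Monte-Carlo LDA decoding of call type from pooled single-neuron rates.

Neurons were not recorded simultaneously across sessions, so population
"pseudo-trials" are assembled by pairing randomly drawn trials across
neurons within each redraw — the central modelling assumption of the
decoder.  Per repetition: each neuron's trials are split 70/30 into
train/test pools per class; ``n_redraw`` bootstrap pseudo-trials per
class are drawn from each pool; a principal-component projection (top
10 components, capped at the feature dimension, fit on training draws
only) feeds a shared-covariance linear discriminant; accuracy is
measured on the test draws.  The mean and 2.5-97.5 percentile interval
over repetitions form the decoding estimate; a window is significant
when that interval excludes chance (0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from callcortex._rng import as_generator
from callcortex.errors import ContractError
from callcortex.types import CallEvent, SpikeTrainSet

log = logging.getLogger(__name__)

__all__ = [
    "MIN_CALLS_DECODING",
    "DecodingDataset",
    "MonteCarloResult",
    "DecodingCurve",
    "build_decoding_dataset",
    "monte_carlo_lda",
    "sliding_decoding_curve",
]

MIN_CALLS_DECODING = 20
CHANCE_LEVEL = 0.5


@dataclass
class DecodingDataset:
    """Per-neuron, per-class window-mean firing rates (Hz).

    ``rates[unit][label]`` is the vector of per-trial mean rates in the
    1 s window centred at ``center_s``; only neurons with at least 20
    calls of each class are included.
    """

    rates: dict[str, dict[str, np.ndarray]]
    labels: tuple[str, str]
    center_s: float
    window_s: float = 1.0

    @property
    def units(self) -> list[str]:
        return list(self.rates)

    @property
    def n_units(self) -> int:
        return len(self.rates)


def _window_rates(
    times: np.ndarray, events: list[CallEvent], center: float, width: float
) -> np.ndarray:
    """Mean firing rate in [center - w/2, center + w/2) per trial."""
    out = []
    for ev in events:
        lo = ev.onset_s + center - width / 2
        hi = ev.onset_s + center + width / 2
        if lo < 0:
            log.info("decoding: trial at %.2fs dropped (window precedes recording)", ev.onset_s)
            continue
        n = np.searchsorted(times, hi) - np.searchsorted(times, lo)
        out.append(n / width)
    return np.asarray(out, dtype=float)


def build_decoding_dataset(
    spikes: SpikeTrainSet,
    events_a: list[CallEvent],
    events_b: list[CallEvent],
    labels: tuple[str, str],
    center_s: float,
    window_s: float = 1.0,
    min_calls: int = MIN_CALLS_DECODING,
    min_duration_s: float = 0.2,
) -> DecodingDataset:
    """Collect eligible neurons' window-mean rates for two call types."""
    ev_a = [e for e in events_a if e.duration_s >= min_duration_s]
    ev_b = [e for e in events_b if e.duration_s >= min_duration_s]
    rates: dict[str, dict[str, np.ndarray]] = {}
    for unit in sorted(spikes.trains):
        ra = _window_rates(spikes.trains[unit], ev_a, center_s, window_s)
        rb = _window_rates(spikes.trains[unit], ev_b, center_s, window_s)
        if ra.size >= min_calls and rb.size >= min_calls:
            rates[unit] = {labels[0]: ra, labels[1]: rb}
    if len(rates) < 2:
        raise ContractError(
            f"need >= 2 neurons with >= {min_calls} calls of each type; got {len(rates)}"
        )
    return DecodingDataset(rates=rates, labels=labels, center_s=center_s, window_s=window_s)


@dataclass
class MonteCarloResult:
    mean_accuracy: float
    ci_low: float
    ci_high: float
    accuracies: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= CHANCE_LEVEL <= self.ci_high)


def _draw_pseudotrials(
    pools: list[np.ndarray], n_draw: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_draw, n_units) matrix pairing random trials across neurons."""
    cols = [pool[rng.integers(0, pool.size, size=n_draw)] for pool in pools]
    return np.column_stack(cols)


def monte_carlo_lda(
    dataset: DecodingDataset,
    train_frac: float = 0.7,
    n_redraw: int = 5000,
    n_pc: int = 10,
    n_rep: int = 500,
    seed: int | np.random.Generator = 0,
) -> MonteCarloResult:
    """Monte-Carlo resampled PCA + linear-discriminant classification."""
    rng = as_generator(seed)
    units = dataset.units
    la, lb = dataset.labels
    for unit in units:
        for lab in (la, lb):
            if dataset.rates[unit][lab].size < 4:
                raise ContractError(f"unit {unit}: too few {lab} trials")

    accuracies = np.empty(n_rep)
    for rep in range(n_rep):
        train_pools: dict[str, list[np.ndarray]] = {la: [], lb: []}
        test_pools: dict[str, list[np.ndarray]] = {la: [], lb: []}
        for unit in units:
            for lab in (la, lb):
                vals = dataset.rates[unit][lab]
                perm = rng.permutation(vals.size)
                n_train = max(int(round(train_frac * vals.size)), 1)
                n_train = min(n_train, vals.size - 1)  # keep a non-empty test pool
                train_pools[lab].append(vals[perm[:n_train]])
                test_pools[lab].append(vals[perm[n_train:]])

        x_train = np.vstack(
            [
                _draw_pseudotrials(train_pools[la], n_redraw, rng),
                _draw_pseudotrials(train_pools[lb], n_redraw, rng),
            ]
        )
        y_train = np.repeat([0, 1], n_redraw)
        x_test = np.vstack(
            [
                _draw_pseudotrials(test_pools[la], n_redraw, rng),
                _draw_pseudotrials(test_pools[lb], n_redraw, rng),
            ]
        )
        y_test = np.repeat([0, 1], n_redraw)

        n_comp = min(n_pc, x_train.shape[1])
        pca = PCA(n_components=n_comp)
        z_train = pca.fit_transform(x_train)
        z_test = pca.transform(x_test)
        lda = LinearDiscriminantAnalysis()
        lda.fit(z_train, y_train)
        accuracies[rep] = float(np.mean(lda.predict(z_test) == y_test))

    return MonteCarloResult(
        mean_accuracy=float(accuracies.mean()),
        ci_low=float(np.percentile(accuracies, 2.5)),
        ci_high=float(np.percentile(accuracies, 97.5)),
        accuracies=accuracies,
    )


@dataclass
class DecodingCurve:
    """Decoding accuracy per sliding-window centre."""

    centers_s: np.ndarray
    mean_accuracy: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    labels: tuple[str, str] = ("", "")

    @property
    def significant(self) -> np.ndarray:
        return ~((self.ci_low <= CHANCE_LEVEL) & (CHANCE_LEVEL <= self.ci_high))


def sliding_decoding_curve(
    spikes: SpikeTrainSet,
    events_a: list[CallEvent],
    events_b: list[CallEvent],
    labels: tuple[str, str],
    centers_s: np.ndarray | None = None,
    window_s: float = 1.0,
    n_redraw: int = 5000,
    n_rep: int = 500,
    n_pc: int = 10,
    seed: int | np.random.Generator = 0,
    min_calls: int = MIN_CALLS_DECODING,
) -> DecodingCurve:
    """One Monte-Carlo LDA per window centre (default -3 .. +3 s)."""
    rng = as_generator(seed)
    if centers_s is None:
        centers_s = np.arange(-3.0, 3.01, 0.5)
    centers_s = np.asarray(sorted(centers_s), dtype=float)
    means, los, his = [], [], []
    for c in centers_s:
        ds = build_decoding_dataset(
            spikes, events_a, events_b, labels, float(c),
            window_s=window_s, min_calls=min_calls,
        )
        res = monte_carlo_lda(
            ds, n_redraw=n_redraw, n_rep=n_rep, n_pc=n_pc, seed=rng
        )
        means.append(res.mean_accuracy)
        los.append(res.ci_low)
        his.append(res.ci_high)
    return DecodingCurve(
        centers_s=centers_s,
        mean_accuracy=np.asarray(means),
        ci_low=np.asarray(los),
        ci_high=np.asarray(his),
        labels=labels,
    )
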