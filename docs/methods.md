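# Methods

This note documents the models, parameter choices and numerical
decisions behind `callcortex`: what the synthetic generator emulates,
how each analysis is computed, and what passing tests do and do not
establish about real recordings.

## Synthetic study conditions

The generator (`callcortex.synth`) produces the four data streams the
analyses consume — two-channel audio, multi-channel LFP, spike trains,
and sync pulses — with the statistical structure the analyses assume.
A single master seed spawns independent named substreams (calls, noise,
lfp, spikes, sync), so any stream can be regenerated in isolation and
identical (config, seed) pairs give bit-identical output.

### Calls

Each call type arrives as an independent Poisson process (defaults, in
calls/min: trill 3.0, twitter 0.8, trillphee 0.6, phee 0.4, compound
0; trills dominate captive repertoires and phees are sparse in the
colony setting).  Target calls are thinned greedily to be
non-overlapping with a 0.25 s minimum gap — the analyses never treat
overlapping target calls — so realized target counts sit slightly below
the Poisson mean; non-target calls are left unthinned.  Durations are
uniform per type (phee 1.2–2.5 s, trill 0.3–0.6 s, twitter 0.6–1.2 s,
trillphee 0.9–1.6 s).  Twitter syllables sit on a 1/7 s grid (rate
7 Hz, ±4 ms uniform jitter after the first, which defines the vocal
onset); the event offset is the last syllable's end, so annotated
boundaries coincide with acoustic energy.  Compound-call elements are
spaced by whole cycles of the 7 Hz rhythm, occasionally skipping one —
longer elements then span multiple oscillation periods yet still begin
near the theta trough.

Waveforms use the field's descriptions: fundamentals near 7.5 kHz
(above the 5 kHz floor of marmoset calls), phee as a slow linear chirp
(+400 Hz/s), trill as sinusoidal FM (30 Hz rate, 500 Hz depth),
trillphee as sinusoidal FM fading into linear FM around mid-call,
twitter syllables as 50 ms sweeps 6→11 kHz.  Amplitudes order phee
loudest (1.0) and trill softest (0.25).  These per-type levels and all
LFP/spike effect sizes below are free parameters chosen to be
physiologically plausible, not claims about any particular animal.

### Scene mixing

Target calls enter the parabolic channel with +20 dB amplitude gain and
the reference channel at unit gain; shared room noise (white, RMS
0.003) and non-target calls enter both channels equally, plus a small
independent sensor floor per microphone (RMS 5e-4).  The channel
difference therefore cancels everything except target calls, which is
the detection principle.

### LFP

Each channel is a sum of: pink (1/f) background (RMS 10 µV);
narrowband 12–30 Hz noise (RMS 12 µV) whose amplitude envelope is
multiplied by `sqrt(1 − depth)` from `onset + start_offset` to call
offset — depth is a *power* fraction, so measured relative beta power
during suppression is `1 − depth` in closed form; and a theta burst for
every multi-syllable call (amplitude 30 µV).  Default beta modulation
per type: phee depth 0.50 starting −0.5 s (deepest, earliest), trill
0.20 at −0.05 s (shallowest), twitter 0.35 at −0.06 s, trillphee 0.45
at 0.0 s — reproducing the qualitative ordering the analyses are meant
to resolve (phee earliest and deepest, trill weakest, trillphee late).

**Theta phase jitter.**  The burst phase is `2π·7·(t − s₀) + π + δ(t)`
(cosine convention, trough = π), where `δ(t)` is a smooth stochastic
process with an exact von Mises(0, κ) marginal: 1 Hz-low-passed
Gaussian noise mapped through the normal CDF and the von Mises quantile
function (κ default 4).  A smooth process, rather than independent
per-syllable jitter, is a measurement-physics requirement: i.i.d.
jitter at a 7 Hz syllable rate places the phase-modulation sidebands
outside the 5–10 Hz analysis band, so no band-limited phase estimate
could recover its distribution (the measured VS inflates from 0.70 to
~0.81 at κ = 2).  Vector strength is a functional of the *marginal*
phase distribution, which the smooth construction preserves exactly;
end-to-end recovery lands within 0.005 of the Bessel ratio I₁(κ)/I₀(κ).
The cost is temporal correlation of the jitter over a few syllables,
which slightly enlarges the Monte-Carlo error of VS at fixed n.

### Spikes and sync

Spike trains are inhomogeneous Poisson (exact thinning), rate =
baseline (5 Hz) × a per-type gain inside each of the four peri-call
windows.  Default gains give the decoder a real class signal (e.g.
trill pre-gain 2.0 vs twitter during-gain 0.5 with post-gain 2.0);
`SynthConfig.null()` sets every gain to 1 and every beta depth to 0 for
calibration runs.  Sync pulses tick every 2 s on the audio clock; the
neural clock reads `offset + (1 + drift)·t`.

## Analyses

* **Detection.**  512-sample Hann STFT, 50% hop, at 48 kHz; linear
  power smoothed 5 bins × 3 frames; score = per-frame max over
  4–20 kHz of the dB difference; threshold 10 dB (half the nominal
  front gain); runs merged across ≤0.15 s gaps (bridging twitter
  inter-syllable silences) and dropped under 0.1 s.  Boundaries are
  frame centers; with the 10.7 ms window the onset/offset bias is a few
  ms, well inside the 25 ms tolerance used in tests.  Raising the
  threshold can split a run that dips across it, so monotonicity holds
  (and is tested) as containment: every higher-threshold segment lies
  inside a lower-threshold one.
* **Classification.**  A deterministic cascade on segment audio: a
  tonality gate (median per-frame share of band energy in the peak
  STFT bin ≥ 0.08; broadband noise fails it → "unknown"); ≥3 envelope
  bursts → twitter (median burst ≤ 90 ms) or compound; single-burst
  calls are split at mid-call and scored for sinusoidal FM (20–45 Hz
  band of the detrended peak-frequency track, threshold 120 Hz RMS):
  sustained FM → trill, early-only → trillphee, none → phee.  This
  replaces the original study's human-corrected learned classifier; it
  is exact on generator output but makes no claim to the real
  classifier's error profile.
* **Band power.**  4th-order Butterworth, zero-phase (forward–backward),
  Hilbert transform with 1 s reflected edge padding (FFT length padded
  to a fast size), power mean-pooled to 200 Hz, per-trial baseline
  normalization over [−3, −1] s (the per-trial baseline mean is exactly
  1 by construction).  Calls shorter than 200 ms and calls without full
  epoch context are excluded and logged.
* **Modulation test.**  Signed-rank compares per-trial window means to
  per-trial baseline means (paired; the paired/unpaired choice was open
  and paired was adopted).  The 2-SD criterion applies to the
  trial-averaged trace, matching the bootstrap SD's definition on
  averaged traces: 200 trials drawn per rep (without replacement when
  available, with replacement otherwise), baseline cut into 200 ms
  segments (500 ms for spikes), SD of segment means, 1000 reps
  averaged.  Because the bootstrap always averages ~200 trials, the
  criterion is conservative exactly when trials are abundant (the
  study's regime, thousands of trills); with few trials it is roughly
  calibrated rather than conservative.  Start-time search slides a
  100 ms window in 5 ms steps over the union of the analysis windows
  ([−0.5, 0] ∪ [−0.1, 0.2] ∪ call duration ∪ [0.3, 0.9] s) and reports
  the earliest qualifying midpoint; on null data the sliding
  multiplicity makes false finds non-negligible at small trial counts,
  while in the abundant-trial regime the 2-SD gate suppresses them —
  the null property is tested there.  Sites are tested at per-site
  α = 0.05 with no cross-site correction, mirroring the reported
  procedure; this is flagged here deliberately.
* **Cross-type comparisons.**  Kruskal–Wallis omnibus; post hoc
  pairwise two-sided rank-sum tests with Bonferroni multiplication.
  Beta temporal profiles ([−1.5, 2.5] s, mean-pooled to 10 Hz) are
  embedded with a 3-component PCA; within- vs between-type Euclidean
  distances are compared by a two-sided rank-sum test.
* **Phase locking.**  5–10 Hz zero-phase band-pass, analytic phase,
  nearest-sample phase per syllable onset.  Rayleigh statistic
  2·n·VS², p from the asymptotic χ²(2) tail — the convention under
  which the printed 0.001 threshold equals 13.8; the tail is slightly
  optimistic below n ≈ 50, irrelevant at the n used here.  The first
  syllable of each call is included in the phase set (switchable).
* **Spike tests.**  50 ms bins over [−10, 10] s, z-scored per trial
  over the whole span; zero-variance trials get z = 0 and a flag
  rather than exclusion, so trial counts match call counts.  Units
  require ≥15 calls; phee typically fails this threshold by itself, so
  no explicit phee exclusion is needed.  Shuffle controls circularly
  shift each trial's spikes by an independent uniform offset over the
  span (100 reps) and re-run the full test.  "Both-different" in the
  two-type tallies means modulated by both types with a differing
  direction in any window or a differing set of significant windows.
* **Decoding.**  Per repetition: each eligible neuron's trials split
  70/30 per class; `n_redraw` bootstrap pseudo-trials per class pair
  trials at random across neurons (the neurons were not recorded
  simultaneously — this independence assumption is the central
  modelling choice); PCA (≤10 components, capped at the unit count) is
  fit on training draws only to avoid leakage; a shared-covariance LDA
  is scored on test draws.  The 95% CI is the 2.5–97.5 percentile over
  repetitions.  At the null with few trials the mean accuracy carries
  the familiar dataset-level bias of split-based validation (spread
  ~±0.1 at 30 trials/class); the CI covers chance throughout.

## Problem sizes

Defaults follow the published procedure (n_redraw 5000, n_rep 500,
bootstrap 200 × 1000).  The test suite and the demo pipeline use
reduced sizes chosen for desk-scale runs: the demo analyses 600 s of
synthetic recording with boosted call rates (so the ≥20-call decoding
threshold is met), sd_reps 200, n_redraw 200, n_rep 50; calibration
suites use 200 null sites × 30 trials, 10⁴ syllables for phase-lock
recovery, and 300 trials for start-time recovery.  The null-decoder
benchmark uses n_redraw 500 and n_rep 100 at 10 neurons × 30
calls/class.

## Reproducibility

Runs are fully determined by (RunConfig, seed); every output row
carries the config hash, and rerunning a stage with an unchanged config
hash is skipped via the manifest.  All result files are byte-identical
across reruns; `manifest.json` is the single exception because it
records wall-clock time.

## Limitations

The generator does not model vocal-tract acoustics, reverberation,
colony social dynamics, electrode drift, artifacts, spike sorting, or
anatomical structure (sites are abstract grid coordinates); passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under its stated assumptions, not performance on real
colony recordings.  The classifier is tuned to the generator's call
models; real calls would need the plug-in classifier interface.  The
theta model makes the oscillation the syllable clock; alternative
causal structures (motor command driving both) would produce the same
marginal statistics and are indistinguishable to these analyses.
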