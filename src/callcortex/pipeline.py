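"""End-to-end orchestration: synth -> detect -> analyze -> report.

A run is fully determined by (RunConfig, master seed): every stochastic
step derives its stream from named substreams of the master seed, and
every output row carries the config hash, so reruns are byte-identical
(the manifest, which records wall-clock time, is the one exception).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from callcortex import io as cxio
from callcortex import __version__
from callcortex._rng import substream
from callcortex.acoustics import (
    ClockMap,
    DetectionParams,
    align_clocks,
    classify_call_type,
    compute_spectrogram_pair,
    detect_syllable_onsets,
    detect_target_segments,
)
from callcortex.decoding import sliding_decoding_curve
from callcortex.errors import ContractError, EmptyInputError, InvalidConfigError
from callcortex.lfp import (
    BETA,
    THETA,
    ONSET_WINDOW,
    band_power_timecourse,
    bootstrap_baseline_sd,
    extract_peak_features,
    find_modulation_start_time,
    test_window_modulation,
)
from callcortex.phaselock import phase_lock_analysis
from callcortex.spikes import (
    build_raster,
    normalize_rates,
    tally_modulation,
    test_spike_modulation,
)
from callcortex.synth import (
    SynthConfig,
    generate_acoustic_scene,
    generate_call_sequence,
    generate_lfp,
    generate_spike_trains,
    generate_sync,
)
from callcortex.types import CallEvent, CallType

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "write_report", "STAGES"]

STAGES = ("synth", "detect", "lfp", "phaselock", "spikes", "decode", "report")

#: Output files per stage (relative to outdir).
STAGE_OUTPUTS = {
    "synth": ["scene.wav", "truth_calls.csv", "lfp.f32", "lfp.json", "spikes.csv", "sync.csv"],
    "detect": ["detected_calls.csv", "clockmap.json"],
    "lfp": ["lfp_results.csv"],
    "phaselock": ["phaselock.csv"],
    "spikes": ["spike_results.csv", "tally.csv"],
    "decode": ["decoding.csv"],
    "report": ["summary.txt"],
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Demo-scale defaults: call rates are boosted relative to colony
    averages so that a short (480 s) recording yields enough trials for
    every stage, including the 20-call decoding threshold.
    """

    seed: int = 0
    duration_s: float = 600.0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # synthesis
    call_rates_per_min: dict[str, float] = field(
        default_factory=lambda: {
            "phee": 0.8, "trill": 6.0, "twitter": 5.5, "trillphee": 5.0, "compound": 0.0,
        }
    )
    n_lfp_channels: int = 2
    n_units: int = 6
    clock_offset_s: float = 0.35
    drift_ppm: float = 20.0
    # detection
    threshold_db: float = 10.0
    min_duration_s: float = 0.1
    max_merge_gap_s: float = 0.15
    # analysis
    alpha: float = 0.05
    sd_reps: int = 200
    min_trials_lfp: int = 10
    decode_centers: list[float] = field(default_factory=lambda: [-1.0, 0.0, 1.0])
    n_redraw: int = 200
    n_rep: int = 50
    n_pc: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def synth_config(self) -> SynthConfig:
        cfg = SynthConfig()
        cfg.call_rates_per_min = {
            CallType(k): float(v) for k, v in self.call_rates_per_min.items()
        }
        cfg.n_lfp_channels = self.n_lfp_channels
        cfg.n_units = self.n_units
        cfg.validate()
        return cfg

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            threshold_db=self.threshold_db,
            min_duration_s=self.min_duration_s,
            max_merge_gap_s=self.max_merge_gap_s,
        )


@dataclass
class ResultsBundle:
    """Paths of stage outputs plus the run manifest."""

    outdir: Path
    config_hash: str
    stage_files: dict[str, list[Path]] = field(default_factory=dict)

    def manifest_path(self) -> Path:
        return self.outdir / "manifest.json"


def _events_to_clock(events: list[CallEvent], cmap: ClockMap) -> list[CallEvent]:
    return [
        CallEvent(
            onset_s=float(cmap.audio_to_neural(e.onset_s)),
            offset_s=float(cmap.audio_to_neural(e.offset_s)),
            call_type=e.call_type,
            syllable_onsets_s=[float(cmap.audio_to_neural(t)) for t in e.syllable_onsets_s],
            is_target=e.is_target,
        )
        for e in events
    ]


def _stage_done(outdir: Path, stage: str, config_hash: str) -> bool:
    manifest = outdir / "manifest.json"
    if not manifest.exists():
        return False
    try:
        meta = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    if meta.get("config_hash") != config_hash:
        return False
    if stage not in meta.get("completed_stages", []):
        return False
    return all((outdir / f).exists() for f in STAGE_OUTPUTS[stage])


def _require(outdir: Path, stage: str, needed_from: str) -> None:
    missing = [f for f in STAGE_OUTPUTS[needed_from] if not (outdir / f).exists()]
    if missing:
        raise ContractError(
            f"stage '{stage}' needs outputs of stage '{needed_from}' "
            f"(missing: {missing}); enable that stage or provide the files"
        )


def run_pipeline(config: RunConfig, outdir: str | Path) -> ResultsBundle:
    """Execute the enabled stages in dependency order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    bundle = ResultsBundle(outdir=outdir, config_hash=chash)
    completed: list[str] = []
    manifest = bundle.manifest_path()
    if manifest.exists():
        try:
            old = json.loads(manifest.read_text())
            if old.get("config_hash") == chash:
                completed = list(old.get("completed_stages", []))
        except json.JSONDecodeError:
            pass

    for stage in STAGES:
        if stage not in config.stages:
            continue
        if _stage_done(outdir, stage, chash) and stage != "report":
            log.info("stage %s: outputs up to date, skipping", stage)
            bundle.stage_files[stage] = [outdir / f for f in STAGE_OUTPUTS[stage]]
            continue
        log.info("stage %s: running", stage)
        _STAGE_FUNCS[stage](config, outdir, chash)
        bundle.stage_files[stage] = [outdir / f for f in STAGE_OUTPUTS[stage]]
        if stage not in completed:
            completed.append(stage)
        manifest.write_text(
            json.dumps(
                {
                    "config_hash": chash,
                    "seed": config.seed,
                    "version": __version__,
                    "completed_stages": completed,
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                },
                indent=1,
                sort_keys=True,
            )
        )
    return bundle


# --- stages --------------------------------------------------------------

def _stage_synth(config: RunConfig, outdir: Path, chash: str) -> None:
    scfg = config.synth_config()
    seed = config.seed
    dur = config.duration_s
    targets = generate_call_sequence(scfg, dur, substream(seed, "calls"))
    nt_cfg = config.synth_config()
    nt_cfg.call_rates_per_min = {
        ct: r * 0.5 for ct, r in scfg.call_rates_per_min.items()
    }
    nontargets = generate_call_sequence(
        nt_cfg, dur, substream(seed, "nontarget-calls"), is_target=False
    )
    scene = generate_acoustic_scene(
        targets, nontargets, scfg, substream(seed, "noise"), duration_s=dur
    )
    cxio.write_scene_wav(scene, outdir / "scene.wav")
    cxio.write_annotations(targets + nontargets, outdir / "truth_calls.csv")

    audio_sync, neural_sync = generate_sync(
        dur, drift_ppm=config.drift_ppm, seed=substream(seed, "sync"),
        offset_s=config.clock_offset_s,
    )
    cmap = ClockMap(offset_s=config.clock_offset_s, drift=config.drift_ppm * 1e-6)
    neural_targets = _events_to_clock(targets, cmap)
    neural_dur = float(cmap.audio_to_neural(dur)) + 1.0

    lfp = generate_lfp(neural_targets, scfg, substream(seed, "lfp"), neural_dur)
    cxio.write_lfp(lfp, outdir / "lfp.f32", outdir / "lfp.json")
    spikes = generate_spike_trains(neural_targets, scfg, substream(seed, "spikes"), neural_dur)
    cxio.write_spikes(spikes, outdir / "spikes.csv")
    cxio.write_sync(audio_sync, neural_sync, outdir / "sync.csv")


def _stage_detect(config: RunConfig, outdir: Path, chash: str) -> None:
    _require(outdir, "detect", "synth")
    scene = cxio.read_scene_wav(outdir / "scene.wav")
    params = config.detection_params()
    spec = compute_spectrogram_pair(scene, params)
    segments = detect_target_segments(spec, params)
    fs = scene.sample_rate_hz
    events: list[CallEvent] = []
    for onset, offset in segments:
        i0, i1 = int(onset * fs), int(offset * fs)
        seg = scene.parabolic[i0:i1]
        if seg.size < int(0.05 * fs):
            continue
        label = classify_call_type(seg, fs)
        if label == "unknown":
            log.info("detect: unclassifiable segment at %.2fs", onset)
            continue
        ct = CallType(label)
        ev_onset = onset
        if ct in (CallType.TWITTER, CallType.COMPOUND):
            syl = [onset + float(t) for t in detect_syllable_onsets(seg, fs)]
            if syl:
                ev_onset = syl[0]  # vocal onset = start of the first syllable
        else:
            syl = [onset]
        try:
            events.append(
                CallEvent(onset_s=ev_onset, offset_s=offset, call_type=ct,
                          syllable_onsets_s=syl, is_target=True)
            )
        except ContractError as exc:
            log.info("detect: dropped malformed segment at %.2fs (%s)", onset, exc)
    cxio.write_annotations(events, outdir / "detected_calls.csv")

    audio_sync, neural_sync = cxio.read_sync(outdir / "sync.csv")
    cmap = align_clocks(audio_sync, neural_sync)
    (outdir / "clockmap.json").write_text(
        json.dumps(
            {
                "offset_s": cmap.offset_s,
                "drift": cmap.drift,
                "residual_rms_s": cmap.residual_rms_s,
                "n_pulses": cmap.n_pulses,
                "config_hash": chash,
            },
            indent=1,
            sort_keys=True,
        )
    )


def _load_neural_calls(outdir: Path) -> list[CallEvent]:
    calls = cxio.read_annotations(outdir / "detected_calls.csv")
    meta = json.loads((outdir / "clockmap.json").read_text())
    cmap = ClockMap(offset_s=meta["offset_s"], drift=meta["drift"])
    return _events_to_clock(calls, cmap)


def _stage_lfp(config: RunConfig, outdir: Path, chash: str) -> None:
    _require(outdir, "lfp", "synth")
    _require(outdir, "lfp", "detect")
    lfp = cxio.read_lfp(outdir / "lfp.f32", outdir / "lfp.json")
    calls = _load_neural_calls(outdir)
    rows = []
    for ch in range(lfp.n_channels):
        for band in (BETA, THETA):
            for ct in (CallType.PHEE, CallType.TRILL, CallType.TWITTER, CallType.TRILLPHEE):
                evs = [e for e in calls if e.call_type is ct]
                if len(evs) < config.min_trials_lfp:
                    continue
                try:
                    power = band_power_timecourse(lfp, evs, ch, band)
                except EmptyInputError:
                    continue
                sd = bootstrap_baseline_sd(
                    power, reps=config.sd_reps, seed=substream(config.seed, f"sd-{ch}-{band.name}-{ct.value}")
                )
                res = test_window_modulation(power, ONSET_WINDOW, sd, alpha=config.alpha)
                row = {
                    "site": f"ch{ch}",
                    "band": band.name,
                    "call_type": ct.value,
                    "n_trials": power.n_trials,
                    "median_power": res.median_power,
                    "p": res.p,
                    "sd": sd,
                    "significant": int(res.significant),
                    "direction": res.direction,
                    "start_time_s": "",
                    "peak_magnitude": "",
                    "peak_time_s": "",
                    "config_hash": chash,
                }
                if res.significant:
                    st = find_modulation_start_time(power, sd, res.direction, alpha=config.alpha)
                    if st.found:
                        row["start_time_s"] = st.start_time_s
                    peak = extract_peak_features(power, res.direction)
                    if not peak.degenerate:
                        row["peak_magnitude"] = peak.magnitude
                        row["peak_time_s"] = peak.time_s
                rows.append(row)
    cols = ["site", "band", "call_type", "n_trials", "median_power", "p", "sd",
            "significant", "direction", "start_time_s", "peak_magnitude",
            "peak_time_s", "config_hash"]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / "lfp_results.csv", index=False)


def _stage_phaselock(config: RunConfig, outdir: Path, chash: str) -> None:
    _require(outdir, "phaselock", "synth")
    _require(outdir, "phaselock", "detect")
    lfp = cxio.read_lfp(outdir / "lfp.f32", outdir / "lfp.json")
    calls = _load_neural_calls(outdir)
    onsets = np.array(
        [t for e in calls if e.n_syllables >= 2 for t in e.syllable_onsets_s]
    )
    rows = []
    for ch in range(lfp.n_channels):
        if onsets.size < 2:
            continue
        res = phase_lock_analysis(lfp, onsets, ch)
        rows.append(
            {
                "site": res.site,
                "n": res.n,
                "vs": res.vs,
                "rayleigh": res.rayleigh,
                "p": res.p,
                "mean_phase": res.mean_phase,
                "significant": int(res.significant),
                "config_hash": chash,
            }
        )
    cols = ["site", "n", "vs", "rayleigh", "p", "mean_phase", "significant", "config_hash"]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / "phaselock.csv", index=False)


_SPIKE_TYPES = (CallType.TRILL, CallType.TWITTER, CallType.TRILLPHEE)


def _stage_spikes(config: RunConfig, outdir: Path, chash: str) -> None:
    _require(outdir, "spikes", "synth")
    _require(outdir, "spikes", "detect")
    spikes = cxio.read_spikes(outdir / "spikes.csv")
    calls = _load_neural_calls(outdir)
    rows = []
    profiles: dict[CallType, dict[str, object]] = {ct: {} for ct in _SPIKE_TYPES}
    for unit in sorted(spikes.trains):
        for ct in _SPIKE_TYPES:
            evs = [e for e in calls if e.call_type is ct]
            raster = build_raster(spikes, evs, unit)
            if raster.n_trials < 1:
                continue
            prof = normalize_rates(raster)
            result = test_spike_modulation(
                prof, unit=unit, call_type=ct.value, alpha=config.alpha,
                seed=substream(config.seed, f"spk-{unit}-{ct.value}"),
                sd_reps=config.sd_reps,
            )
            profiles[ct][unit] = result
            for wname, wout in (result.windows or {}).items():
                rows.append(
                    {
                        "unit": unit,
                        "call_type": ct.value,
                        "window": wname,
                        "direction": wout.direction,
                        "p": wout.p,
                        "passes_2sd": int(wout.passes_2sd),
                        "tested": int(result.tested),
                        "modulated": int(result.modulated),
                        "n_trials": result.n_trials,
                        "config_hash": chash,
                    }
                )
            if not result.tested:
                rows.append(
                    {
                        "unit": unit, "call_type": ct.value, "window": "",
                        "direction": "", "p": "", "passes_2sd": "",
                        "tested": 0, "modulated": 0,
                        "n_trials": result.n_trials, "config_hash": chash,
                    }
                )
    cols = ["unit", "call_type", "window", "direction", "p", "passes_2sd",
            "tested", "modulated", "n_trials", "config_hash"]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / "spike_results.csv", index=False)

    tally_rows = []
    for a, b in ((CallType.TRILL, CallType.TWITTER), (CallType.TRILL, CallType.TRILLPHEE)):
        t = tally_modulation(profiles[a], profiles[b])
        tally_rows.append(
            {
                "type_a": a.value,
                "type_b": b.value,
                "a_only": t.a_only,
                "b_only": t.b_only,
                "both_same": t.both_same,
                "both_different": t.both_different,
                "modulated": t.modulated,
                "n_tested_both": t.n_tested_both,
                "difference_proportion": t.difference_proportion,
                "config_hash": chash,
            }
        )
    pd.DataFrame(tally_rows).to_csv(outdir / "tally.csv", index=False)


def _stage_decode(config: RunConfig, outdir: Path, chash: str) -> None:
    _require(outdir, "decode", "synth")
    _require(outdir, "decode", "detect")
    spikes = cxio.read_spikes(outdir / "spikes.csv")
    calls = _load_neural_calls(outdir)
    rows = []
    for a, b in ((CallType.TRILL, CallType.TWITTER), (CallType.TRILL, CallType.TRILLPHEE)):
        ev_a = [e for e in calls if e.call_type is a]
        ev_b = [e for e in calls if e.call_type is b]
        try:
            curve = sliding_decoding_curve(
                spikes, ev_a, ev_b, (a.value, b.value),
                centers_s=np.asarray(config.decode_centers),
                n_redraw=config.n_redraw, n_rep=config.n_rep, n_pc=config.n_pc,
                seed=substream(config.seed, f"decode-{a.value}-{b.value}"),
            )
        except ContractError as exc:
            log.warning("decode %s vs %s skipped: %s", a.value, b.value, exc)
            continue
        for i, c in enumerate(curve.centers_s):
            rows.append(
                {
                    "pair": f"{a.value}-vs-{b.value}",
                    "center_s": float(c),
                    "mean_accuracy": curve.mean_accuracy[i],
                    "ci_low": curve.ci_low[i],
                    "ci_high": curve.ci_high[i],
                    "significant": int(curve.significant[i]),
                    "config_hash": chash,
                }
            )
    cols = ["pair", "center_s", "mean_accuracy", "ci_low", "ci_high",
            "significant", "config_hash"]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / "decoding.csv", index=False)


def write_report(config: RunConfig, outdir: str | Path) -> Path:
    """Plain-text summary distilled from the stage CSVs."""
    outdir = Path(outdir)
    lines = [f"callcortex run summary (config {config.config_hash()})", ""]
    missing = []
    for stage in ("detect", "lfp", "phaselock", "spikes", "decode"):
        for f in STAGE_OUTPUTS[stage]:
            if not (outdir / f).exists():
                missing.append(f"{stage}:{f}")
    if missing:
        lines.append("INCOMPLETE — missing stage outputs: " + ", ".join(missing))
    det = outdir / "detected_calls.csv"
    if det.exists():
        calls = cxio.read_annotations(det)
        lines.append(f"detected target calls: {len(calls)}")
        for ct in CallType:
            n = sum(1 for c in calls if c.call_type is ct)
            if n:
                lines.append(f"  {ct.value}: {n}")
    lfp_csv = outdir / "lfp_results.csv"
    if lfp_csv.exists():
        df = pd.read_csv(lfp_csv)
        if len(df):
            sig = df[df["significant"] == 1]
            lines.append(
                f"LFP: {len(sig)} of {len(df)} (site, band, type) combinations modulated"
            )
    pl_csv = outdir / "phaselock.csv"
    if pl_csv.exists():
        df = pd.read_csv(pl_csv)
        if len(df):
            lines.append(
                f"phase locking: {int(df['significant'].sum())} of {len(df)} sites "
                f"significant (median VS {df['vs'].median():.2f})"
            )
    tally_csv = outdir / "tally.csv"
    if tally_csv.exists():
        df = pd.read_csv(tally_csv)
        for _, r in df.iterrows():
            lines.append(
                f"tally {r['type_a']} vs {r['type_b']}: "
                f"A-only {r['a_only']}, B-only {r['b_only']}, "
                f"both-same {r['both_same']}, both-different {r['both_different']} "
                f"(modulated {r['modulated']}/{r['n_tested_both']} tested)"
            )
    dec_csv = outdir / "decoding.csv"
    if dec_csv.exists():
        df = pd.read_csv(dec_csv)
        for pair, grp in df.groupby("pair"):
            peak = grp.loc[grp["mean_accuracy"].idxmax()]
            lines.append(
                f"decoding {pair}: peak accuracy {peak['mean_accuracy']:.2f} "
                f"at t = {peak['center_s']:+.1f} s "
                f"[{peak['ci_low']:.2f}, {peak['ci_high']:.2f}]"
            )
    text = "\n".join(lines) + "\n"
    path = outdir / "summary.txt"
    path.write_text(text)
    return path


def _stage_report(config: RunConfig, outdir: Path, chash: str) -> None:
    write_report(config, outdir)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "detect": _stage_detect,
    "lfp": _stage_lfp,
    "phaselock": _stage_phaselock,
    "spikes": _stage_spikes,
    "decode": _stage_decode,
    "report": _stage_report,
}
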