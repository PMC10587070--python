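"""Readers/writers for the plain-text and WAV interchange formats.

Scenes are 2-channel float32 WAV; annotations, spikes and sync pulses
are CSV; LFP is float32 flat binary plus a JSON sidecar describing
shape, sampling rate and site coordinates.  Annotation round-trips are
exact: floats are serialised with shortest-repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from callcortex.errors import ContractError
from callcortex.types import (
    AcousticScene,
    CallEvent,
    CallType,
    LfpChannelSet,
    SpikeTrainSet,
    SyncPulseTrain,
)

__all__ = [
    "write_scene_wav",
    "read_scene_wav",
    "write_annotations",
    "read_annotations",
    "write_lfp",
    "read_lfp",
    "write_spikes",
    "read_spikes",
    "write_sync",
    "read_sync",
]


# --- audio ---------------------------------------------------------------

def write_scene_wav(scene: AcousticScene, path: str | Path) -> None:
    """Write parabolic (ch 0) and reference (ch 1) as float32 WAV."""
    data = np.stack([scene.parabolic, scene.reference], axis=1).astype(np.float32)
    wavfile.write(str(path), int(scene.sample_rate_hz), data)


def read_scene_wav(path: str | Path) -> AcousticScene:
    fs, data = wavfile.read(str(path))
    if data.ndim != 2 or data.shape[1] != 2:
        raise ContractError(f"{path}: expected a 2-channel WAV")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AcousticScene(
        parabolic=data[:, 0].astype(np.float64),
        reference=data[:, 1].astype(np.float64),
        sample_rate_hz=float(fs),
    )


# --- annotations ---------------------------------------------------------

def write_annotations(events: list[CallEvent], path: str | Path) -> None:
    rows = [
        {
            "onset_s": repr(float(e.onset_s)),
            "offset_s": repr(float(e.offset_s)),
            "call_type": e.call_type.value,
            "syllable_onsets": ";".join(repr(float(t)) for t in e.syllable_onsets_s),
            "is_target": int(e.is_target),
        }
        for e in sorted(events, key=lambda e: e.onset_s)
    ]
    pd.DataFrame(
        rows, columns=["onset_s", "offset_s", "call_type", "syllable_onsets", "is_target"]
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[CallEvent]:
    df = pd.read_csv(path, dtype={"syllable_onsets": str})
    events = []
    for _, row in df.iterrows():
        syl_raw = row["syllable_onsets"]
        syl = (
            [float(tok) for tok in str(syl_raw).split(";")]
            if isinstance(syl_raw, str) and str(syl_raw).strip()
            else []
        )
        events.append(
            CallEvent(
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                call_type=CallType(row["call_type"]),
                syllable_onsets_s=syl,
                is_target=bool(int(row["is_target"])),
            )
        )
    return events


# --- LFP -----------------------------------------------------------------

def write_lfp(lfp: LfpChannelSet, bin_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Float32 channel-major flat binary + JSON sidecar."""
    bin_path = Path(bin_path)
    if sidecar_path is None:
        sidecar_path = bin_path.with_suffix(".json")
    lfp.samples.astype(np.float32).tofile(bin_path)
    meta = {
        "sample_rate_hz": lfp.sample_rate_hz,
        "n_channels": lfp.n_channels,
        "n_samples": lfp.n_samples,
        "dtype": "float32",
        "order": "channel-major",
        "site_xy_mm": lfp.site_xy_mm.tolist(),
        "site_label": lfp.site_label,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_lfp(bin_path: str | Path, sidecar_path: str | Path | None = None) -> LfpChannelSet:
    bin_path = Path(bin_path)
    if sidecar_path is None:
        sidecar_path = bin_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    raw = np.fromfile(bin_path, dtype=np.float32)
    samples = raw.reshape(meta["n_channels"], meta["n_samples"]).astype(np.float64)
    return LfpChannelSet(
        samples=samples,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        site_xy_mm=np.asarray(meta["site_xy_mm"], dtype=float),
        site_label=meta.get("site_label"),
    )


# --- spikes --------------------------------------------------------------

def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = []
    for unit in sorted(spikes.trains):
        ch = spikes.unit_channel.get(unit, -1)
        for t in spikes.trains[unit]:
            rows.append({"unit_id": unit, "spike_time_s": repr(float(t)), "channel": ch})
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s", "channel"]).to_csv(path, index=False)


def read_spikes(path: str | Path, duration_s: float | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path)
    trains = {
        str(unit): np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        for unit, grp in df.groupby("unit_id")
    }
    unit_channel = {}
    if "channel" in df.columns:
        unit_channel = {
            str(unit): int(grp["channel"].iloc[0]) for unit, grp in df.groupby("unit_id")
        }
    return SpikeTrainSet(trains=trains, unit_channel=unit_channel, duration_s=duration_s)


# --- sync ----------------------------------------------------------------

def write_sync(audio: SyncPulseTrain, neural: SyncPulseTrain, path: str | Path) -> None:
    n = min(audio.n_pulses, neural.n_pulses)
    pd.DataFrame(
        {
            "pulse_index": np.arange(n),
            "audio_time_s": [repr(float(t)) for t in audio.times[:n]],
            "neural_time_s": [repr(float(t)) for t in neural.times[:n]],
        }
    ).to_csv(path, index=False)


def read_sync(path: str | Path) -> tuple[SyncPulseTrain, SyncPulseTrain]:
    df = pd.read_csv(path)
    return (
        SyncPulseTrain(times=df["audio_time_s"].to_numpy(dtype=float)),
        SyncPulseTrain(times=df["neural_time_s"].to_numpy(dtype=float)),
    )
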