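"""Plain-file container I/O and configuration.

A recording is stored as a directory with two files: ``signal.raw`` — raw
little-endian 32-bit floats in channel-major frames (frame = all channels at
one sample time) — and ``recording.json`` with the sampling rate, channel
ids, geometry, event times and (for synthetic sessions) the ground-truth
block. Epochs and averaged responses use the same dialect with a
processing-history block. Scenario configurations are YAML files mirroring
``ScenarioConfig`` field for field. Write→read round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .containers import AveragedResponse, Epochs, Recording
from .geometry import geometry_from_dict
from .synthetic import ScenarioConfig

__all__ = [
    "save_recording", "load_recording",
    "save_epochs", "load_epochs",
    "save_averaged", "load_averaged",
    "load_scenario_config", "save_scenario_config",
    "export_map_tsv",
]

_RAW_NAME = "signal.raw"


def _write_raw(path: Path, array: np.ndarray) -> None:
    """Channel-major frames: disk layout is (samples, channels) float32 LE."""
    arr = np.ascontiguousarray(np.moveaxis(array, -2, -1), dtype="<f4")
    arr.tofile(path)


def _read_raw(path: Path, shape_ch_last: tuple) -> np.ndarray:
    arr = np.fromfile(path, dtype="<f4").reshape(shape_ch_last)
    return np.moveaxis(arr, -1, -2)


def save_recording(recording: Recording, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_raw(out / _RAW_NAME, recording.data)
    meta = {
        "container": "recording",
        "fs_hz": recording.fs,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "channel_ids": recording.channel_ids,
        "geometry": recording.geometry.to_dict(),
        "event_times_s": recording.event_times.tolist(),
        "ground_truth": recording.ground_truth,
        "provenance": recording.provenance,
        "dtype": "<f4",
        "frame_order": "sample-major frames, channel-major within frame",
    }
    (out / "recording.json").write_text(json.dumps(meta, indent=1))
    return out


def load_recording(in_dir) -> Recording:
    src = Path(in_dir)
    meta = json.loads((src / "recording.json").read_text())
    if meta.get("container") != "recording":
        raise ValueError(f"{src} does not hold a recording container")
    data = _read_raw(src / _RAW_NAME,
                     (meta["n_samples"], meta["n_channels"]))
    return Recording(
        data=data,
        fs=meta["fs_hz"],
        geometry=geometry_from_dict(meta["geometry"]),
        event_times=np.asarray(meta["event_times_s"]),
        ground_truth=meta.get("ground_truth"),
        provenance=meta.get("provenance", []),
    )


def save_epochs(epochs: Epochs, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_raw(out / _RAW_NAME, epochs.data)
    meta = {
        "container": "epochs",
        "fs_hz": epochs.fs,
        "pre_s": epochs.pre,
        "post_s": epochs.post,
        "shape": list(epochs.data.shape),
        "event_times_s": epochs.event_times.tolist(),
        "geometry": epochs.geometry.to_dict(),
        "bad_channels": sorted(epochs.bad_channels),
        "processing_history": epochs.provenance,
        "dtype": "<f4",
    }
    (out / "epochs.json").write_text(json.dumps(meta, indent=1))
    return out


def load_epochs(in_dir) -> Epochs:
    src = Path(in_dir)
    meta = json.loads((src / "epochs.json").read_text())
    if meta.get("container") != "epochs":
        raise ValueError(f"{src} does not hold an epochs container")
    trials, channels, times = meta["shape"]
    data = _read_raw(src / _RAW_NAME, (trials, times, channels))
    return Epochs(
        data=data, fs=meta["fs_hz"], pre=meta["pre_s"], post=meta["post_s"],
        event_times=np.asarray(meta["event_times_s"]),
        geometry=geometry_from_dict(meta["geometry"]),
        bad_channels=frozenset(meta.get("bad_channels", [])),
        provenance=meta.get("processing_history", []),
    )


def save_averaged(avg: AveragedResponse, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_raw(out / _RAW_NAME, avg.data)
    meta = {
        "container": "averaged_response",
        "fs_hz": avg.fs,
        "pre_s": avg.pre,
        "post_s": avg.post,
        "n_trials_averaged": avg.n_trials_averaged,
        "shape": list(avg.data.shape),
        "geometry": avg.geometry.to_dict(),
        "processing_history": avg.provenance,
        "dtype": "<f4",
    }
    (out / "averaged.json").write_text(json.dumps(meta, indent=1))
    return out


def load_averaged(in_dir) -> AveragedResponse:
    src = Path(in_dir)
    meta = json.loads((src / "averaged.json").read_text())
    if meta.get("container") != "averaged_response":
        raise ValueError(f"{src} does not hold an averaged-response container")
    channels, times = meta["shape"]
    data = _read_raw(src / _RAW_NAME, (times, channels))
    return AveragedResponse(
        data=data, fs=meta["fs_hz"], pre=meta["pre_s"], post=meta["post_s"],
        n_trials_averaged=meta["n_trials_averaged"],
        geometry=geometry_from_dict(meta["geometry"]),
        provenance=meta.get("processing_history", []),
    )


def save_scenario_config(config: ScenarioConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def load_scenario_config(path) -> ScenarioConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"{path} does not hold a scenario mapping")
    return ScenarioConfig.from_dict(d)


def export_map_tsv(tmap, path) -> Path:
    """Optional plain-matrix TSV export of a topographic map (μV)."""
    path = Path(path)
    header = (f"# step_um={tmap.step} origin_um={tmap.origin} "
              f"component={tmap.component} {tmap.axes}")
    with path.open("w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, tmap.field, delimiter="\t", fmt="%.6g")
    return path
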