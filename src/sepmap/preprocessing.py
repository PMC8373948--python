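"""Continuous recording → baseline-corrected, referenced, averaged epochs.

The canonical pipeline order is fixed and recorded in provenance:

    downsample → epoch → replace_bad_channels → average_reference
    → baseline_correct → average_epochs

Bad channels are replaced *before* the common average reference so a noisy
channel cannot contaminate the reference. Defaults mirror the standard
epidural workflow: downsample to 2 kHz, 1.5 s epochs (0.5 s pre / 1.0 s
post stimulus).
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import AveragedResponse, Epochs, Recording
from .geometry import GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "detect_stimulus_onsets",
    "downsample",
    "epoch",
    "replace_bad_channels",
    "average_reference",
    "baseline_correct",
    "average_epochs",
    "flag_bad_channels",
    "preprocess",
]


def detect_stimulus_onsets(trigger: np.ndarray, fs: float, threshold: float,
                           refractory: float) -> np.ndarray:
    """Times (s) of first supra-threshold crossings in a trigger trace.

    A crossing is a sample ≥ threshold whose predecessor is below it;
    crossings within ``refractory`` seconds of an accepted onset are
    suppressed (ringing on a piezo trace re-crosses many times per tap).
    """
    trigger = np.asarray(trigger, dtype=float)
    if trigger.ndim != 1:
        raise ValueError("trigger trace must be one-dimensional")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    if trigger.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(trigger)):
        raise ValueError("trigger trace contains non-finite samples")
    above = trigger >= threshold
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    onsets = []
    last = -math.inf
    ref_samples = refractory * fs
    for idx in crossings:
        if idx - last >= ref_samples:
            onsets.append(idx / fs)
            last = idx
    return np.asarray(onsets)


def downsample(recording: Recording, target_fs: float) -> Recording:
    """Anti-aliased downsampling to ``target_fs`` (DC level preserved).

    A zero-phase Butterworth low-pass at 0.4 × target_fs precedes decimation
    (zero-phase, so evoked latencies are not biased). Integer decimation is
    used when the ratio is integral, polyphase resampling otherwise.
    """
    if target_fs > recording.fs:
        raise ValueError(
            f"target_fs {target_fs} exceeds recording fs {recording.fs}"
        )
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    step = {"step": "downsample", "from_fs": recording.fs, "to_fs": target_fs}
    if target_fs == recording.fs:
        return recording.with_data(recording.data.copy(), step=step)

    cutoff = 0.4 * target_fs
    sos = signal.butter(8, cutoff, btype="low", fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data.astype(float), axis=1)
    ratio = recording.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:, :: int(round(ratio))]
    else:
        frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
        out = signal.resample_poly(filtered, frac.numerator, frac.denominator,
                                   axis=1)
    return recording.with_data(np.ascontiguousarray(out), fs=target_fs,
                               step=step)


def epoch(recording: Recording, events: np.ndarray | None = None,
          pre: float = 0.5, post: float = 1.0) -> Epochs:
    """Cut stimulus-aligned epochs of (pre + post) s around each event.

    Events too close to the record edges for a full window are dropped (the
    count is logged). Sample ``round(pre·fs)`` of every epoch falls on the
    stimulus time.
    """
    if events is None:
        events = recording.event_times
    events = np.asarray(events, dtype=float)
    fs = recording.fs
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    n_len = n_pre + n_post
    starts, kept = [], []
    for t in events:
        i0 = int(round(t * fs)) - n_pre
        if i0 >= 0 and i0 + n_len <= recording.n_samples:
            starts.append(i0)
            kept.append(t)
    dropped = len(events) - len(kept)
    if dropped:
        logger.info("epoch: dropped %d/%d events without a full window",
                    dropped, len(events))
    if not kept:
        raise ValueError("no events with a complete epoch window remain")
    data = np.stack(
        [recording.data[:, i0:i0 + n_len] for i0 in starts]
    ).astype(float)
    return Epochs(
        data=data, fs=fs, pre=pre, post=post,
        event_times=np.asarray(kept), geometry=recording.geometry,
        provenance=list(recording.provenance) + [{
            "step": "epoch", "pre_s": pre, "post_s": post,
            "n_events": len(events), "n_dropped": dropped,
        }],
    )


def replace_bad_channels(epochs: Epochs, bad) -> Epochs:
    """Replace declared bad channels by the mean of their good 4-neighbors.

    ``bad`` may contain channel ids ("C5") or integer indices. Edge and
    corner channels use whichever of their (2–4) neighbors exist; a bad
    channel whose neighbors are all bad is rejected. Replacement is per
    trial and per sample; good channels are untouched.
    """
    geom = epochs.geometry
    if not bad:
        return epochs.with_data(epochs.data.copy(),
                                step={"step": "replace_bad_channels",
                                      "bad": []})
    if not isinstance(geom, GridGeometry):
        raise TypeError("bad-channel replacement is defined on grid geometry")
    ids = geom.channel_ids
    bad_idx = set()
    for b in bad:
        if isinstance(b, str):
            if b not in ids:
                raise ValueError(f"unknown channel id {b!r}")
            bad_idx.add(ids.index(b))
        else:
            bad_idx.add(int(b))
    data = epochs.data.copy()
    for idx in sorted(bad_idx):
        good = [n for n in geom.neighbors4(idx) if n not in bad_idx]
        if not good:
            raise ValueError(
                f"bad channel {ids[idx]} has no good 4-neighbor; declare "
                "fewer adjacent bad channels or drop the channel instead"
            )
        data[:, idx, :] = epochs.data[:, good, :].mean(axis=1)
    return epochs.with_data(
        data, step={"step": "replace_bad_channels",
                    "bad": sorted(ids[i] for i in bad_idx)},
        bad_channels=frozenset(ids[i] for i in bad_idx),
    )


def average_reference(epochs: Epochs) -> Epochs:
    """Subtract the instantaneous across-channel mean (common average).

    After this, the mean across channels is zero at every trial and time
    sample; applying it twice equals applying it once.
    """
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(data, step={"step": "average_reference"})


def baseline_correct(epochs: Epochs) -> Epochs:
    """Subtract each trial/channel's pre-stimulus mean (idempotent)."""
    n_pre = epochs.stim_index
    if n_pre < 1:
        raise ValueError("pre-stimulus window is empty")
    base = epochs.data[:, :, :n_pre].mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - base,
                            step={"step": "baseline_correct"})


def average_epochs(epochs: Epochs) -> AveragedResponse:
    """Sample-wise arithmetic mean across trials."""
    return AveragedResponse(
        data=epochs.data.mean(axis=0),
        fs=epochs.fs, pre=epochs.pre, post=epochs.post,
        n_trials_averaged=epochs.n_trials,
        geometry=epochs.geometry,
        provenance=list(epochs.provenance) + [{
            "step": "average_epochs", "n_trials": epochs.n_trials,
        }],
    )


def flag_bad_channels(recording: Recording, z_threshold: float = 5.0) -> list:
    """Optional automatic flagger: per-channel RMS z-score > threshold.

    Off by default in the pipeline — bad channels are normally declared by
    the experimenter.
    """
    rms = np.sqrt(np.mean(recording.data.astype(float) ** 2, axis=1))
    med = np.median(rms)
    mad = np.median(np.abs(rms - med)) * 1.4826
    if mad == 0:
        return []
    z = (rms - med) / mad
    return [recording.channel_ids[i] for i in np.flatnonzero(z > z_threshold)]


def preprocess(recording: Recording, target_fs: float = 2000.0,
               pre: float = 0.5, post: float = 1.0,
               bad_channels=()) -> AveragedResponse:
    """Run the fixed pipeline end to end and return the averaged response."""
    rec = downsample(recording, target_fs)
    ep = epoch(rec, pre=pre, post=post)
    ep = replace_bad_channels(ep, bad_channels)
    ep = average_reference(ep)
    ep = baseline_correct(ep)
    return average_epochs(ep)
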