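"""Depth-resolved probe analysis: MUA detection, PSTH, LFP and CSD.

The multiunit branch band-passes the wideband signal to 0.25–4 kHz, detects
spikes by a negative amplitude threshold at −k × robust SD (median absolute
deviation based — a deliberate simplification of template-based sorting:
only multiunit activity is analyzed), and accumulates peristimulus time
histograms in 5 ms bins. The LFP branch low-passes and downsamples to 2 kHz
and computes the one-dimensional current source density as the negative
second spatial difference of the trial-averaged depth profile — sinks
(inward current) are negative, volume-conducted (depth-constant) components
cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import AveragedResponse, Recording
from .geometry import ProbeGeometry
from . import preprocessing

__all__ = [
    "SpikeTrain",
    "PSTH",
    "CSDMap",
    "bandpass_mua",
    "detect_spikes",
    "psth",
    "extract_lfp",
    "csd",
]


@dataclass(frozen=True)
class SpikeTrain:
    times: np.ndarray  # s, strictly increasing
    channel: str
    threshold_used: float  # μV (negative)

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PSTH:
    """Peristimulus spike counts summed over trials: (n_bins, n_channels)."""

    counts: np.ndarray  # non-negative integers
    bin_width: float  # ms
    window: tuple[float, float]  # (pre, post) ms relative to stimulus
    n_trials: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + self.bin_width / 2,
                         self.bin_width)

    def rate_hz(self) -> np.ndarray:
        """Mean firing rate per bin and channel in Hz."""
        return self.counts / (self.n_trials * self.bin_width / 1000.0)


@dataclass(frozen=True)
class CSDMap:
    """Current source density at interior depths: (n_sites − 2, n_times).

    Units are μV/μm² times unit conductivity (arbitrary scale); the sign
    convention puts sinks negative.
    """

    values: np.ndarray
    depths: np.ndarray  # μm, interior sites
    fs: float
    pre: float  # s, as in the source averaged response

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.fs - self.pre

    def sink(self) -> tuple[float, float]:
        """(depth μm, time ms) of the most negative CSD value."""
        i, j = np.unravel_index(int(np.argmin(self.values)),
                                self.values.shape)
        return float(self.depths[i]), float(self.times[j] * 1000.0)


def bandpass_mua(recording: Recording, low: float = 250.0,
                 high: float = 4000.0) -> Recording:
    """Zero-phase 0.25–4 kHz band-pass isolating the multiunit band."""
    if recording.fs <= 2.0 * high:
        raise ValueError(
            f"fs {recording.fs} too low for a {high} Hz band edge"
        )
    sos = signal.butter(4, [low, high], btype="band", fs=recording.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, recording.data.astype(float), axis=1)
    return recording.with_data(out, step={
        "step": "bandpass_mua", "low_hz": low, "high_hz": high,
    })


def detect_spikes(recording: Recording, k: float = 4.5,
                  refractory: float = 1.0) -> list[SpikeTrain]:
    """Negative-threshold multiunit detection on a band-passed recording.

    Per channel: robust SD = MAD/0.6745; threshold = −k × SD; each spike
    time is the trough of a sub-threshold excursion; a refractory period
    (ms) suppresses re-triggering on the same excursion.
    """
    fs = recording.fs
    ref_samples = max(1, int(round(refractory / 1000.0 * fs)))
    trains = []
    for ch in range(recording.n_channels):
        x = recording.data[ch].astype(float)
        mad = np.median(np.abs(x - np.median(x)))
        sd = mad / 0.6745
        thr = -k * sd
        times: list[float] = []
        if sd > 0:
            below = x < thr
            # excursion starts: below-threshold runs
            starts = np.flatnonzero(below & ~np.concatenate(([False],
                                                             below[:-1])))
            last = -ref_samples
            for s in starts:
                e = s
                while e < x.size and x[e] < thr:
                    e += 1
                trough = s + int(np.argmin(x[s:e]))
                if trough - last >= ref_samples:
                    times.append(trough / fs)
                    last = trough
        trains.append(SpikeTrain(
            times=np.asarray(times),
            channel=recording.channel_ids[ch],
            threshold_used=thr,
        ))
    return trains


def psth(trains: list[SpikeTrain], events: np.ndarray,
         bin_width: float = 5.0,
         window: tuple[float, float] = (-100.0, 300.0)) -> PSTH:
    """Histogram of spike times relative to each event, summed over trials.

    Bins are half-open [left, right): a spike exactly on a bin's left edge
    counts in that bin. Total counts equal the number of in-window spikes.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    events = np.asarray(events, dtype=float)
    edges = np.arange(window[0], window[1] + bin_width / 2.0, bin_width)
    n_bins = edges.size - 1
    counts = np.zeros((n_bins, len(trains)), dtype=int)
    for ci, train in enumerate(trains):
        if train.times.size == 0:
            continue
        for ev in events:
            # round to ns so a spike constructed exactly on a bin edge is
            # not displaced by float round-off
            rel = np.round((train.times - ev) * 1000.0, 9)  # ms
            sel = rel[(rel >= edges[0]) & (rel < edges[-1])]
            idx = np.floor((sel - edges[0]) / bin_width).astype(int)
            np.add.at(counts[:, ci], idx, 1)
    return PSTH(counts=counts, bin_width=bin_width,
                window=(float(edges[0]), float(edges[-1])),
                n_trials=events.size)


def extract_lfp(recording: Recording, target_fs: float = 2000.0) -> Recording:
    """LFP branch: anti-aliased low-pass + downsample (mirrors the grid path)."""
    return preprocessing.downsample(recording, target_fs)


def csd(avg: AveragedResponse, spacing: float | None = None) -> CSDMap:
    """One-dimensional CSD of a trial-averaged laminar LFP.

    CSD_i(t) = −(φ_{i−1} − 2φ_i + φ_{i+1}) / h² at interior sites; the two
    edge sites are dropped (no Vaknin padding, unit conductivity). Linear
    depth profiles map to identically zero CSD, and any depth-constant
    offset — pure volume conduction — cancels exactly.
    """
    geom = avg.geometry
    if isinstance(geom, ProbeGeometry):
        depths = geom.depths
        h = spacing if spacing is not None else geom.site_spacing
        site_spacing = np.diff(depths)
        if not np.allclose(site_spacing, site_spacing[0]):
            raise ValueError("CSD requires uniformly spaced sites")
    else:
        if spacing is None:
            raise ValueError("spacing must be given for non-probe input")
        h = spacing
        depths = np.arange(avg.n_channels) * h
    if avg.n_channels < 3:
        raise ValueError("CSD needs at least 3 sites")
    phi = avg.data
    second_diff = phi[:-2] - 2.0 * phi[1:-1] + phi[2:]
    values = -second_diff / (h * h)
    return CSDMap(values=values, depths=np.asarray(depths[1:-1], dtype=float),
                  fs=avg.fs, pre=avg.pre)
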