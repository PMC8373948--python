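"""In-memory containers shared by all pipeline stages.

``Recording`` holds a continuous multichannel signal (channels × samples,
μV) together with its geometry, sampling rate, stimulus event times and — for
synthetic sessions — a ground-truth block. ``Epochs`` and ``AveragedResponse``
are the epoched and trial-averaged views produced by preprocessing. Every
container carries a ``provenance`` list of processing-step records so a
report can be traced back to the operations that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .geometry import GridGeometry, ProbeGeometry

Geometry = Union[GridGeometry, ProbeGeometry]

__all__ = ["Recording", "Epochs", "AveragedResponse"]


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples), μV
    fs: float  # Hz
    geometry: Geometry
    event_times: np.ndarray  # s from recording start
    ground_truth: dict | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be (n_channels, n_samples)")
        if self.data.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but geometry "
                f"declares {self.geometry.n_channels}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.event_times = np.asarray(self.event_times, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_ids(self) -> list[str]:
        return self.geometry.channel_ids

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  step: dict | None = None) -> "Recording":
        """Copy with new samples (and optionally rate), provenance appended."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            geometry=self.geometry,
            event_times=self.event_times.copy(),
            ground_truth=self.ground_truth,
            provenance=prov,
        )


@dataclass
class Epochs:
    """Stimulus-aligned trials: (n_trials, n_channels, n_times).

    Sample ``int(pre * fs)`` of every trial falls on the stimulus time.
    """

    data: np.ndarray
    fs: float
    pre: float  # s before stimulus
    post: float  # s after stimulus
    event_times: np.ndarray  # retained events, s
    geometry: Geometry
    bad_channels: frozenset = frozenset()
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Epochs data must be (trials, channels, times)")
        if self.pre <= 0 or self.post <= 0:
            raise ValueError("pre and post windows must be positive")
        n_expected = int(round((self.pre + self.post) * self.fs))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != (pre+post)*fs = "
                f"{n_expected}"
            )
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.bad_channels = frozenset(self.bad_channels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def stim_index(self) -> int:
        return int(round(self.pre * self.fs))

    @property
    def times(self) -> np.ndarray:
        """Time axis in s relative to stimulus onset."""
        return np.arange(self.n_times) / self.fs - self.pre

    def with_data(self, data: np.ndarray, step: dict | None = None,
                  bad_channels=None) -> "Epochs":
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return Epochs(
            data=data,
            fs=self.fs,
            pre=self.pre,
            post=self.post,
            event_times=self.event_times.copy(),
            geometry=self.geometry,
            bad_channels=self.bad_channels if bad_channels is None
            else frozenset(bad_channels),
            provenance=prov,
        )


@dataclass
class AveragedResponse:
    """Trial-averaged evoked response: (n_channels, n_times)."""

    data: np.ndarray
    fs: float
    pre: float
    post: float
    n_trials_averaged: int
    geometry: Geometry
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("AveragedResponse data must be (channels, times)")
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def stim_index(self) -> int:
        return int(round(self.pre * self.fs))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs - self.pre

    def time_to_index(self, t_ms: float) -> float:
        """Fractional sample index of a post-stimulus time in ms."""
        return self.pre * self.fs + (t_ms / 1000.0) * self.fs
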