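"""In-memory containers for epoched EEG data.

Two array containers are used throughout the package:

* :class:`EpochSet` — spontaneous EEG cut into fixed-length epochs,
  shaped ``(n_epochs, n_channels, n_samples)``, in microvolts.
* :class:`TepSet` — a TMS-evoked trial set shaped
  ``(n_trials, n_channels, n_samples)`` with the sample index of the
  stimulus pulse, so that window definitions in milliseconds relative
  to the pulse can be mapped onto samples.

Window convention: all windows are half-open sample ranges
``[start, end)``; millisecond bounds are converted with ``floor`` at the
start and ``ceil`` at the end, relative to the stimulus-onset sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def ms_to_sample_window(window_ms: tuple[float, float], fs: float,
                        onset_idx: int = 0) -> tuple[int, int]:
    """Convert an (start_ms, end_ms) window to a half-open sample range.

    ``floor`` at the start and ``ceil`` at the end so the returned range
    covers the full requested span; ``onset_idx`` is the sample of t=0.
    """
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError(f"empty window {window_ms!r}")
    start = onset_idx + math.floor(lo * fs / 1000.0)
    end = onset_idx + math.ceil(hi * fs / 1000.0)
    return start, end


@dataclass
class EpochSet:
    """Fixed-length spontaneous-EEG epochs (epoch x channel x sample), µV."""

    data: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be (epoch, channel, sample)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [f"CH{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TepSet:
    """TMS-evoked trial set (trial x channel x sample), µV.

    ``onset_idx`` is the 0-based sample index of the stimulus pulse
    (time 0); samples before it are pre-stimulus baseline.
    """

    data: np.ndarray
    fs: float
    onset_idx: int
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("TepSet.data must be (trial, channel, sample)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0 <= self.onset_idx < self.data.shape[2]:
            raise ValueError("stimulus onset outside the epoch")
        if not self.channels:
            self.channels = [f"CH{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus pulse."""
        return (np.arange(self.n_samples) - self.onset_idx) * 1000.0 / self.fs

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        start, end = ms_to_sample_window(window_ms, self.fs, self.onset_idx)
        if start < 0 or end > self.n_samples:
            raise ValueError(
                f"window {window_ms!r} ms falls outside the epoch "
                f"({self.times_ms[0]:.1f}..{self.times_ms[-1]:.1f} ms)")
        return slice(start, end)
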