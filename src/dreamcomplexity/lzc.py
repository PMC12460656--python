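"""Single-channel Lempel-Ziv complexity (LZc) of spontaneous EEG.

The measure quantifies the temporal diversity of the instantaneous
amplitude of an EEG channel:

1. take the analytic-signal envelope (modulus of signal + i·Hilbert),
2. binarize it at its median within the calculation window
   (strictly-greater-than-median -> 1),
3. count LZ76 words in the binary sequence,
4. normalize by the word count of the same sequence after a single
   random shuffle (which preserves the 0/1 multiset but destroys
   temporal structure).

A recording-level value is the mean over 5-second epochs within each
channel, then the mean over channels.  Values near 1 indicate
noise-like, incompressible envelopes; rhythmic or slow-wave-dominated
signals score lower.

Tie policy: envelope samples exactly equal to the median map to 0; the
threshold is strict.  The single shuffle per window is seeded
deterministically from the global seed and a checksum of the window's
binarized sequence, so results do not depend on computation order or on
how channels and epochs are arranged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from ._lz76 import lz76_count
from .containers import EpochSet

__all__ = [
    "LzcResult",
    "analytic_amplitude",
    "binarize_median",
    "lz76_count",
    "normalize_by_shuffle",
    "lzc_series",
    "lzc_recording",
    "time_resolved_lzc",
]


@dataclass
class LzcResult:
    """Normalized LZc values for one recording."""

    per_epoch_per_channel: np.ndarray  # (n_epochs, n_channels)
    recording_value: float
    n_epochs: int
    n_channels: int
    shuffle_seed: int


def analytic_amplitude(x) -> np.ndarray:
    """Envelope of ``x``: pointwise modulus of the analytic signal."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("expected a 1-D series of length >= 8")
    if not np.isfinite(x).all():
        raise ValueError("input contains NaN or Inf")
    return np.abs(hilbert(x))


def binarize_median(envelope) -> np.ndarray:
    """Binarize an envelope at its within-window median (strict >)."""
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    return (env > np.median(env)).astype(np.uint8)


def normalize_by_shuffle(c: int, bits, seed) -> float:
    """Normalize an LZ76 count by that of a single random shuffle.

    ``seed`` may be anything acceptable to :func:`numpy.random.default_rng`
    (an int or a sequence of ints).
    """
    bits = np.asarray(bits, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(bits)
    return c / lz76_count(shuffled)


def _lzc_window(x: np.ndarray, seed: int) -> float:
    """Full per-window pipeline: envelope -> median binarize -> LZ76 -> shuffle norm.

    The shuffle seed combines the global seed with a CRC of the
    binarized window, making the value independent of where in the
    recording the window sits.
    """
    bits = binarize_median(analytic_amplitude(x))
    c = lz76_count(bits)
    key = [int(seed), zlib.crc32(bits.tobytes())]
    return normalize_by_shuffle(c, bits, key)


def lzc_series(x, seed: int = 0) -> float:
    """Normalized LZc of a single-channel series treated as one window."""
    return _lzc_window(np.asarray(x, dtype=float), int(seed))


def lzc_recording(e: EpochSet, epoch_length: float = 5.0,
                  seed: int = 0) -> LzcResult:
    """Recording-level LZc: mean over 5-s epochs, then over channels.

    Each stored epoch is cut into consecutive non-overlapping windows of
    ``epoch_length`` seconds (incomplete trailing windows are dropped);
    envelope and median are computed within each window.
    """
    win = int(round(epoch_length * e.fs))
    n_win_per_epoch = e.n_samples // win
    if n_win_per_epoch < 1:
        raise ValueError(
            f"epochs of {e.epoch_duration:.2f} s are shorter than the "
            f"{epoch_length:.2f} s calculation window")
    values = np.empty((e.n_epochs * n_win_per_epoch, e.n_channels))
    for ch in range(e.n_channels):
        w = 0
        for ep in range(e.n_epochs):
            for j in range(n_win_per_epoch):
                seg = e.data[ep, ch, j * win:(j + 1) * win]
                values[w, ch] = _lzc_window(seg, seed)
                w += 1
    # mean over epochs within channel, then over channels
    recording_value = float(values.mean(axis=0).mean())
    return LzcResult(per_epoch_per_channel=values,
                     recording_value=recording_value,
                     n_epochs=values.shape[0],
                     n_channels=e.n_channels,
                     shuffle_seed=int(seed))


def time_resolved_lzc(x, fs: float, window: float, step: float,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window LZc of a single-channel series.

    Returns (window center times in s, normalized LZc per window).  The
    envelope and median threshold are computed within each window.
    """
    x = np.asarray(x, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    win = int(round(window * fs))
    hop = int(round(step * fs))
    if hop < 1:
        raise ValueError("step shorter than one sample")
    if win > x.size:
        raise ValueError("window longer than the series")
    starts = range(0, x.size - win + 1, hop)
    centers = np.array([(s + win / 2.0) / fs for s in starts])
    values = np.array([_lzc_window(x[s:s + win], int(seed)) for s in starts])
    return centers, values
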