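"""Readers and writers for epoch containers and measure tables.

The package's native epoch container is a NumPy ``.npz`` archive with a
JSON header; it round-trips :class:`EpochSet` and :class:`TepSet`
losslessly.  Adapters for BrainVision (``.vhdr``/``.vmrk``/``.eeg``) and
EDF+ recordings are provided through MNE-Python when it is installed;
they cut continuous recordings into fixed-length epochs or
stimulus-locked trials.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .containers import EpochSet, TepSet

__all__ = [
    "write_epochs", "read_epochs", "resample_epochs",
    "read_raw_epochs", "read_raw_tep",
    "write_measure_table", "read_measure_table", "validate_measure_table",
]

_SUPPORTED = (".npz (native container)", ".vhdr (BrainVision)", ".edf (EDF+)")

MEASURE_COLUMNS = ["participant_id", "condition", "measure", "value",
                   "experience_class"]


def write_epochs(obj: EpochSet | TepSet, path) -> None:
    """Write an epoch container to the native ``.npz`` format."""
    path = Path(path)
    header = {"fs": obj.fs, "channels": obj.channels,
              "kind": "tep" if isinstance(obj, TepSet) else "epochs"}
    if isinstance(obj, TepSet):
        header["onset_idx"] = int(obj.onset_idx)
    np.savez(path, data=obj.data, header=json.dumps(header))


def _read_container(path: Path) -> EpochSet | TepSet:
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        data = npz["data"]
    if header["kind"] == "tep":
        return TepSet(data=data, fs=header["fs"],
                      onset_idx=header["onset_idx"],
                      channels=list(header["channels"]))
    return EpochSet(data=data, fs=header["fs"],
                    channels=list(header["channels"]))


def read_epochs(path, format: str | None = None, **kwargs
                ) -> EpochSet | TepSet:
    """Read an epoch container; format inferred from the extension.

    Raw-recording formats accept the keyword arguments of
    :func:`read_raw_epochs` / :func:`read_raw_tep` (``epoch_length`` or
    ``epoch_window`` selects the container kind).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "npz":
        return _read_container(path)
    if fmt in ("vhdr", "brainvision", "edf"):
        if "epoch_window" in kwargs:
            return read_raw_tep(path, **kwargs)
        return read_raw_epochs(path, **kwargs)
    raise ValueError(
        f"unsupported format {fmt!r}; supported: {', '.join(_SUPPORTED)}")


def resample_epochs(e: EpochSet | TepSet, fs_new: float) -> EpochSet | TepSet:
    """Polyphase resampling of an epoch container to ``fs_new`` Hz."""
    if fs_new <= 0:
        raise ValueError("target sampling rate must be positive")
    frac = Fraction(fs_new / e.fs).limit_denominator(10000)
    data = resample_poly(e.data, frac.numerator, frac.denominator, axis=2)
    if isinstance(e, TepSet):
        onset = int(round(e.onset_idx * fs_new / e.fs))
        return TepSet(data=data, fs=fs_new, onset_idx=onset,
                      channels=list(e.channels))
    return EpochSet(data=data, fs=fs_new, channels=list(e.channels))


def _load_raw(path: Path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading raw EEG formats requires the optional dependency "
            "mne (pip install dreamcomplexity[eeg])") from exc
    suffix = path.suffix.lower()
    try:
        if suffix == ".vhdr":
            return mne.io.read_raw_brainvision(path, preload=True,
                                               verbose="error")
        if suffix == ".edf":
            return mne.io.read_raw_edf(path, preload=True, verbose="error")
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"incomplete recording {path.name}: {exc}") from exc
    raise ValueError(
        f"unsupported raw format {suffix!r}; supported: {', '.join(_SUPPORTED)}")


def read_raw_epochs(path, epoch_length: float = 5.0,
                    resample_to: float | None = None) -> EpochSet:
    """Cut a continuous BrainVision/EDF+ recording into fixed epochs."""
    path = Path(path)
    raw = _load_raw(path)
    raw = raw.pick("eeg")
    if resample_to is not None:
        raw = raw.resample(resample_to)
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    win = int(round(epoch_length * fs))
    n_epochs = data.shape[1] // win
    if n_epochs < 1:
        raise ValueError(f"recording shorter than one {epoch_length}-s epoch")
    epochs = np.stack([data[:, i * win:(i + 1) * win]
                       for i in range(n_epochs)])
    return EpochSet(data=epochs, fs=fs, channels=list(raw.ch_names))


def read_raw_tep(path, epoch_window: tuple[float, float] = (-250.0, 500.0),
                 resample_to: float | None = None,
                 stim_channel: str | None = None) -> TepSet:
    """Cut a raw recording into stimulus-locked trials (time 0 = pulse)."""
    import mne

    path = Path(path)
    raw = _load_raw(path)
    if resample_to is not None:
        raw = raw.resample(resample_to)
    try:
        events = mne.events_from_annotations(raw, verbose="error")[0]
    except ValueError:
        events = mne.find_events(raw, stim_channel=stim_channel,
                                 verbose="error")
    if len(events) == 0:
        raise ValueError(f"no stimulus markers found in {path.name}")
    raw = raw.pick("eeg")
    fs = float(raw.info["sfreq"])
    lo, hi = epoch_window
    epochs = mne.Epochs(raw, events, tmin=lo / 1000.0, tmax=hi / 1000.0,
                        baseline=None, preload=True, verbose="error")
    data = epochs.get_data() * 1e6
    onset = int(round(-lo * fs / 1000.0))
    return TepSet(data=data, fs=fs, onset_idx=onset,
                  channels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# Measure tables


def validate_measure_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a tidy per-recording measure table."""
    missing = set(MEASURE_COLUMNS[:4]) - set(table.columns)
    if missing:
        raise ValueError(f"measure table missing columns {sorted(missing)}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("measure table contains non-finite values")
    keys = table[["participant_id", "condition", "measure"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (participant, condition, measure) row "
                         f"{dup}")
    return table


def write_measure_table(table: pd.DataFrame, path) -> None:
    validate_measure_table(table)
    cols = [c for c in MEASURE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_measure_table(path) -> pd.DataFrame:
    return validate_measure_table(pd.read_csv(path))
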