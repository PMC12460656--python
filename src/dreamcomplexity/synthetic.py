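"""Synthetic EEG, TMS-evoked trial sets, and awakening-report tables.

The generators emulate the statistical structure the analysis pipeline
assumes, so every downstream stage can be exercised without any
recorded data:

* :func:`gen_spontaneous` — multichannel spontaneous EEG as a sum of
  1/f^alpha background noise and amplitude-modulated band-limited
  oscillators mixed through smooth random channel topographies.  Three
  default state profiles mirror the recorded conditions: wakefulness
  with eyes open, wakefulness with eyes closed (elevated alpha), and
  deep propofol sedation (dominant slow-wave power, steeper spectral
  slope).
* :func:`gen_tep` — TMS-evoked trial sets: each trial is pink noise
  plus an identical deterministic evoked waveform (a sum of damped
  sinusoids with per-component latency, frequency and topography)
  starting at the stimulus pulse.  The number of distinct components
  controls the spatiotemporal complexity of the evoked response.
* :func:`gen_reports` / :func:`fixture_joint_table` — awakening-report
  tables whose Q1/Q2/class marginals equal the packaged study-level
  counts (52 awakenings; Q1 1/28/2/9/12; Q2 8/22/4/18; classes
  24/23/5).  The published joint Q1 x Q2 table is a color-coded figure,
  so a deterministic constraint-consistent reconstruction is used.

All generators are bitwise reproducible under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import EpochSet, TepSet
from .reports import (AwakeningReport, ClassificationRule, Q1_CATEGORIES,
                      Q2_CATEGORIES, EXPERIENCE_CLASSES, default_rule)

__all__ = [
    "BANDS", "StateProfile", "default_profiles",
    "gen_spontaneous",
    "TepComponent", "TepSpec", "make_tep_spec", "wake_tep_spec",
    "sedation_tep_spec", "gen_tep",
    "ReportMarginals", "default_marginals", "default_awakening_counts",
    "fixture_joint_table", "gen_reports",
]

#: Named frequency bands (Hz) used by the state profiles.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class StateProfile:
    """Spectral recipe for one recorded condition.

    ``band_powers`` maps band name to oscillator RMS amplitude relative
    to ``broadband_rms``; ``one_over_f_exponent`` is the spectral slope
    of the background noise; ``broadband_rms`` is the per-channel RMS of
    the background in microvolts.
    """

    name: str
    band_powers: dict[str, float]
    one_over_f_exponent: float
    broadband_rms: float

    def __post_init__(self) -> None:
        for band, amp in self.band_powers.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if amp < 0:
                raise ValueError(f"negative power for band {band!r}")
        if self.broadband_rms < 0:
            raise ValueError("broadband_rms must be non-negative")


def default_profiles() -> dict[str, StateProfile]:
    """The three packaged state profiles.

    Sedation has markedly higher delta amplitude and a steeper spectral
    slope than wakefulness; eyes-closed wakefulness doubles the alpha
    amplitude of eyes-open.  Amplitudes are in units of the broadband
    RMS (10 µV awake, 15 µV sedated).
    """
    return {
        "wake_eo": StateProfile(
            "wake_eo",
            {"delta": 0.25, "theta": 0.25, "alpha": 0.35, "beta": 0.45},
            one_over_f_exponent=1.0, broadband_rms=10.0),
        "wake_ec": StateProfile(
            "wake_ec",
            {"delta": 0.25, "theta": 0.25, "alpha": 0.70, "beta": 0.45},
            one_over_f_exponent=1.0, broadband_rms=10.0),
        "sedation": StateProfile(
            "sedation",
            {"delta": 1.80, "theta": 0.50, "alpha": 0.25, "beta": 0.15},
            one_over_f_exponent=2.0, broadband_rms=15.0),
    }


def _powerlaw_noise(rng: np.random.Generator, n: int, exponent: float,
                    n_series: int = 1, fs: float | None = None,
                    highpass_hz: float | None = None) -> np.ndarray:
    """(n_series, n) noise with power spectrum ~ 1/f^exponent, unit RMS.

    With ``highpass_hz`` set (requires ``fs``), the 1/f shaping is
    flattened below that frequency and a second-order high-pass
    shoulder applied, emulating the drift-free character of cleaned,
    baseline-corrected epochs.
    """
    white = rng.standard_normal((n_series, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs if fs else 1.0)
    scale = np.zeros_like(freqs)
    if highpass_hz:
        eff = np.maximum(freqs[1:], highpass_hz)
        ratio = freqs[1:] / highpass_hz
        hp = ratio ** 2 / np.sqrt(1.0 + ratio ** 4)
        scale[1:] = eff ** (-exponent / 2.0) * hp
    else:
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def _smooth_topography(rng: np.random.Generator, n_channels: int,
                       unit_rms: bool = True) -> np.ndarray:
    """Random channel-weight vector smoothed over a 1-D channel ordering."""
    w = rng.standard_normal(n_channels)
    if n_channels > 2:
        w = gaussian_filter1d(w, sigma=max(1.0, n_channels / 8.0),
                              mode="wrap")
    norm = np.sqrt(np.mean(w ** 2)) if unit_rms else np.linalg.norm(w)
    if norm == 0:  # pragma: no cover - measure-zero draw
        w = np.ones(n_channels)
        norm = np.sqrt(np.mean(w ** 2)) if unit_rms else np.linalg.norm(w)
    return w / norm


def _am_envelope(rng: np.random.Generator, n: int, fs: float,
                 depth: float = 0.5) -> np.ndarray:
    """Slow (~0.5 s scale) non-negative random amplitude envelope."""
    z = rng.standard_normal(n)
    z = gaussian_filter1d(z, sigma=0.3 * fs, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = z / sd
    return np.clip(1.0 + depth * z, 0.0, None)


def gen_spontaneous(profile: StateProfile, n_channels: int, duration: float,
                    fs: float, seed: int) -> EpochSet:
    """Spontaneous multichannel EEG cut into 5-second epochs.

    Each channel is a sum of 1/f^alpha background noise and one
    amplitude-modulated oscillator per band, mixed through smooth random
    topographies.  ``floor(duration / 5)`` epochs are returned.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration < 5:
        raise ValueError("duration must be >= 5 s (one epoch)")
    rng = np.random.default_rng(int(seed))
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    data = profile.broadband_rms * _powerlaw_noise(
        rng, n, profile.one_over_f_exponent, n_channels)

    for band in BANDS:  # fixed iteration order for determinism
        amp = profile.band_powers.get(band, 0.0) * profile.broadband_rms
        lo, hi = BANDS[band]
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = _am_envelope(rng, n, fs)
        osc = env * np.cos(2.0 * np.pi * f * t + phase)
        rms = osc.std()
        if rms > 0:
            osc = osc / rms
        topo = _smooth_topography(rng, n_channels, unit_rms=True)
        data += amp * np.outer(topo, osc)

    n_epochs = int(duration // 5)
    win = int(round(5 * fs))
    epochs = np.stack([data[:, i * win:(i + 1) * win]
                       for i in range(n_epochs)])
    return EpochSet(data=epochs, fs=fs)


# ---------------------------------------------------------------------------
# TMS-evoked trial sets


@dataclass(frozen=True)
class TepComponent:
    """One damped oscillatory component of the evoked response."""

    frequency_hz: float
    damping_ms: float
    latency_ms: float
    amplitude_uv: float
    topography: np.ndarray | None = None  # unit-norm over channels, or None


@dataclass
class TepSpec:
    """Recipe for a synthetic TMS-evoked trial set."""

    components: list[TepComponent] = field(default_factory=list)
    trial_noise_rms: float = 10.0
    n_trials: int = 60

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_noise_rms < 0:
            raise ValueError("trial_noise_rms must be non-negative")


def _component_waveform(comp: TepComponent, t_ms: np.ndarray) -> np.ndarray:
    """Damped sinusoid starting at the component latency (zero before)."""
    dt = t_ms - comp.latency_ms
    active = dt >= 0
    y = np.zeros_like(t_ms)
    y[active] = (comp.amplitude_uv
                 * np.exp(-dt[active] / comp.damping_ms)
                 * np.sin(2.0 * np.pi * comp.frequency_hz * dt[active] / 1000.0))
    return y


def make_tep_spec(n_components: int, n_channels: int = 8,
                  n_trials: int = 60, trial_noise_rms: float = 10.0,
                  total_energy: float | None = None,
                  fs: float = 500.0,
                  epoch_window: tuple[float, float] = (-250.0, 500.0),
                  seed: int = 0) -> TepSpec:
    """Deterministic K-component evoked recipe with smooth topographies.

    Component frequencies, latencies and damping constants are drawn
    from fixed tables spanning alpha-to-gamma carriers (8-48 Hz) with
    15-100 ms onset latencies and ~220 ms damping, so a rich response
    stays active across the full analysis window.  If ``total_energy`` is given, amplitudes are
    rescaled so the summed single-trial evoked energy (µV²·samples at
    ``fs`` over ``epoch_window``) is exactly that value, making recipes
    with different K directly comparable.
    """
    freq_table = [8.0, 13.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0]
    lat_table = [15.0, 25.0, 35.0, 45.0, 55.0, 70.0, 85.0, 100.0]
    damp_table = [220.0] * 8
    amp_table = [40.0, 36.0, 32.0, 28.0, 24.0, 20.0, 18.0, 16.0]
    if n_components > len(freq_table):
        raise ValueError(f"at most {len(freq_table)} components supported")
    rng = np.random.default_rng(int(seed))
    comps = []
    for k in range(n_components):
        topo = _smooth_topography(rng, n_channels, unit_rms=False)
        comps.append(TepComponent(freq_table[k], damp_table[k], lat_table[k],
                                  amp_table[k], topo))
    if total_energy is not None and comps:
        n = int(round((epoch_window[1] - epoch_window[0]) * fs / 1000.0))
        t_ms = epoch_window[0] + np.arange(n) * 1000.0 / fs
        # channel-space energy, including topography cross-terms
        evoked = np.zeros((n_channels, n))
        for c in comps:
            topo = c.topography / np.linalg.norm(c.topography)
            evoked += np.outer(topo, _component_waveform(c, t_ms))
        energy = float(np.sum(evoked ** 2))
        if energy > 0:
            s = np.sqrt(total_energy / energy)
            comps = [TepComponent(c.frequency_hz, c.damping_ms, c.latency_ms,
                                  c.amplitude_uv * s, c.topography)
                     for c in comps]
    return TepSpec(components=comps, trial_noise_rms=trial_noise_rms,
                   n_trials=n_trials)


def wake_tep_spec(n_channels: int = 8, n_trials: int = 60,
                  seed: int = 0) -> TepSpec:
    """Default wakefulness evoked recipe: 8 distinct components."""
    return make_tep_spec(8, n_channels=n_channels, n_trials=n_trials,
                         trial_noise_rms=10.0, seed=seed)


def sedation_tep_spec(n_channels: int = 8, n_trials: int = 60,
                      seed: int = 0) -> TepSpec:
    """Default sedation evoked recipe: a single slow stereotyped wave."""
    spec = make_tep_spec(1, n_channels=n_channels, n_trials=n_trials,
                         trial_noise_rms=10.0, seed=seed)
    comp = spec.components[0]
    slow = TepComponent(frequency_hz=3.0, damping_ms=160.0,
                        latency_ms=20.0, amplitude_uv=30.0,
                        topography=comp.topography)
    return TepSpec(components=[slow], trial_noise_rms=spec.trial_noise_rms,
                   n_trials=spec.n_trials)


def gen_tep(spec: TepSpec, n_channels: int, fs: float,
            epoch_window: tuple[float, float] = (-250.0, 500.0),
            seed: int = 0) -> TepSet:
    """Synthetic TMS-evoked trial set.

    Every trial is independent pink noise plus one identical evoked
    waveform that is exactly zero before the stimulus pulse at t=0.
    """
    lo, hi = epoch_window
    if not (lo < 0 < hi):
        raise ValueError("epoch_window must span negative to positive times")
    for comp in spec.components:
        if not (0 <= comp.latency_ms < hi):
            raise ValueError(
                f"component latency {comp.latency_ms} ms outside the "
                f"response window [0, {hi}) ms")
    rng = np.random.default_rng(int(seed))
    n = int(round((hi - lo) * fs / 1000.0))
    onset = int(round(-lo * fs / 1000.0))
    t_ms = (np.arange(n) - onset) * 1000.0 / fs

    evoked = np.zeros((n_channels, n))
    for comp in spec.components:
        topo = comp.topography
        if topo is None:
            topo = _smooth_topography(rng, n_channels, unit_rms=False)
        topo = np.asarray(topo, dtype=float)
        if topo.shape != (n_channels,):
            raise ValueError("component topography does not match n_channels")
        norm = np.linalg.norm(topo)
        if norm == 0:
            raise ValueError("zero component topography")
        evoked += np.outer(topo / norm, _component_waveform(comp, t_ms))

    data = np.empty((spec.n_trials, n_channels, n))
    for trial in range(spec.n_trials):
        # pink trial noise, drift-free below 2 Hz as in cleaned epochs
        noise = spec.trial_noise_rms * _powerlaw_noise(
            rng, n, 1.0, n_channels, fs=fs, highpass_hz=2.0)
        data[trial] = noise + evoked
    return TepSet(data=data, fs=fs, onset_idx=onset)


# ---------------------------------------------------------------------------
# Awakening-report tables


@dataclass(frozen=True)
class ReportMarginals:
    """Study-level marginal counts of Q1, Q2 and experience classes."""

    q1_counts: dict[str, int]
    q2_counts: dict[str, int]
    class_totals: dict[str, int]
    n_awakenings: int

    def validate(self) -> None:
        for name, counts, keys in (
                ("q1_counts", self.q1_counts, Q1_CATEGORIES),
                ("q2_counts", self.q2_counts, Q2_CATEGORIES),
                ("class_totals", self.class_totals, EXPERIENCE_CLASSES)):
            unknown = set(counts) - set(keys)
            if unknown:
                raise ValueError(f"{name}: unknown categories {unknown}")
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"{name}: negative count")
            total = sum(counts.values())
            if total != self.n_awakenings:
                raise ValueError(
                    f"infeasible marginals: {name} sums to {total}, "
                    f"expected n_awakenings = {self.n_awakenings}")


def default_marginals() -> ReportMarginals:
    """The packaged study-level marginals (52 awakenings)."""
    return ReportMarginals(
        q1_counts={"nothing": 1, "no_info": 28, "white": 2,
                   "vague": 9, "vivid": 12},
        q2_counts={"no": 8, "no_info": 22, "maybe": 4, "yes": 18},
        class_totals={"experience": 24, "no_information": 23,
                      "no_experience": 5},
        n_awakenings=52,
    )


def default_awakening_counts() -> list[int]:
    """Awakenings per participant: 14 woken 3x, 4 woken 2x, 2 woken once."""
    return [3] * 14 + [2] * 4 + [1] * 2


def fixture_joint_table(marginals: ReportMarginals,
                        rule: ClassificationRule | None = None) -> np.ndarray:
    """A 5x4 Q1 x Q2 contingency table consistent with the marginals.

    Rows follow ``Q1_CATEGORIES``, columns ``Q2_CATEGORIES``.  Row sums
    equal the Q1 counts, column sums the Q2 counts, and the class totals
    under ``rule`` equal the stated class totals.  The table is found by
    backtracking over cells in row-major order, trying larger cell
    values first; the fixed search order makes the result deterministic.
    """
    marginals.validate()
    rule = rule if rule is not None else default_rule()
    n_rows, n_cols = len(Q1_CATEGORIES), len(Q2_CATEGORIES)
    row_tot = [marginals.q1_counts.get(q, 0) for q in Q1_CATEGORIES]
    col_tot = [marginals.q2_counts.get(q, 0) for q in Q2_CATEGORIES]
    cls_tot = {c: marginals.class_totals.get(c, 0) for c in EXPERIENCE_CLASSES}
    cell_class = [[rule.classify(Q1_CATEGORIES[i], Q2_CATEGORIES[j])
                   for j in range(n_cols)] for i in range(n_rows)]

    table = np.zeros((n_rows, n_cols), dtype=int)
    col_rem = list(col_tot)
    cls_rem = dict(cls_tot)
    # row capacity below row i, to prune columns that can no longer fill
    rows_below = [sum(row_tot[i + 1:]) for i in range(n_rows)]

    def solve(idx: int, row_rem: int) -> bool:
        if idx == n_rows * n_cols:
            return all(v == 0 for v in col_rem) and \
                all(v == 0 for v in cls_rem.values())
        i, j = divmod(idx, n_cols)
        if j == 0:
            row_rem = row_tot[i]
        cls = cell_class[i][j]
        if j == n_cols - 1:
            candidates = [row_rem]  # last column of a row is forced
        else:
            candidates = range(min(row_rem, col_rem[j], cls_rem[cls]), -1, -1)
        for v in candidates:
            if v > col_rem[j] or v > cls_rem[cls] or v > row_rem:
                continue
            # a column must stay fillable by this row's remainder plus
            # everything below it
            if j == n_cols - 1 and any(
                    (col_rem[jj] - v if jj == j else col_rem[jj])
                    > rows_below[i] for jj in range(n_cols)):
                continue
            table[i, j] = v
            col_rem[j] -= v
            cls_rem[cls] -= v
            if solve(idx + 1, row_rem - v):
                return True
            table[i, j] = 0
            col_rem[j] += v
            cls_rem[cls] += v
        return False

    if not solve(0, 0):
        raise ValueError(
            "no joint table is consistent with the given marginals and rule")
    return table


def gen_reports(marginals: ReportMarginals, participants: list[int],
                seed: int = 0,
                rule: ClassificationRule | None = None) -> list[AwakeningReport]:
    """One AwakeningReport per awakening, consistent with the marginals.

    A marginal-consistent joint Q1 x Q2 table is built with
    :func:`fixture_joint_table`; its (q1, q2) pairs are then assigned to
    the awakening slots by a single uniform random shuffle.
    ``participants`` lists the number of awakenings per participant.
    """
    marginals.validate()
    if any(c < 1 for c in participants):
        raise ValueError("every participant needs at least one awakening")
    total = sum(participants)
    if total != marginals.n_awakenings:
        raise ValueError(
            f"infeasible marginals: participant awakenings sum to {total}, "
            f"expected n_awakenings = {marginals.n_awakenings}")
    table = fixture_joint_table(marginals, rule)
    pairs = [(Q1_CATEGORIES[i], Q2_CATEGORIES[j])
             for i in range(table.shape[0]) for j in range(table.shape[1])
             for _ in range(table[i, j])]
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(pairs))
    reports = []
    slot = 0
    for p, count in enumerate(participants):
        pid = f"P{p + 1:02d}"
        for idx in range(1, count + 1):
            q1, q2 = pairs[order[slot]]
            reports.append(AwakeningReport(pid, idx, q1, q2))
            slot += 1
    return reports
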