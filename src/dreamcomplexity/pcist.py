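"""Perturbational Complexity Index, state-transition variant (PCIst).

PCIst quantifies the spatiotemporal complexity of a TMS-evoked EEG
response.  The trial-averaged evoked potential is decomposed into
principal components over the post-stimulus response window; for each
component time course the pointwise amplitude-distance matrix is
thresholded at a binarization level epsilon, chosen to maximize the
weighted excess of state transitions in the response over the
pre-stimulus baseline; the excess transition counts are summed over
components.  A response that is both strong and temporally diverse over
many spatial components scores high; a stereotyped or absent response
scores near zero.

Number-of-state-transitions (NST) operator: with distance matrix
``D(i, j) = |y(i) - y(j)|`` over a segment and ``T = D > eps``, the NST
is the mean over reference columns t' of the number of sign changes of
``T(., t')`` along consecutive rows.  NST is converted to a per-sample
transition rate so baseline and response windows of unequal length are
comparable; the per-component contribution is the response-length-scaled
rate difference, clipped at zero.

Every stage is scale-equivariant or quantile-based, so PCIst is
invariant under global amplitude scaling of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .containers import TepSet

__all__ = [
    "PcistParams", "PcistResult", "ComponentResult",
    "trial_average", "pca_components", "distance_matrix", "nst",
    "optimize_epsilon", "pcist", "gmfp", "itpc",
]


@dataclass(frozen=True)
class PcistParams:
    """Tunable parameters of the PCIst computation.

    Defaults: response window (0, 300) ms and baseline (-250, -5) ms
    inside the standard -250..+500 ms epoch; components retained up to
    99% response variance, at most 10, and only if their
    response/baseline RMS ratio is at least ``min_component_snr``
    (default 1.6, chosen so that stimulus-free noise yields values near
    zero: response-energy PCA inflates the apparent SNR of pure-noise
    components to about 1.1-1.4); the epsilon threshold is searched
    over ``epsilon_grid_size`` pooled distance quantiles with baseline
    transitions weighted by ``k_weight`` in the objective.
    """

    baseline_window: tuple[float, float] = (-250.0, -5.0)
    response_window: tuple[float, float] = (0.0, 300.0)
    variance_retained: float = 0.99
    max_components: int = 10
    k_weight: float = 1.2
    epsilon_grid_size: int = 100
    min_component_snr: float = 1.6

    def __post_init__(self) -> None:
        if not (self.baseline_window[0] < self.baseline_window[1] <= 0):
            raise ValueError("baseline window must lie before the stimulus")
        if not (0 <= self.response_window[0] < self.response_window[1]):
            raise ValueError("response window must lie after the stimulus")
        if not (0 < self.variance_retained <= 1):
            raise ValueError("variance_retained must be in (0, 1]")
        if self.k_weight < 1:
            raise ValueError("k_weight must be >= 1")
        if self.epsilon_grid_size < 2:
            raise ValueError("epsilon_grid_size must be >= 2")


@dataclass
class ComponentResult:
    """Per-component bookkeeping of the PCIst sum."""

    delta_nst: float
    epsilon: float
    nst_base: float
    nst_resp: float


@dataclass
class PcistResult:
    value: float
    per_component: list[ComponentResult] = field(default_factory=list)
    n_components_retained: int = 0


def trial_average(t: TepSet,
                  baseline_window: tuple[float, float] = (-250.0, -5.0)
                  ) -> np.ndarray:
    """Baseline-corrected, average-referenced trial mean (channels x time)."""
    if t.n_trials < 1:
        raise ValueError("need at least one trial")
    evoked = t.data.mean(axis=0)
    base = t.window_slice(baseline_window)
    evoked = evoked - evoked[:, base].mean(axis=1, keepdims=True)
    evoked = evoked - evoked.mean(axis=0, keepdims=True)  # average reference
    return evoked


def pca_components(evoked: np.ndarray, t: TepSet,
                   p: PcistParams) -> np.ndarray:
    """Principal-component time courses of the evoked response.

    The SVD is taken over the response-window matrix; left singular
    vectors project the full epoch onto component time courses carrying
    the component amplitudes.  The smallest set of components reaching
    ``variance_retained`` of response energy is kept (capped at
    ``max_components``), and components whose response/baseline RMS
    ratio falls below ``min_component_snr`` are dropped.

    Returns an array (n_components, n_samples); may be empty.
    """
    resp = t.window_slice(p.response_window)
    base = t.window_slice(p.baseline_window)
    r = evoked[:, resp]
    u, s, _ = np.linalg.svd(r, full_matrices=False)
    energy = s ** 2
    total = energy.sum()
    if total == 0:
        return np.empty((0, evoked.shape[1]))
    frac = np.cumsum(energy) / total
    n_keep = int(np.searchsorted(frac, p.variance_retained - 1e-12) + 1)
    n_keep = min(n_keep, p.max_components, len(s))
    courses = u[:, :n_keep].T @ evoked  # (n_keep, n_samples)
    keep = []
    for row in courses:
        rms_resp = np.sqrt(np.mean(row[resp] ** 2))
        rms_base = np.sqrt(np.mean(row[base] ** 2))
        snr = np.inf if rms_base == 0 else rms_resp / rms_base
        if snr >= p.min_component_snr:
            keep.append(row)
    if not keep:
        return np.empty((0, evoked.shape[1]))
    return np.array(keep)


def distance_matrix(y) -> np.ndarray:
    """Pointwise amplitude distances ``D(i, j) = |y(i) - y(j)|``."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("expected a 1-D segment of length >= 2")
    return np.abs(y[:, None] - y[None, :])


def nst(y, eps: float) -> float:
    """Mean number of state transitions of a segment at threshold ``eps``.

    ``T = D > eps``; transitions are counted along consecutive rows for
    each reference column and averaged over columns.
    """
    if eps < 0:
        raise ValueError("threshold must be non-negative")
    d = distance_matrix(y)
    t = d > eps
    return float(np.abs(np.diff(t.astype(np.int8), axis=0)).sum(axis=0).mean())


def _nst_curve(y: np.ndarray, eps_grid: np.ndarray) -> np.ndarray:
    """NST at every threshold in ``eps_grid``, vectorized.

    For each consecutive row pair and column of the distance matrix a
    transition exists at threshold eps iff min(d1, d2) <= eps < max(d1, d2),
    so the count at eps is #{min <= eps} - #{max <= eps}.
    """
    d = distance_matrix(y)
    lo = np.minimum(d[:-1, :], d[1:, :]).ravel()
    hi = np.maximum(d[:-1, :], d[1:, :]).ravel()
    lo.sort()
    hi.sort()
    counts = (np.searchsorted(lo, eps_grid, side="right")
              - np.searchsorted(hi, eps_grid, side="right"))
    return counts / d.shape[0]


def optimize_epsilon(y_base, y_resp, p: PcistParams) -> tuple[float, float]:
    """Threshold maximizing the weighted response-baseline NST difference.

    Candidate thresholds are ``epsilon_grid_size`` evenly spaced
    quantiles of the pooled off-diagonal distance values of both
    segments.  The objective is the per-sample rate difference
    ``NST_resp/L_resp - k_weight * NST_base/L_base``; ties are broken
    toward the smaller threshold.
    """
    y_base = np.asarray(y_base, dtype=float)
    y_resp = np.asarray(y_resp, dtype=float)
    if y_base.size < 2 or y_resp.size < 2:
        raise ValueError("both segments must have length >= 2")

    def offdiag(y):
        d = distance_matrix(y)
        return d[np.triu_indices_from(d, k=1)]

    pooled = np.concatenate([offdiag(y_base), offdiag(y_resp)])
    probs = np.linspace(0.0, 1.0, p.epsilon_grid_size)
    grid = np.quantile(pooled, probs)
    obj = (_nst_curve(y_resp, grid) / y_resp.size
           - p.k_weight * _nst_curve(y_base, grid) / y_base.size)
    best = int(np.argmax(obj))  # argmax takes the first (smallest) maximizer
    return float(grid[best]), float(obj[best])


def pcist(t: TepSet, p: PcistParams | None = None) -> PcistResult:
    """PCIst of a TMS-evoked trial set.

    Pipeline: trial average -> response-window PCA -> per component:
    optimize epsilon, then the response-length-scaled transition-rate
    excess (clipped at zero); the value is the sum over components.
    """
    p = p if p is not None else PcistParams()
    evoked = trial_average(t, p.baseline_window)
    courses = pca_components(evoked, t, p)
    resp = t.window_slice(p.response_window)
    base = t.window_slice(p.baseline_window)
    per_component = []
    total = 0.0
    for row in courses:
        y_base, y_resp = row[base], row[resp]
        eps, _ = optimize_epsilon(y_base, y_resp, p)
        nst_b = nst(y_base, eps)
        nst_r = nst(y_resp, eps)
        delta = y_resp.size * (nst_r / y_resp.size - nst_b / y_base.size)
        delta = max(delta, 0.0)
        per_component.append(ComponentResult(delta, eps, nst_b, nst_r))
        total += delta
    return PcistResult(value=total, per_component=per_component,
                       n_components_retained=len(per_component))


def gmfp(evoked: np.ndarray) -> np.ndarray:
    """Global mean field power: across-channel SD at each time point.

    Population convention (ddof=0): for two channels at +a and -a the
    GMFP is |a|.
    """
    evoked = np.asarray(evoked, dtype=float)
    if evoked.ndim != 2 or evoked.shape[0] < 2:
        raise ValueError("expected a (channels >= 2, time) matrix")
    return evoked.std(axis=0, ddof=0)


def itpc(t: TepSet, band: tuple[float, float] = (8.0, 12.0)) -> np.ndarray:
    """Inter-trial phase coherence per channel and time point, in [0, 1].

    Each trial is band-filtered (4th-order zero-phase Butterworth), the
    analytic phase extracted, and the modulus of the trial-mean unit
    phase vector returned.
    """
    if t.n_trials < 2:
        raise ValueError("need at least two trials")
    lo, hi = band
    nyq = t.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band!r} not realizable at fs={t.fs}")
    b, a = butter(4, [lo / nyq, hi / nyq], btype="bandpass")
    filtered = filtfilt(b, a, t.data, axis=2)
    phases = np.angle(hilbert(filtered, axis=2))
    return np.abs(np.exp(1j * phases).mean(axis=0))
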