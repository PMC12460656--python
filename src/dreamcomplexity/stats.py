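"""Statistical layer: random-intercept LMM, Wilcoxon, Holm, IQR screening.

The study-level battery consists of

* linear mixed models ``value ~ experience_class + (1 | participant)``
  fitted by REML, reporting the Type-III F for the class effect and
  estimated marginal means (EMMs),
* matched-pairs Wilcoxon signed-rank tests (normal approximation with
  midrank tie correction and no continuity correction) for the four
  wakefulness/sedation state contrasts,
* Holm-Bonferroni step-down correction across the six tests,
* 1.5-IQR outlier screening of each measure distribution.

Denominator degrees of freedom for the F test default to the
Satterthwaite approximation, computed from the closed-form REML
likelihood of the single-random-intercept model; "between_within" and
"residual" approximations are also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LmmSpec", "LmmResult", "PairedTestResult", "HolmDecision", "StatReport",
    "fit_lmm", "emm", "wilcoxon_z", "holm", "iqr_outliers", "run_full_battery",
]


# ---------------------------------------------------------------------------
# Linear mixed model


@dataclass(frozen=True)
class LmmSpec:
    """Model specification for the class-effect mixed model."""

    dependent: str = "value"
    fixed_effect: str = "experience_class"
    random_intercept: str | None = "participant_id"
    reference: str = "no_experience"
    df_method: str = "satterthwaite"  # or "between_within", "residual"


@dataclass
class LmmResult:
    F: float
    ndf: int
    ddf: float
    p: float
    emms: pd.DataFrame            # columns: level, emm, se
    variance_components: tuple[float, float]  # (sigma2_u, sigma2_e)
    coefficients: pd.DataFrame    # columns: term, estimate, se
    levels: list[str]
    singular: bool
    n_obs: int
    n_groups: int


def _design(df: pd.DataFrame, spec: LmmSpec):
    y = df[spec.dependent].to_numpy(dtype=float)
    classes = df[spec.fixed_effect].astype(str).to_numpy()
    levels = sorted(set(classes))
    if spec.reference in levels:
        levels = [spec.reference] + [l for l in levels if l != spec.reference]
    X = np.column_stack(
        [np.ones(len(df))] + [(classes == l).astype(float)
                              for l in levels[1:]])
    terms = ["intercept"] + [f"{spec.fixed_effect}[{l}]" for l in levels[1:]]
    return y, X, levels, terms, classes


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    order = {}
    for i, g in enumerate(groups):
        order.setdefault(g, []).append(i)
    return [np.array(v) for v in order.values()]


def _gls_pieces(theta, X, y, group_idx):
    """Accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V| groupwise.

    V_j = sigma2_e I + sigma2_u 11' has the closed-form inverse
    (1/sigma2_e)(I - c 11') with c = sigma2_u / (sigma2_e + n_j sigma2_u).
    """
    su2, se2 = theta
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx in group_idx:
        Xj, yj = X[idx], y[idx]
        nj = len(idx)
        c = su2 / (se2 + nj * su2)
        sx = Xj.sum(axis=0)
        sy = yj.sum()
        xtvx += (Xj.T @ Xj - c * np.outer(sx, sx)) / se2
        xtvy += (Xj.T @ yj - c * sx * sy) / se2
        ytvy += (yj @ yj - c * sy * sy) / se2
        logdet += (nj - 1) * np.log(se2) + np.log(se2 + nj * su2)
    return xtvx, xtvy, ytvy, logdet


def _reml_loglik(theta, X, y, group_idx) -> float:
    xtvx, xtvy, ytvy, logdet = _gls_pieces(theta, X, y, group_idx)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - xtvy @ beta
    return -0.5 * (logdet + logdet_xtvx + ypy)


def _beta_cov(theta, X, group_idx) -> np.ndarray:
    su2, se2 = theta
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    for idx in group_idx:
        Xj = X[idx]
        nj = len(idx)
        c = su2 / (se2 + nj * su2)
        sx = Xj.sum(axis=0)
        xtvx += (Xj.T @ Xj - c * np.outer(sx, sx)) / se2
    return np.linalg.inv(xtvx)


def _satterthwaite_ddf(L, theta, X, y, group_idx) -> float:
    """Satterthwaite denominator df for the F test of L beta = 0.

    Follows the multi-contrast recipe of averaging per-eigencontrast
    Satterthwaite dfs: the variance of each scalar contrast variance is
    taken from the delta method with the REML-information covariance of
    the variance components.
    """
    theta = np.asarray(theta, dtype=float)
    q = L.shape[0]

    # numeric Hessian of the REML loglik wrt (sigma2_u, sigma2_e)
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))
    # keep evaluation points inside the parameter space
    lo_ok = theta - h > 0
    H = np.zeros((2, 2))
    f0 = _reml_loglik(theta, X, y, group_idx)

    def ll(t):
        return _reml_loglik(np.maximum(t, 1e-12), X, y, group_idx)

    for a in range(2):
        ea = np.zeros(2); ea[a] = h[a]
        if lo_ok[a]:
            H[a, a] = (ll(theta + ea) - 2 * f0 + ll(theta - ea)) / h[a] ** 2
        else:
            H[a, a] = (ll(theta + 2 * ea) - 2 * ll(theta + ea) + f0) / h[a] ** 2
    ea = np.array([h[0], 0.0]); eb = np.array([0.0, h[1]])
    if lo_ok.all():
        H[0, 1] = H[1, 0] = (
            ll(theta + ea + eb) - ll(theta + ea - eb)
            - ll(theta - ea + eb) + ll(theta - ea - eb)) / (4 * h[0] * h[1])
    else:
        H[0, 1] = H[1, 0] = (
            ll(theta + ea + eb) - ll(theta + ea) - ll(theta + eb) + f0
        ) / (h[0] * h[1])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float("nan")
    if not np.all(np.isfinite(A)):
        return float("nan")

    phi = _beta_cov(theta, X, group_idx)
    M = L @ phi @ L.T
    d, P = np.linalg.eigh(M)
    nu = []
    for i in range(q):
        li = P[:, i] @ L  # 1 x p contrast

        def cvar(t):
            return float(li @ _beta_cov(np.maximum(t, 1e-12), X, group_idx) @ li)

        g = np.zeros(2)
        for a in range(2):
            ea = np.zeros(2); ea[a] = h[a]
            if lo_ok[a]:
                g[a] = (cvar(theta + ea) - cvar(theta - ea)) / (2 * h[a])
            else:
                g[a] = (cvar(theta + ea) - cvar(theta)) / h[a]
        denom = float(g @ A @ g)
        if denom <= 0:
            continue
        nu_i = 2.0 * d[i] ** 2 / denom
        if nu_i > 2.0:
            nu.append(nu_i)
    if not nu:
        return float("nan")
    E = sum(v / (v - 2.0) for v in nu)
    if E <= q:
        return float("inf")
    return 2.0 * E / (E - q)


def fit_lmm(table: pd.DataFrame, spec: LmmSpec | None = None) -> LmmResult:
    """REML fit of ``value ~ class + (1 | participant)`` with Type-III F.

    With ``spec.random_intercept = None`` the random term is omitted and
    the model reduces to ordinary least squares with residual df, in
    which case the F statistic equals the one-way fixed-effects ANOVA F.
    """
    spec = spec if spec is not None else LmmSpec()
    df = table.dropna(subset=[spec.dependent, spec.fixed_effect])
    y, X, levels, terms, _ = _design(df, spec)
    n, p = X.shape
    q = p - 1  # q = 0 with a single observed level: intercept-only fit
    L = np.zeros((q, p))
    L[:, 1:] = np.eye(q)

    if spec.random_intercept is None:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ddf = n - rank
        sigma2_e = float(resid @ resid / ddf)
        phi = sigma2_e * np.linalg.inv(X.T @ X)
        theta = (0.0, sigma2_e)
        n_groups = 0
        singular = True
    else:
        groups = df[spec.random_intercept].astype(str).to_numpy()
        group_idx = _group_indices(groups)
        n_groups = len(group_idx)
        if n_groups < 2:
            raise ValueError("need >= 2 participants for a random intercept")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=groups)
            fit = model.fit(reml=True)
        sigma2_u = float(np.asarray(fit.cov_re)[0, 0])
        sigma2_e = float(fit.scale)
        singular = sigma2_u < 1e-10 * max(sigma2_e, 1e-300)
        # floor the residual variance so degenerate (saturated) fits
        # cannot divide by zero in the GLS algebra
        theta = (max(sigma2_u, 0.0), max(sigma2_e, 1e-30))
        phi = _beta_cov(theta, X, group_idx)
        if q == 0:
            ddf = n - n_groups
        elif spec.df_method == "satterthwaite" and not singular:
            ddf = _satterthwaite_ddf(L, theta, X, y, group_idx)
            if not np.isfinite(ddf):
                ddf = n - n_groups - q
        elif spec.df_method == "between_within" or singular:
            ddf = n - n_groups - q
        elif spec.df_method == "residual":
            ddf = n - p
        else:
            raise ValueError(f"unknown df_method {spec.df_method!r}")
        ddf = max(float(ddf), 1.0)
        beta = phi @ sum_xtvy(theta, X, y, group_idx)

    if q > 0:
        lb = L @ beta
        M = L @ phi @ L.T
        F = float(lb @ np.linalg.solve(M, lb) / q)
        pval = float(sps.f.sf(F, q, ddf))
    else:
        F = float("nan")
        pval = float("nan")

    emm_rows = []
    for i, level in enumerate(levels):
        c = np.zeros(p)
        c[0] = 1.0
        if i > 0:
            c[i] = 1.0
        emm_rows.append((level, float(c @ beta), float(np.sqrt(c @ phi @ c))))
    coef = pd.DataFrame({"term": terms, "estimate": beta,
                         "se": np.sqrt(np.diag(phi))})
    return LmmResult(F=F, ndf=q, ddf=float(ddf), p=pval,
                     emms=pd.DataFrame(emm_rows,
                                       columns=["level", "emm", "se"]),
                     variance_components=(theta[0], theta[1]),
                     coefficients=coef, levels=levels, singular=singular,
                     n_obs=n, n_groups=n_groups)


def sum_xtvy(theta, X, y, group_idx) -> np.ndarray:
    _, xtvy, _, _ = _gls_pieces(theta, X, y, group_idx)
    return xtvy


def emm(result: LmmResult) -> pd.DataFrame:
    """Estimated marginal means: per-class predictions at u = 0."""
    return result.emms.copy()


# ---------------------------------------------------------------------------
# Wilcoxon signed rank (normal approximation)


@dataclass
class PairedTestResult:
    Z: float
    p: float
    n_pairs: int
    t_plus: float


def wilcoxon_z(x, y) -> PairedTestResult:
    """Matched-pairs Wilcoxon signed-rank test, normal approximation.

    Differences ``d = y - x``; zero differences are dropped; midranks
    for ties; the tie-corrected normal approximation is used with no
    continuity correction, so fully concordant samples reproduce the
    closed-form Z (e.g. n=20, all d < 0: Z = -3.92).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if x.size < 5:
        raise ValueError("need >= 5 pairs for the normal approximation")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (t_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return PairedTestResult(Z=float(z), p=float(p), n_pairs=n, t_plus=t_plus)


# ---------------------------------------------------------------------------
# Holm-Bonferroni and outlier screening


@dataclass
class HolmDecision:
    name: str
    p: float
    threshold: float
    reject: bool


def holm(pvals: list[tuple[str, float]], alpha: float = 0.05
         ) -> list[HolmDecision]:
    """Holm-Bonferroni step-down decisions, in the input order.

    The i-th smallest p-value is compared with alpha / (m - i + 1); the
    step-down stops at the first failure.
    """
    m = len(pvals)
    for name, p in pvals:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value for {name!r} outside [0, 1]")
    order = sorted(range(m), key=lambda i: pvals[i][1])
    decisions: list[HolmDecision | None] = [None] * m
    failed = False
    for rank, idx in enumerate(order):
        name, p = pvals[idx]
        threshold = alpha / (m - rank)
        reject = (not failed) and p <= threshold
        if not reject:
            failed = True
        decisions[idx] = HolmDecision(name, p, threshold, reject)
    return decisions  # type: ignore[return-value]


def iqr_outliers(values) -> np.ndarray:
    """Boolean flags for values beyond 1.5 IQR outside [Q1, Q3].

    Quartiles use linear interpolation between order statistics
    (numpy's default), which is pinned because flags can differ across
    quantile conventions.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values for quartile screening")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return (v > q3 + 1.5 * iqr) | (v < q1 - 1.5 * iqr)


# ---------------------------------------------------------------------------
# The full study battery


#: Wilcoxon contrasts: name -> (measure, state-1 condition, state-2 tag)
_WILCOXON_TESTS = [
    ("pcist_w_vs_sed", "pcist", "wake_ec", "sed_mean"),
    ("lzc_wo_vs_wc", "lzc", "wake_eo", "wake_ec"),
    ("lzc_wo_vs_sed", "lzc", "wake_eo", "sed_mean"),
    ("lzc_wc_vs_sed", "lzc", "wake_ec", "sed_mean"),
]

#: Outlier-screened distributions: name -> (measure, condition selector)
_OUTLIER_SETS = [
    ("pcist_wake", "pcist", "wake"),
    ("pcist_sedation", "pcist", "sedation"),
    ("lzc_wake_eo", "lzc", "wake_eo"),
    ("lzc_wake_ec", "lzc", "wake_ec"),
    ("lzc_sedation", "lzc", "sedation"),
]


@dataclass
class StatReport:
    """Results of the full statistical battery over a measure table."""

    wilcoxon: dict[str, PairedTestResult]
    lmm: dict[str, LmmResult]
    holm_decisions: list[HolmDecision]
    outliers: dict[str, pd.DataFrame]
    skipped: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        holm_by_name = {d.name: d for d in self.holm_decisions}
        rows = []
        for name, res in self.wilcoxon.items():
            d = holm_by_name.get(name)
            rows.append((name, "wilcoxon", res.Z, res.p, res.n_pairs,
                         d.threshold if d else np.nan,
                         bool(d.reject) if d else False))
        for name, res in self.lmm.items():
            d = holm_by_name.get(name)
            rows.append((name, "lmm_type3_F", res.F, res.p, res.n_obs,
                         d.threshold if d else np.nan,
                         bool(d.reject) if d else False))
        for name, reason in self.skipped.items():
            rows.append((name, "skipped", np.nan, np.nan, 0, np.nan, False))
        return pd.DataFrame(rows, columns=[
            "test", "kind", "statistic", "p", "n", "holm_threshold", "reject"])

    def to_dict(self) -> dict:
        return {
            "tests": self.to_frame().to_dict(orient="records"),
            "emms": {name: res.emms.to_dict(orient="records")
                     for name, res in self.lmm.items()},
            "variance_components": {
                name: {"sigma2_u": res.variance_components[0],
                       "sigma2_e": res.variance_components[1]}
                for name, res in self.lmm.items()},
            "outliers": {name: df.to_dict(orient="records")
                         for name, df in self.outliers.items()},
            "skipped": self.skipped,
            "warnings": self.warnings,
        }


def _condition_values(table: pd.DataFrame, measure: str, tag: str
                      ) -> pd.Series:
    """Per-participant values for a condition tag.

    ``sed_mean`` averages all sedation_* rows per participant; other
    tags select the single matching condition row.
    """
    sub = table[table["measure"] == measure]
    if tag == "sed_mean":
        sub = sub[sub["condition"].str.startswith("sedation")]
    elif tag == "sedation":
        sub = sub[sub["condition"].str.startswith("sedation")]
    else:
        sub = sub[sub["condition"] == tag]
    return sub.groupby("participant_id")["value"].mean()


def run_full_battery(table: pd.DataFrame, alpha: float = 0.05,
                    lmm_spec: LmmSpec | None = None) -> StatReport:
    """Run the full six-test battery over a tidy measure table.

    ``table`` columns: participant_id, condition (wake_eo, wake_ec,
    sedation_1..3), measure (lzc, pcist), value, experience_class
    (blank for wake rows).  Wilcoxon contrasts compare wake values with
    the per-participant mean of up to three sedation recordings;
    mixed models regress the sedation values on the experience class.
    Participants missing either member of a pair are dropped from that
    pair.  Holm correction is applied across all tests that ran.
    """
    required = {"participant_id", "condition", "measure", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"measure table must have columns {sorted(required)}")
    keys = ["participant_id", "condition", "measure"]
    warn0: list[str] = []
    if table.duplicated(subset=keys).any():
        n_dup = int(table.duplicated(subset=keys).sum())
        warn0.append(f"dropped {n_dup} duplicate measure row(s)")
        table = table.drop_duplicates(subset=keys, keep="first")
    wilcoxon_results: dict[str, PairedTestResult] = {}
    lmm_results: dict[str, LmmResult] = {}
    skipped: dict[str, str] = {}
    warn: list[str] = warn0

    for name, measure, tag1, tag2 in _WILCOXON_TESTS:
        s1 = _condition_values(table, measure, tag1)
        s2 = _condition_values(table, measure, tag2)
        common = s1.index.intersection(s2.index)
        dropped = len(s1.index.union(s2.index)) - len(common)
        if dropped:
            warn.append(f"{name}: dropped {dropped} incomplete pair(s)")
        try:
            wilcoxon_results[name] = wilcoxon_z(s1.loc[common].to_numpy(),
                                                s2.loc[common].to_numpy())
        except ValueError as exc:
            skipped[name] = str(exc)

    sed = table[table["condition"].str.startswith("sedation")]
    if "experience_class" in sed.columns:
        sed = sed.dropna(subset=["experience_class"])
    for measure in ("pcist", "lzc"):
        name = f"lmm_class_{measure}"
        sub = sed[sed["measure"] == measure]
        if sub.empty:
            skipped[name] = "no sedation rows with experience classes"
            continue
        try:
            lmm_results[name] = fit_lmm(sub, lmm_spec)
        except (ValueError, np.linalg.LinAlgError) as exc:
            skipped[name] = str(exc)

    pvals = ([(k, v.p) for k, v in wilcoxon_results.items()]
             + [(k, v.p) for k, v in lmm_results.items()])
    decisions = holm(pvals, alpha=alpha) if pvals else []

    outliers: dict[str, pd.DataFrame] = {}
    for name, measure, tag in _OUTLIER_SETS:
        sub = table[table["measure"] == measure]
        if tag == "sedation":
            sub = sub[sub["condition"].str.startswith("sedation")]
        elif tag == "wake":
            sub = sub[sub["condition"].str.startswith("wake")]
        else:
            sub = sub[sub["condition"] == tag]
        if len(sub) < 4:
            continue
        flags = iqr_outliers(sub["value"].to_numpy())
        outliers[name] = sub.iloc[np.flatnonzero(flags)][
            ["participant_id", "condition", "value"]].reset_index(drop=True)

    return StatReport(wilcoxon=wilcoxon_results, lmm=lmm_results,
                      holm_decisions=decisions, outliers=outliers,
                      skipped=skipped, warnings=warn)
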