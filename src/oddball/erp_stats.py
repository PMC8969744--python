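"""ROI / time-window ERP statistics.

Trial-level analyses on region-of-interest (ROI) averaged voltage:

* mass-univariate two-way type-II ANOVA (factors STATE and STIMULUS) at
  every time point, with Benjamini-Hochberg FDR correction across time,
  run separately per factor;
* component mean amplitudes (window average over the ROI series) with a
  2x2 ANOVA, partial eta squared for the interaction, Welch pairwise
  t-tests per state (deviant vs. standard) with Cohen's d and FDR
  correction over the post hoc family;
* JZS (Cauchy-prior) two-sample Bayes factors for the same contrasts and
  a BIC-based Bayes-factor approximation for the interaction term.

Sign convention for all contrasts: deviant minus standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .containers import EpochSet

__all__ = [
    "ROIDefinition",
    "AnovaTrace",
    "ComponentResult",
    "fdr_bh",
    "roi_trial_series",
    "mass_univariate_anova",
    "component_amplitude",
    "component_tests",
    "bayes_t",
    "welch_t",
    "cohens_d",
]

#: component measurement windows, seconds relative to the fifth-sound onset
COMPONENT_WINDOWS = {
    "P1": (-0.532, -0.484),
    "MMN": (0.140, 0.192),
    "P3a": (0.280, 0.340),
    "P3b": (0.400, 0.800),
}


@dataclass(frozen=True)
class ROIDefinition:
    """Named sensor group with its component measurement window."""

    name: str
    sensors: np.ndarray
    window: tuple  # seconds relative to fifth-sound onset

    def __post_init__(self):
        object.__setattr__(self, "sensors", np.asarray(self.sensors, dtype=int))


def fdr_bh(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR over a family of p-values.

    Returns ``(reject_mask, p_adjusted)``.
    """
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), pvals.copy()
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def roi_trial_series(epochs: EpochSet, sensors):
    """Per-trial time series averaged over the ROI sensors.

    Returns ``(series, metadata)`` with ``series`` of shape
    (n_trials, n_times).
    """
    sensors = np.asarray(sensors, dtype=int)
    if sensors.size == 0:
        raise ValueError("ROI has no sensors")
    series = epochs.data[:, sensors, :].mean(axis=1)
    return series, epochs.metadata.copy()


def _design_codes(metadata: pd.DataFrame):
    """+-1 effect codes for STATE, STIMULUS and their product."""
    states = np.unique(metadata["state"].to_numpy())
    stims = np.unique(metadata["stimulus"].to_numpy())
    if len(states) != 2 or len(stims) != 2:
        raise ValueError("need exactly two states and two stimulus classes")
    a = np.where(metadata["state"].to_numpy() == states[1], 1.0, -1.0)
    b = np.where(metadata["stimulus"].to_numpy() == stims[1], 1.0, -1.0)
    for st in states:
        for sm in stims:
            n_cell = int(np.sum((metadata["state"] == st) & (metadata["stimulus"] == sm)))
            if n_cell < 2:
                raise ValueError(f"factor cell ({st}, {sm}) has fewer than 2 trials")
    return a, b, a * b


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits of each column of Y on X."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return np.sum(Y * Y, axis=0) - np.sum(proj * proj, axis=0)


def _type2_anova(Y: np.ndarray, metadata: pd.DataFrame):
    """Type-II two-way ANOVA for a 2x2 between-trials design.

    ``Y`` is (n_trials, n_targets); returns dicts of F and p arrays for
    the factors ``state``, ``stimulus`` and ``interaction``, plus the
    residual sum of squares and df of the full model (for effect sizes).

    Type-II sums of squares are obtained by model comparison: each main
    effect is tested against the model containing the other main effect,
    and the interaction against the two-main-effects model; this is exact
    for unbalanced 2x2 designs and reduces to the classical decomposition
    when the design is balanced.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    a, b, ab = _design_codes(metadata)
    one = np.ones(n)
    X_a = np.column_stack([one, a])
    X_b = np.column_stack([one, b])
    X_main = np.column_stack([one, a, b])
    X_full = np.column_stack([one, a, b, ab])

    rss_a = _rss(X_a, Y)
    rss_b = _rss(X_b, Y)
    rss_main = _rss(X_main, Y)
    rss_full = _rss(X_full, Y)

    df_resid = n - 4
    mse = rss_full / df_resid
    ss = {
        "state": rss_b - rss_main,
        "stimulus": rss_a - rss_main,
        "interaction": rss_main - rss_full,
    }
    F, p = {}, {}
    for k, s in ss.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            F[k] = np.where(mse > 0, s / mse, np.inf)
        p[k] = stats.f.sf(F[k], 1, df_resid)
    return F, p, ss, rss_full, df_resid


@dataclass
class AnovaTrace:
    """Per-timepoint two-way ANOVA with FDR masks (correction per factor)."""

    times: np.ndarray
    F: dict
    p: dict
    p_adj: dict
    mask: dict
    alpha: float
    fdr_scope: str = "per_factor"


def mass_univariate_anova(series, metadata: pd.DataFrame, alpha: float = 0.05,
                          times=None) -> AnovaTrace:
    """Type-II two-way ANOVA at every time point of a trial x time array.

    FDR correction (Benjamini-Hochberg) is applied across time points,
    separately for each of the three terms.
    """
    Y = np.asarray(series, dtype=float)
    F, p, _, _, _ = _type2_anova(Y, metadata)
    p_adj, mask = {}, {}
    for k in p:
        mask[k], p_adj[k] = fdr_bh(p[k], alpha=alpha)
    if times is None:
        times = np.arange(Y.shape[1], dtype=float)
    return AnovaTrace(times=np.asarray(times), F=F, p=p, p_adj=p_adj, mask=mask,
                      alpha=alpha)


def component_amplitude(series, times, window) -> np.ndarray:
    """Per-trial mean voltage over the component window.

    The window is half-open in sample terms, [lo, hi): at 250 Hz the
    400-800 ms window covers exactly 100 samples.  This keeps window
    averages commensurate with evoked kernels spanning the same window.
    """
    times = np.asarray(times, dtype=float)
    lo, hi = window
    mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} outside the time axis")
    return np.asarray(series, dtype=float)[:, mask].mean(axis=1)


def welch_t(x, y):
    """Welch two-sample t statistic, df and two-sided p for x vs. y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def cohens_d(x, y) -> float:
    """Cohen's d with pooled standard deviation (x minus y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def bayes_t(x, y, r: float = np.sqrt(2) / 2.0) -> float:
    """JZS two-sample Bayes factor BF10 (Cauchy prior on effect size).

    Numerical integration of the Rouder et al. JZS marginal likelihood
    ratio with prior scale ``r``; the t statistic uses the pooled-variance
    two-sample formulation with effective sample size n1*n2/(n1+n2).
    BF01 is the reciprocal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return bayes_t_from_stats(t, n1, n2, r=r)


def bayes_t_from_stats(t: float, n1: int, n2: int, r: float = np.sqrt(2) / 2.0) -> float:
    """JZS BF10 from a pooled two-sample t statistic and group sizes."""
    df = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)

    def log_null():
        return -0.5 * (df + 1) * np.log1p(t * t / df)

    def integrand(g):
        # g ~ inverse-chi-square(1) prior scaled by r^2
        c = 1.0 + neff * g * r * r
        logf = (
            -0.5 * np.log(c)
            - 0.5 * (df + 1) * np.log1p(t * t / (c * df))
            - 1.5 * np.log(g)
            - 1.0 / (2.0 * g)
            - 0.5 * np.log(2.0 * np.pi)
        )
        return np.exp(logf - log_null())

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(val)


def bic_interaction_bf(amplitudes, metadata: pd.DataFrame) -> float:
    """BIC-approximated Bayes factor for the STATE x STIMULUS interaction.

    Compares the full linear model against the two-main-effects model via
    BF10 ~= exp((BIC_reduced - BIC_full) / 2).  A coarse stand-in for full
    Bayesian model averaging, adequate for order-of-magnitude evidence.
    """
    y = np.asarray(amplitudes, dtype=float)[:, None]
    n = len(y)
    a, b, ab = _design_codes(metadata)
    one = np.ones(n)
    X_main = np.column_stack([one, a, b])
    X_full = np.column_stack([one, a, b, ab])
    rss_main = float(_rss(X_main, y)[0])
    rss_full = float(_rss(X_full, y)[0])
    bic_main = n * np.log(rss_main / n) + 3 * np.log(n)
    bic_full = n * np.log(rss_full / n) + 4 * np.log(n)
    return float(np.exp((bic_main - bic_full) / 2.0))


@dataclass
class ComponentResult:
    """Cell means, interaction test and per-state post hoc contrasts."""

    name: str
    cell_means: dict  # (state, stimulus) -> uV
    interaction_F: float
    interaction_p: float
    partial_eta_sq: float
    posthoc: dict  # state -> {t, df, p, p_fdr, d, bf10, diff}
    bf10_interaction: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cell_means": {f"{k[0]}_{k[1]}": float(v) for k, v in self.cell_means.items()},
            "interaction_F": float(self.interaction_F),
            "interaction_p": float(self.interaction_p),
            "partial_eta_sq": float(self.partial_eta_sq),
            "bf10_interaction": float(self.bf10_interaction),
            "posthoc": {
                k: {kk: float(vv) for kk, vv in v.items()} for k, v in self.posthoc.items()
            },
        }


def component_tests(amplitudes, metadata: pd.DataFrame, name: str = "",
                    alpha: float = 0.05) -> ComponentResult:
    """Full component-level analysis of per-trial window amplitudes.

    The interaction is tested with the type-II 2x2 ANOVA (partial eta
    squared from its sum of squares); post hoc deviant-vs-standard Welch
    t-tests are run per state, FDR-corrected over the two-state family,
    with Cohen's d (pooled SD) and a JZS Bayes factor per contrast.
    """
    amp = np.asarray(amplitudes, dtype=float)
    F, p, ss, rss_full, _ = _type2_anova(amp[:, None], metadata)
    ss_int = float(ss["interaction"][0])
    eta_p2 = ss_int / (ss_int + float(rss_full[0])) if (ss_int + rss_full[0]) > 0 else 0.0

    states = sorted(np.unique(metadata["state"].to_numpy()))
    cell_means = {}
    posthoc = {}
    pvals = []
    for st in states:
        in_state = metadata["state"].to_numpy() == st
        dev = amp[in_state & (metadata["stimulus"].to_numpy() == "deviant")]
        std = amp[in_state & (metadata["stimulus"].to_numpy() == "standard")]
        cell_means[(st, "deviant")] = float(dev.mean())
        cell_means[(st, "standard")] = float(std.mean())
        t, df, pv = welch_t(dev, std)
        posthoc[st] = {
            "t": float(t),
            "df": float(df),
            "p": float(pv),
            "d": cohens_d(dev, std),
            "bf10": bayes_t(dev, std),
            "diff": float(dev.mean() - std.mean()),
        }
        pvals.append(pv)
    _, p_fdr = fdr_bh(np.asarray(pvals), alpha=alpha)
    for st, pf in zip(states, p_fdr):
        posthoc[st]["p_fdr"] = float(pf)

    return ComponentResult(
        name=name,
        cell_means=cell_means,
        interaction_F=float(F["interaction"][0]),
        interaction_p=float(p["interaction"][0]),
        partial_eta_sq=float(eta_p2),
        posthoc=posthoc,
        bf10_interaction=bic_interaction_bf(amp, metadata),
    )
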