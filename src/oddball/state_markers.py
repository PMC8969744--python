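"""Pseudo-resting-state markers: band power, wSMI connectivity, cluster tests.

Markers are computed per sensor and per epoch on the 800-ms window
preceding the fifth-sound onset (the "pseudo-resting state" spanned by
the first four sounds):

* normalized power spectral density in the delta (1-4), theta (4-8),
  alpha (8-12), beta (12-30) and gamma (30-45 Hz) bands, each expressed
  as a fraction of total 1-45 Hz power (the five fractions tile the
  total, so they sum to one);

* weighted symbolic mutual information (wSMI): signals are converted to
  sequences of rank-order symbols (k consecutive samples spaced tau
  apart; k=3 gives 6 possible patterns) and the mutual information of
  the joint symbol distribution of a sensor pair is computed with zero
  weight on identical and sign-opposite symbol pairs, suppressing
  common-source and volume-conduction artifacts; normalization by
  log(k!) bounds the value by 1.  Per-sensor topographies take the
  median connectivity of each sensor with all others.

* condition contrasts per sensor (Welch t), corrected topographically by
  a cluster-mass permutation test on the montage adjacency, plus a JZS
  Bayes-factor map.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import EpochSet
from .erp_stats import bayes_t, welch_t

__all__ = [
    "BANDS",
    "WSMI_TAU_SAMPLES",
    "MarkerTopography",
    "ClusterTestResult",
    "normalized_band_power",
    "symbolic_transform",
    "wsmi_weights",
    "wsmi",
    "cluster_permutation_contrast",
    "sensor_bayes_map",
]

#: canonical frequency bands, Hz (half-open intervals [lo, hi))
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: symbol spacing tau per band, in samples at 250 Hz; the span of a k=3
#: symbol (2*tau) then targets the band's characteristic period
#: (delta 64 ms, theta 32 ms, alpha 16 ms)
WSMI_TAU_SAMPLES = {"delta": 16, "theta": 8, "alpha": 4}

PSEUDO_REST_WINDOW = (-0.8, 0.0)


@dataclass
class MarkerTopography:
    """Per-epoch, per-sensor values of one marker."""

    name: str
    values: np.ndarray  # (n_epochs, n_sensors)
    condition: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"marker {self.name}: non-finite values")


def normalized_band_power(
    epochs: EpochSet,
    bands: dict = BANDS,
    window=PSEUDO_REST_WINDOW,
    total_band=(1.0, 45.0),
) -> dict:
    """Relative band power per epoch and sensor over the given window.

    The power spectral density is estimated with a single full-window
    Hann taper (Welch with one segment -- the 800-ms window is too short
    for multi-segment averaging at delta frequencies).  Each band's power
    is the sum of PSD bins with frequency in [lo, hi), divided by the
    total over [1, 45) Hz, so bands tiling the total sum to one exactly.
    Returns a dict band name -> MarkerTopography.
    """
    mask = epochs.time_mask((window[0], window[1] - 1e-9))
    seg = epochs.data[:, :, mask]
    n = seg.shape[-1]
    freqs, psd = signal.welch(
        seg, fs=epochs.sfreq, window="hann", nperseg=n, noverlap=0, axis=-1
    )
    lo_t, hi_t = total_band
    total_mask = (freqs >= lo_t) & (freqs < hi_t)
    total = psd[:, :, total_mask].sum(axis=-1)
    total[total == 0] = np.inf
    out = {}
    for name, (lo, hi) in bands.items():
        bmask = (freqs >= lo) & (freqs < hi)
        out[name] = MarkerTopography(
            name=f"psd_{name}", values=psd[:, :, bmask].sum(axis=-1) / total
        )
    return out


def _permutation_tables(k: int):
    """Lookup tables mapping rank codes to symbol ids and their opposites."""
    perms = list(itertools.permutations(range(k)))
    code_of = {}
    for sid, p in enumerate(perms):
        code = 0
        for i, r in enumerate(p):
            code = code * k + r
        code_of[code] = sid
    table = np.full(k ** k, -1, dtype=int)
    for code, sid in code_of.items():
        table[code] = sid
    # opposite pattern: ranks reversed (the symbol of the negated signal)
    opposite = np.zeros(len(perms), dtype=int)
    for sid, p in enumerate(perms):
        q = tuple((k - 1) - r for r in p)
        code = 0
        for r in q:
            code = code * k + r
        opposite[sid] = code_of[code]
    return table, opposite


def symbolic_transform(series, k: int = 3, tau: int = 1) -> np.ndarray:
    """Rank-order symbol sequence of a 1-D (or n-D along last axis) signal.

    Each symbol encodes the rank-order pattern of
    ``(x[t], x[t+tau], ..., x[t+(k-1)tau])``; there are k! possible
    symbols.  Ties are broken by temporal order (stable argsort).
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    m = n - (k - 1) * tau
    if m < 1:
        raise ValueError(f"series too short for k={k}, tau={tau}")
    windows = np.stack([x[..., i * tau : i * tau + m] for i in range(k)], axis=-1)
    order = np.argsort(windows, axis=-1, kind="stable")
    ranks = np.argsort(order, axis=-1, kind="stable")
    code = np.zeros(windows.shape[:-1], dtype=int)
    for i in range(k):
        code = code * k + ranks[..., i]
    table, _ = _permutation_tables(k)
    return table[code]


def wsmi_weights(k: int = 3) -> np.ndarray:
    """Symbol-pair weights: zero for identical and sign-opposite patterns."""
    n_sym = math.factorial(k)
    _, opposite = _permutation_tables(k)
    w = np.ones((n_sym, n_sym))
    np.fill_diagonal(w, 0.0)
    for s in range(n_sym):
        w[s, opposite[s]] = 0.0
        w[opposite[s], s] = 0.0
    return w


@dataclass
class WsmiResult:
    """Per-epoch wSMI matrices and the median-connectivity topography."""

    matrices: np.ndarray  # (n_epochs, n_sensors, n_sensors), symmetric
    topography: MarkerTopography  # median over the other sensors
    tau: int
    k: int


def wsmi(
    epochs: EpochSet,
    tau: int,
    k: int = 3,
    window=PSEUDO_REST_WINDOW,
) -> WsmiResult:
    """Weighted symbolic mutual information between all sensor pairs.

    For each epoch, each channel is symbolized over the analysis window
    and the joint symbol histogram of every pair (i, j) gives

        wSMI(i,j) = 1/log(k!) * sum_{s,s'} w(s,s') p(s,s')
                    * log[ p(s,s') / (p(s) p(s')) ]

    with the weight matrix from :func:`wsmi_weights`.  The per-sensor
    topography is the median of each sensor's connectivity to all other
    sensors, per epoch.
    """
    mask = epochs.time_mask((window[0], window[1] - 1e-9))
    seg = epochs.data[:, :, mask]
    n_ep, n_ch, _ = seg.shape
    n_sym = math.factorial(k)
    w = wsmi_weights(k)
    log_norm = np.log(n_sym)

    symbols = symbolic_transform(seg, k=k, tau=tau)  # (n_ep, n_ch, m)
    m = symbols.shape[-1]
    matrices = np.zeros((n_ep, n_ch, n_ch))
    eye = np.eye(n_sym)
    for e in range(n_ep):
        onehot = eye[symbols[e]]  # (n_ch, m, n_sym)
        flat = onehot.transpose(0, 2, 1).reshape(n_ch * n_sym, m)
        counts = flat @ flat.T  # (n_ch*n_sym, n_ch*n_sym)
        joint = counts.reshape(n_ch, n_sym, n_ch, n_sym).transpose(0, 2, 1, 3) / m
        p_ch = onehot.mean(axis=1)  # (n_ch, n_sym) marginal symbol probabilities
        denom = p_ch[:, None, :, None] * p_ch[None, :, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * (np.log(joint) - np.log(denom))
        term[joint == 0] = 0.0
        mat = (term * w[None, None, :, :]).sum(axis=(2, 3)) / log_norm
        mat = np.triu(mat, 1)
        matrices[e] = mat + mat.T

    n_other = n_ch - 1
    topo = np.zeros((n_ep, n_ch))
    for i in range(n_ch):
        others = np.delete(np.arange(n_ch), i)
        topo[:, i] = np.median(matrices[:, i, others], axis=1)
    return WsmiResult(
        matrices=matrices,
        topography=MarkerTopography(name=f"wsmi_tau{tau}", values=topo),
        tau=tau,
        k=k,
    )


@dataclass
class ClusterInfo:
    sensors: np.ndarray
    mass: float
    p: float
    sign: int

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


@dataclass
class ClusterTestResult:
    """Per-sensor t map plus adjacency-connected cluster statistics."""

    t_map: np.ndarray
    clusters: list
    n_permutations: int
    cluster_alpha: float

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)


def _welch_t_map(a: np.ndarray, b: np.ndarray):
    """Vectorized per-sensor Welch t and df for (n_a, n_ch) vs (n_b, n_ch)."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def _clusters_and_masses(t, thresh, adjacency):
    """Sign-separated suprathreshold clusters with their |t| masses."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) > thresh
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, labels = connected_components(csr_matrix(sub), directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            out.append((members, float(np.abs(t[members]).sum()), sign))
    return out


def cluster_permutation_contrast(
    topoA: np.ndarray,
    topoB: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 10000,
    cluster_alpha: float = 0.05,
    rng_seed: int = 0,
) -> ClusterTestResult:
    """Cluster-mass permutation test of a per-sensor condition contrast.

    Per-sensor Welch t-tests (condition A vs. B) are thresholded at the
    two-sided ``cluster_alpha`` t-quantile; suprathreshold sensors of
    equal sign are grouped into adjacency-connected clusters whose mass
    is the sum of |t|.  The null distribution of the maximal cluster
    mass is built from ``n_perm`` random condition-label shuffles, and
    each observed cluster's p-value is the (add-one smoothed) proportion
    of permutation maxima at or above its mass -- the familywise-error
    controlling max-statistic convention.
    """
    topoA = np.atleast_2d(np.asarray(topoA, dtype=float))
    topoB = np.atleast_2d(np.asarray(topoB, dtype=float))
    nA = topoA.shape[0]
    t_obs, df = _welch_t_map(topoA, topoB)
    thresh = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    observed = _clusters_and_masses(t_obs, thresh, adjacency)

    both = np.vstack([topoA, topoB])
    n_total = both.shape[0]
    rng = np.random.default_rng(rng_seed)
    max_mass = np.zeros(n_perm)
    for kperm in range(n_perm):
        order = rng.permutation(n_total)
        pa, pb = both[order[:nA]], both[order[nA:]]
        t_p, df_p = _welch_t_map(pa, pb)
        th_p = stats.t.ppf(1.0 - cluster_alpha / 2.0, df_p)
        cl = _clusters_and_masses(t_p, th_p, adjacency)
        max_mass[kperm] = max((mass for _, mass, _ in cl), default=0.0)

    clusters = [
        ClusterInfo(
            sensors=members,
            mass=mass,
            p=float((1 + np.sum(max_mass >= mass)) / (n_perm + 1)),
            sign=sign,
        )
        for members, mass, sign in observed
    ]
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(
        t_map=t_obs, clusters=clusters, n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
    )


def sensor_bayes_map(topoA: np.ndarray, topoB: np.ndarray) -> np.ndarray:
    """JZS two-sample BF10 per sensor for the A-vs-B contrast."""
    topoA = np.atleast_2d(np.asarray(topoA, dtype=float))
    topoB = np.atleast_2d(np.asarray(topoB, dtype=float))
    n_ch = topoA.shape[1]
    return np.array([bayes_t(topoA[:, s], topoB[:, s]) for s in range(n_ch)])
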