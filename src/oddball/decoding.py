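"""Timewise multivariate decoding of stimulus class, with permutation inference.

At every time point a linear support vector machine is trained on the
vector of channel amplitudes at that sample to separate deviant from
standard trials.  Features are standardized using training-trial
statistics; class weights are inversely proportional to class frequency
(deviants are the rarer class); a Platt sigmoid is fitted to the training
decision values to produce calibrated probabilities.  Performance is
summarized as the area under the ROC curve (AUC) over held-out trials.

Within-condition decoding uses stratified k-fold cross-validation
(7 folds for timewise decoding, 5 for temporal generalization);
cross-condition transfer trains on all trials of one condition and tests
on all trials of the other.  Significance against chance is assessed by
label-permutation: the whole decoding procedure is repeated with shuffled
trial labels, p(t) = #{perm AUC >= true AUC} / (n_perm + 1), floored at
1/(n_perm + 1), then FDR-corrected across time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import EpochSet
from .erp_stats import fdr_bh

__all__ = [
    "DecoderSpec",
    "TemporalDecodingResult",
    "GATResult",
    "decode_timewise",
    "permutation_null",
    "permutation_pvalues",
    "temporal_generalization",
]

POSITIVE = "deviant"
NEGATIVE = "standard"


@dataclass(frozen=True)
class DecoderSpec:
    """Linear max-margin decoder with Platt calibration."""

    cv_folds: int = 7
    C: float = 1.0
    rng_seed: int = 0
    decim: int = 1  # decode every decim-th sample

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _labels(epochs: EpochSet) -> np.ndarray:
    y = (epochs.metadata["stimulus"].to_numpy() == POSITIVE).astype(int)
    if y.min() == y.max():
        raise ValueError("a stimulus class is absent from the data")
    return y


def _platt_fit(scores: np.ndarray, y: np.ndarray):
    """Fit Platt's sigmoid P(y=1|s) = 1/(1+exp(A*s+B)) on training scores.

    Uses the regularized targets from Platt's method to avoid saturation.
    Returns (A, B).
    """
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * scores + b
        # log(1 + exp(z)) computed stably
        log1pexp = np.logaddexp(0.0, z)
        return np.sum(t * z + log1pexp - z)  # = -sum[t*log p + (1-t)*log(1-p)]

    def grad(params):
        a, b = params
        z = a * scores + b
        p = 1.0 / (1.0 + np.exp(-z))  # note: p here is 1/(1+exp(-z)) = 1 - sigmoid target
        d = t - (1.0 - p)
        return np.array([np.sum(d * scores), np.sum(d)])

    res = minimize(nll, x0=np.array([-1.0, 0.0]), jac=grad, method="BFGS")
    return float(res.x[0]), float(res.x[1])


def _platt_prob(scores: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(a * scores + b, -500, 500)))


class _TimepointDecoder:
    """Standardize -> linear SVM -> Platt sigmoid, for one time sample."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit_svm_only(self, X: np.ndarray, y: np.ndarray):
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        Xs = (X - self.mean_) / self.sd_
        self.svm_ = SVC(kernel="linear", C=self.C, class_weight="balanced")
        self.svm_.fit(Xs, y)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.fit_svm_only(X, y)
        train_scores = self.svm_.decision_function((X - self.mean_) / self.sd_)
        self.platt_ = _platt_fit(train_scores, y)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.svm_.decision_function((X - self.mean_) / self.sd_)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _platt_prob(self.decision_scores(X), *self.platt_)

    @property
    def weights(self):
        """(w, b) of the separating hyperplane in standardized space."""
        return self.svm_.coef_[0], float(self.svm_.intercept_[0])


@dataclass
class TemporalDecodingResult:
    """AUC over time, optionally with permutation p-values and FDR mask."""

    times: np.ndarray
    auc: np.ndarray
    train_condition: str
    test_condition: str
    p: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    mask: np.ndarray | None = None
    n_permutations: int = 0


def _decode_cv(data: np.ndarray, y: np.ndarray, spec: DecoderSpec,
               platt: bool = True) -> np.ndarray:
    """Stratified k-fold CV; pooled held-out probabilities -> AUC per time.

    With ``platt=False`` the (strictly monotone) sigmoid calibration is
    skipped and raw decision values are pooled instead; the resulting AUC
    is identical because AUC is rank-based, but each fit is cheaper --
    used inside permutation loops.
    """
    n_tr, n_ch, n_t = data.shape
    scores = np.zeros((n_tr, n_t))
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.rng_seed)
    for train_idx, test_idx in skf.split(np.zeros(n_tr), y):
        for ti in range(n_t):
            dec = _TimepointDecoder(C=spec.C)
            if platt:
                dec.fit(data[train_idx, :, ti], y[train_idx])
                scores[test_idx, ti] = dec.predict_proba(data[test_idx, :, ti])
            else:
                dec.fit_svm_only(data[train_idx, :, ti], y[train_idx])
                scores[test_idx, ti] = dec.decision_scores(data[test_idx, :, ti])
    return np.array([roc_auc_score(y, scores[:, ti]) for ti in range(n_t)])


def _decode_transfer(train_data, y_train, test_data, y_test, spec) -> np.ndarray:
    n_t = train_data.shape[2]
    auc = np.zeros(n_t)
    for ti in range(n_t):
        dec = _TimepointDecoder(C=spec.C).fit(train_data[:, :, ti], y_train)
        auc[ti] = roc_auc_score(y_test, dec.predict_proba(test_data[:, :, ti]))
    return auc


def decode_timewise(
    epochs_train: EpochSet,
    spec: DecoderSpec = DecoderSpec(),
    epochs_test: EpochSet | None = None,
) -> TemporalDecodingResult:
    """AUC(t) for deviant-vs-standard decoding.

    With ``epochs_test=None`` (within-condition), a stratified
    ``spec.cv_folds``-fold cross-validation is run and the AUC computed
    from the pooled held-out Platt probabilities.  With a distinct test
    set (cross-condition transfer), the decoder is trained on all
    training trials and evaluated on all test trials.
    """
    sl = slice(None, None, spec.decim)
    data = epochs_train.data[:, :, sl]
    times = epochs_train.times[sl]
    y = _labels(epochs_train)
    cond_tr = _condition_label(epochs_train)
    if epochs_test is None or epochs_test is epochs_train:
        auc = _decode_cv(data, y, spec)
        cond_te = cond_tr
    else:
        y_te = _labels(epochs_test)
        auc = _decode_transfer(data, y, epochs_test.data[:, :, sl], y_te, spec)
        cond_te = _condition_label(epochs_test)
    return TemporalDecodingResult(times=times, auc=auc,
                                  train_condition=cond_tr, test_condition=cond_te)


def _condition_label(epochs: EpochSet) -> str:
    states = pd.unique(epochs.metadata["state"]) if "state" in epochs.metadata else []
    states = [s for s in states if s is not None]
    return "+".join(str(s) for s in states) if len(states) else "?"


def permutation_pvalues(true_auc: np.ndarray, perm_auc: np.ndarray) -> np.ndarray:
    """p(t) = #{perm >= true} / (n_perm + 1), floored at 1/(n_perm + 1).

    ``perm_auc`` has shape (n_perm, n_times).  The floor replaces the
    unusable p = 0 outcome of the counting formula when the true AUC
    beats every permutation.
    """
    true_auc = np.asarray(true_auc, dtype=float)
    perm_auc = np.asarray(perm_auc, dtype=float)
    n_perm = perm_auc.shape[0]
    count = (perm_auc >= true_auc[None, :]).sum(axis=0)
    p = count / (n_perm + 1.0)
    return np.maximum(p, 1.0 / (n_perm + 1.0))


def permutation_null(
    epochs: EpochSet,
    spec: DecoderSpec = DecoderSpec(),
    n_perm: int = 500,
    alpha: float = 0.05,
    rng_seed: int | None = None,
) -> TemporalDecodingResult:
    """Within-condition decoding with a label-permutation null and FDR mask.

    Each permutation shuffles the trial labels (an independent seeded
    stream from the fold-assignment seed) and repeats the whole
    cross-validated decoding procedure.
    """
    sl = slice(None, None, spec.decim)
    data = epochs.data[:, :, sl]
    times = epochs.times[sl]
    y = _labels(epochs)
    true_auc = _decode_cv(data, y, spec)

    rng = np.random.default_rng(spec.rng_seed + 1 if rng_seed is None else rng_seed)
    perm_auc = np.zeros((n_perm, len(true_auc)))
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        perm_auc[k] = _decode_cv(data, y_perm, spec, platt=False)
    p = permutation_pvalues(true_auc, perm_auc)
    mask, p_adj = fdr_bh(p, alpha=alpha)
    cond = _condition_label(epochs)
    return TemporalDecodingResult(
        times=times, auc=true_auc, train_condition=cond, test_condition=cond,
        p=p, p_adj=p_adj, mask=mask, n_permutations=n_perm,
    )


@dataclass
class GATResult:
    """Temporal generalization (train-time x test-time) AUC matrix."""

    times: np.ndarray
    auc_matrix: np.ndarray  # (n_train_times, n_test_times)
    condition: str


def temporal_generalization(
    epochs: EpochSet,
    spec: DecoderSpec = DecoderSpec(cv_folds=5),
) -> GATResult:
    """Train at each time, test at every time, within stratified CV folds.

    The diagonal equals timewise decoding under the same fold assignment.
    """
    sl = slice(None, None, spec.decim)
    data = epochs.data[:, :, sl]
    times = epochs.times[sl]
    y = _labels(epochs)
    n_tr, n_ch, n_t = data.shape
    probs = np.zeros((n_tr, n_t, n_t))  # trial x train-time x test-time
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.rng_seed)
    for train_idx, test_idx in skf.split(np.zeros(n_tr), y):
        X_test = data[test_idx]  # (n_test, n_ch, n_t)
        for ti in range(n_t):
            dec = _TimepointDecoder(C=spec.C).fit(data[train_idx, :, ti], y[train_idx])
            w, b = dec.weights
            Xs = (X_test - dec.mean_[None, :, None]) / dec.sd_[None, :, None]
            scores = np.tensordot(Xs, w, axes=(1, 0)) + b  # (n_test, n_t)
            probs[test_idx, ti, :] = _platt_prob(scores, *dec.platt_)
    auc = np.zeros((n_t, n_t))
    for ti in range(n_t):
        for tj in range(n_t):
            auc[ti, tj] = roc_auc_score(y, probs[:, ti, tj])
    return GATResult(times=times, auc_matrix=auc, condition=_condition_label(epochs))
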