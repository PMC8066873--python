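"""Multivariate data-driven analysis: LOO-CV linear scoring, ROC, bootstrap.

A deliberately simple linear regressor (ordinary least squares of the
0/1 group label on the features, intercept included) is trained in a
leave-one-out scheme; each subject's out-of-fold prediction is a score,
larger for the patient class.  The ROC of those scores is summarized by
the AUC (normalized Mann-Whitney statistic, ties counted one half), its
significance against the null AUC of 0.5 via the Hanley-McNeil standard
error evaluated at the null, feature loadings averaged over folds, and
bootstrap z-scores of those loadings.  Sweeps re-run the whole chain as
a function of recording time or EEG channel count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st
from scipy.stats import rankdata

from .errors import DataError, NumericalError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledFeatures",
    "ROCResult",
    "ConfusionMatrix",
    "BootstrapLoadings",
    "SweepResult",
    "loocv_scores",
    "roc_analysis",
    "hanley_mcneil_se",
    "confusion_at_threshold",
    "youden_threshold",
    "bootstrap_loading_z",
    "auc_difference_independent",
    "sweep_recording_time",
    "sweep_channel_count",
]


@dataclass
class LabeledFeatures:
    """Feature matrix (subjects x features) with binary labels (patient = 1)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y).astype(int)
        if self.X.shape[0] != len(self.y):
            raise DataError(f"{self.X.shape[0]} feature rows but {len(self.y)} labels")
        if not np.isfinite(self.X).all():
            raise DataError("features contain NaN/inf")
        if set(np.unique(self.y)) - {0, 1}:
            raise DataError("labels must be 0/1")
        if len(np.unique(self.y)) < 2:
            raise DataError("both classes must be present")
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    se_null: float
    z: float
    p: float  # one-sided, upper tail
    n_pos: int
    n_neg: int


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    threshold: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class BootstrapLoadings:
    loadings: np.ndarray  # mean over LOO folds, per feature
    sd_boot: np.ndarray
    z: np.ndarray
    n_boot: int
    seed: int
    feature_names: list[str] = field(default_factory=list)


@dataclass
class SweepResult:
    axis: np.ndarray  # seconds or channel counts, strictly increasing
    auc: np.ndarray
    loadings: np.ndarray  # len(axis) x features
    z: np.ndarray  # bootstrap z per axis value (len(axis) x features)
    seed: int | None = None
    axis_name: str = ""


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    X1 = np.column_stack([X, np.ones(len(X))])
    beta, _, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    if rank < X1.shape[1]:
        raise NumericalError("singular design in linear regressor fit")
    return beta  # last entry is the intercept


def loocv_scores(data: LabeledFeatures):
    """Leave-one-out out-of-fold scores of the linear regressor.

    Returns ``(scores, fold_loadings)`` where ``fold_loadings`` is
    n_subjects x n_features (per-fold coefficients, intercept dropped).
    """
    X, y = data.X, data.y
    n, p = X.shape
    if n < 3:
        raise ParameterError(f"leave-one-out needs n >= 3 subjects, got {n}")
    if p >= n - 1:
        raise ParameterError(f"{p} features with only {n} subjects; need features < n - 1")
    scores = np.empty(n)
    loadings = np.empty((n, p))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            beta = _ols_fit(X[mask], y[mask])
        except NumericalError as err:
            raise NumericalError(f"singular design in LOO fold {i}") from err
        scores[i] = X[i] @ beta[:-1] + beta[-1]
        loadings[i] = beta[:-1]
    return scores, loadings


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U (ties counted one half)."""
    pos = labels == 1
    n1, n2 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC for given group sizes."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return float(np.sqrt(var))


def roc_analysis(scores, labels) -> ROCResult:
    """ROC curve, AUC and its significance against the null AUC of 0.5.

    The z statistic is (AUC - 0.5) / SE0 with SE0 the Hanley-McNeil
    standard error evaluated at the null AUC (for A = 0.5 this reduces
    to sqrt(3 / (n_pos * n_neg))); p is the one-sided upper-tail normal
    probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise DataError("ROC analysis needs both classes")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    auc = _mann_whitney_auc(scores, labels)
    se0 = hanley_mcneil_se(0.5, n_pos, n_neg)
    z = (auc - 0.5) / se0
    p = float(_st.norm.sf(z))
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    spec = np.array([(scores[labels == 0] < t).mean() for t in thresholds])
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, se_null=se0, z=float(z), p=p, n_pos=n_pos, n_neg=n_neg,
    )


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (score >= t -> patient)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    candidates = np.unique(scores)
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        sens = (scores[labels == 1] >= t).mean()
        spec = (scores[labels == 0] < t).mean()
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def confusion_at_threshold(scores, labels, threshold: float | None = None) -> ConfusionMatrix:
    """Confusion matrix at a score threshold (default: Youden-optimal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise DataError("confusion matrix needs both classes")
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int((pred & (labels == 1)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        threshold=float(threshold),
    )


def bootstrap_loading_z(data: LabeledFeatures, n_boot: int = 10000, seed: int = 0) -> BootstrapLoadings:
    """Bootstrap z-scores of the regression loadings.

    The reported loading per feature is the mean over LOO folds; its
    variability is the SD of the full-model loading over ``n_boot``
    subject resamples (with replacement; single-class resamples are
    redrawn and logged).  z = loading / sd_boot.
    """
    X, y = data.X, data.y
    n, p = X.shape
    if n < 10:
        raise ParameterError(f"bootstrap needs n >= 10 subjects, got {n}")
    _, fold_loadings = loocv_scores(data)
    loadings = fold_loadings.mean(axis=0)
    rng = np.random.default_rng(seed)
    X1 = np.column_stack([X, np.ones(n)])
    idx = rng.integers(0, n, size=(n_boot, n))
    redrawn = 0
    while True:
        single = np.nonzero([len(np.unique(y[row])) < 2 for row in idx])[0]
        if len(single) == 0:
            break
        redrawn += len(single)
        idx[single] = rng.integers(0, n, size=(len(single), n))
    if redrawn:
        logger.info("redrew %d single-class bootstrap resamples", redrawn)
    Xb = X1[idx]  # n_boot x n x (p+1)
    yb = y[idx].astype(float)
    gram = Xb.transpose(0, 2, 1) @ Xb
    rhs = np.einsum("bnp,bn->bp", Xb, yb)
    try:
        betas = np.linalg.solve(gram, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        betas = np.stack([np.linalg.lstsq(Xb[i], yb[i], rcond=None)[0] for i in range(n_boot)])
    sd_boot = betas[:, :p].std(axis=0, ddof=1)
    if (sd_boot == 0).any():
        raise NumericalError("bootstrap loading SD is zero for some feature")
    return BootstrapLoadings(
        loadings=loadings, sd_boot=sd_boot, z=loadings / sd_boot,
        n_boot=n_boot, seed=seed, feature_names=list(data.feature_names),
    )


def sweep_recording_time(cohort, cfg, windows=None, n_boot=None):
    """Classification vs centered recording-time window; see :mod:`nvcpipe.pipeline`."""
    from .pipeline import sweep_recording_time as _impl

    return _impl(cohort, cfg, windows=windows, n_boot=n_boot)


def sweep_channel_count(cohort, cfg, counts=None, seed=None, n_boot=None):
    """Classification vs EEG channel count; see :mod:`nvcpipe.pipeline`."""
    from .pipeline import sweep_channel_count as _impl

    return _impl(cohort, cfg, counts=counts, seed=seed, n_boot=n_boot)


def auc_difference_independent(auc1: float, auc2: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """z-test for two AUCs treated as independent (Hanley-McNeil SEs).

    Provided for completeness only: when both classifiers score the same
    subjects the AUCs are correlated and this independence assumption is
    wrong, so this is not a substitute for a paired AUC comparison.
    Returns ``(z, two_sided_p)``.
    """
    se = np.hypot(hanley_mcneil_se(auc1, n_pos, n_neg), hanley_mcneil_se(auc2, n_pos, n_neg))
    z = (auc1 - auc2) / se
    return float(z), float(2 * _st.norm.sf(abs(z)))
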