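"""CSP spatial filtering, classification, and the validation protocols.

The common-spatial-patterns filters solve

    maximize tr(W' S1 W)  subject to  W'(S1 + S2) W = I

where S1, S2 are per-class trial covariances, each trial's E E' normalized
by its trace before averaging.  The program reduces to the generalized
eigenproblem S1 w = lambda (S1 + S2) w; components are ordered by descending
eigenvalue and the top and bottom halves retained (large lambda = variance
concentrated in class 1, small = class 2).  Features are log-variances of
the spatially filtered trials.

Validation follows two cross-classification directions — (a) train on
original, test on synthetic; (b) the reverse — plus a Monte-Carlo
cross-validated baseline on the original data alone (random 95/5 splits)
and a Wilcoxon signed-rank comparison of paired accuracies.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .augmentation import EpochSet

__all__ = [
    "CSPModel",
    "ValidationReport",
    "DegenerateTestError",
    "csp_fit",
    "csp_features",
    "fit_classifier",
    "validate_cross",
    "baseline_cv",
    "wilcoxon_signed_rank",
    "CLASSIFIER_KINDS",
]

log = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("LDA", "SVM_linear", "KNN5", "Gaussian")


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass
class CSPModel:
    """Fitted CSP filters (rows of W) and the class covariances."""

    W: np.ndarray  # (n_components, n_channels)
    sigma1: np.ndarray
    sigma2: np.ndarray
    n_components: int


@dataclass
class ValidationReport:
    """Accuracy of one validation run; accuracies are proportions in [0, 1]."""

    direction: str  # "a" (train original / test synthetic), "b", or "baseline"
    classifier: str
    accuracy: float
    n_train: int
    n_test: int
    fold_accuracies: np.ndarray | None = None
    per_cfg: dict | None = None

    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "classifier": self.classifier,
            "accuracy_pct": self.accuracy_pct(),
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        if self.fold_accuracies is not None:
            d["fold_accuracies_pct"] = (100.0 * self.fold_accuracies).tolist()
        if self.per_cfg is not None:
            d["per_cfg_accuracy_pct"] = {
                str(k): 100.0 * v for k, v in self.per_cfg.items()
            }
        return d

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _class_covariance(trials: np.ndarray) -> np.ndarray:
    """Mean of trace-normalized per-trial covariances E E'."""
    covs = np.einsum("tcs,tds->tcd", trials, trials)
    traces = np.trace(covs, axis1=1, axis2=2)
    if (traces <= 0).any():
        raise ValueError("a trial has zero power; covariance undefined")
    return (covs / traces[:, None, None]).mean(axis=0)


def csp_fit(epochs: EpochSet, n_components: int = 4) -> CSPModel:
    """Fit CSP filters by simultaneous diagonalization of (S1, S1 + S2)."""
    if len(epochs.class_names) != 2:
        raise ValueError("CSP requires exactly two classes")
    if epochs.n_channels < 2:
        raise ValueError("CSP requires at least two channels")
    if n_components < 2 or n_components % 2:
        raise ValueError("n_components must be an even count >= 2")
    if n_components > epochs.n_channels:
        log.info(
            "n_components=%d clipped to the %d available channels",
            n_components,
            epochs.n_channels,
        )
        n_components = epochs.n_channels - (epochs.n_channels % 2)
    s1 = _class_covariance(epochs.class_trials(0))
    s2 = _class_covariance(epochs.class_trials(1))
    total = s1 + s2
    # rank-deficient composite: shrink toward the identity and warn
    eigvals = np.linalg.eigvalsh(total)
    if eigvals[0] <= 1e-12 * eigvals[-1]:
        lam = 1e-8 * np.trace(total) / total.shape[0]
        log.warning("singular composite covariance; regularizing with %.3g * I", lam)
        total = total + lam * np.eye(total.shape[0])
    w, V = scipy.linalg.eigh(s1, total)  # ascending; V' total V = I
    order = np.argsort(w)[::-1]
    V = V[:, order]
    half = n_components // 2
    keep = np.r_[np.arange(half), np.arange(V.shape[1] - half, V.shape[1])]
    W = V[:, keep].T
    return CSPModel(W=W, sigma1=s1, sigma2=s2, n_components=n_components)


def csp_features(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Log-variance of each spatially filtered trial, (trials, components)."""
    if epochs.n_channels != model.W.shape[1]:
        raise ValueError("channel count does not match the fitted CSP model")
    proj = np.einsum("kc,tcs->tks", model.W, epochs.data)
    var = proj.var(axis=2)
    return np.log(np.maximum(var, np.finfo(float).tiny))


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "LDA",
    gaussian_variant: str = "qda",
):
    """Fit one of the four reference classifiers on feature vectors.

    LDA exposes class posteriors via ``predict_proba`` (used for best-trial
    template selection).  "Gaussian" is quadratic discriminant analysis by
    default (class-conditional Gaussians with per-class covariance); set
    ``gaussian_variant='naive_bayes'`` for the diagonal variant.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < 2 and kind != "KNN5":
        raise ValueError("each class needs at least two samples")
    if kind == "LDA":
        clf = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            try:
                return clf.fit(features, labels)
            except Exception:
                log.warning("LDA scatter singular; falling back to shrinkage LDA")
                return LinearDiscriminantAnalysis(
                    solver="lsqr", shrinkage="auto"
                ).fit(features, labels)
    if kind == "SVM_linear":
        return SVC(kernel="linear").fit(features, labels)
    if kind == "KNN5":
        k = min(5, len(labels))
        if k % 2 == 0:
            k -= 1  # keep k odd so binary votes cannot tie
        if k < 5:
            log.warning("k lowered from 5 to %d (only %d samples)", k, len(labels))
        return KNeighborsClassifier(n_neighbors=k).fit(features, labels)
    if kind == "Gaussian":
        if gaussian_variant == "naive_bayes":
            return GaussianNB().fit(features, labels)
        return QuadraticDiscriminantAnalysis(reg_param=1e-6).fit(features, labels)
    raise ValueError(f"unknown classifier kind {kind!r}; use one of {CLASSIFIER_KINDS}")


def spectral_logpower_features(
    epochs: EpochSet, fmin: float = 0.5, fmax: float = 20.0
) -> np.ndarray:
    """Per-trial log Welch band powers, (trials, channels * bins).

    The feature set used in place of CSP when only one channel is available
    (spatial filtering is undefined there); frequency bins span the analysis
    band at the resolution of a 2 s Welch segment.
    """
    from .fixtures import power_spectrum

    f, p = power_spectrum(epochs.data, epochs.fs)
    keep = (f >= fmin) & (f <= fmax)
    logp = np.log(np.maximum(p[..., keep], np.finfo(float).tiny))
    return logp.reshape(epochs.n_trials, -1)


class _FeaturePipeline:
    """CSP log-variance features when >=2 channels, spectral log-power else."""

    def __init__(self, train: EpochSet, n_components: int):
        self.use_csp = train.n_channels >= 2
        self.model = csp_fit(train, n_components) if self.use_csp else None

    def __call__(self, epochs: EpochSet) -> np.ndarray:
        if self.use_csp:
            return csp_features(self.model, epochs)
        return spectral_logpower_features(epochs)


def _check_compatible(a: EpochSet, b: EpochSet) -> None:
    if a.class_names != b.class_names:
        raise ValueError("class names differ between the two epoch sets")
    if a.channel_names != b.channel_names:
        raise ValueError("channel names differ between the two epoch sets")
    if a.fs != b.fs:
        raise ValueError("sampling rates differ between the two epoch sets")


def validate_cross(
    original: EpochSet,
    synthetic: EpochSet,
    direction: str,
    classifier_kind: str = "LDA",
    n_components: int = 4,
) -> ValidationReport:
    """Cross-classification between original and synthetic sets.

    Direction "a" trains (CSP filters included) on the original set and
    tests on the synthetic one; "b" is the reverse.  The CSP filters are
    learned strictly on the training side.
    """
    if direction not in ("a", "b"):
        raise ValueError("direction must be 'a' or 'b'")
    _check_compatible(original, synthetic)
    train, test = (original, synthetic) if direction == "a" else (synthetic, original)
    features = _FeaturePipeline(train, n_components)
    clf = fit_classifier(features(train), train.labels, classifier_kind)
    pred = clf.predict(features(test))
    acc = float(np.mean(pred == test.labels))
    return ValidationReport(
        direction=direction,
        classifier=classifier_kind,
        accuracy=acc,
        n_train=train.n_trials,
        n_test=test.n_trials,
    )


def baseline_cv(
    epochs: EpochSet,
    n_folds: int = 100,
    test_fraction: float = 0.05,
    classifier_kind: str = "LDA",
    seed: int = 0,
    n_components: int = 4,
) -> ValidationReport:
    """Monte-Carlo cross-validated baseline on the original data.

    Each fold draws a fresh random test split of the given fraction (at
    least one trial, resampled until both classes appear on both sides) and
    reports the mean fold accuracy.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = epochs.n_trials
    n_test = max(1, round(test_fraction * n))
    if n_test < len(epochs.class_names) or n - n_test < 2 * len(epochs.class_names):
        raise ValueError("too few trials for the requested split")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_folds)
    for f in range(n_folds):
        for attempt in range(1000):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if (
                len(np.unique(epochs.labels[train_idx])) == len(epochs.class_names)
                and len(np.unique(epochs.labels[test_idx])) == len(epochs.class_names)
            ):
                break
        else:  # pragma: no cover - pathological label imbalance
            raise ValueError("could not draw a split covering every class")
        if attempt:
            log.info("fold %d: resampled split %d times", f, attempt)
        train, test = epochs.subset(train_idx), epochs.subset(test_idx)
        features = _FeaturePipeline(train, n_components)
        clf = fit_classifier(features(train), train.labels, classifier_kind)
        pred = clf.predict(features(test))
        accs[f] = np.mean(pred == test.labels)
    return ValidationReport(
        direction="baseline",
        classifier=classifier_kind,
        accuracy=float(accs.mean()),
        n_train=n - n_test,
        n_test=n_test,
        fold_accuracies=accs,
    )


def wilcoxon_signed_rank(
    paired_a: np.ndarray, paired_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired accuracy vectors.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 pairs and the normal approximation above.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired accuracy vectors must be 1-D and equal length")
    d = a - b
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n_nonzero < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)
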