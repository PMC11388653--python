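"""The seven-classifier bank behind a single train/predict/score contract.

BLDC (Bayesian linear discriminant) and NBC (Gaussian naive Bayes) are
implemented directly from their discriminant equations; decision trees,
random forests and the three SVM kernels delegate their solvers to
scikit-learn while the split-impurity, vote-aggregation and kernel
primitives are implemented and tested here as contracts.

Every model exposes a continuous score in ``[t_meso, t_adeno]`` — the
posterior (BLDC/NBC), sigmoid-squashed margin (SVM) or positive-class vote
fraction (trees/forest) mapped onto the regression targets — used for MSE
monitoring and optimizer fitness.  Prediction ties break toward Adeno, the
majority class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, FitError, InputError, PredictError
from .io_formats import ADENO, MESO, RunConfig

CLASSIFIER_KINDS = ("BLDC", "NBC", "RFC", "DTC", "SVM_linear", "SVM_poly", "SVM_rbf")


# ---------------------------------------------------------------------------
# Bayesian linear discriminant


@dataclass
class BldcModel:
    """Per-class Gaussian: mean, ridge-regularized covariance, log-prior."""

    classes: list[str]
    means: dict
    inv_covs: dict
    logdets: dict
    log_priors: dict
    ridge: float


def bldc_fit(X, y, priors: dict | None = None, ridge: float = 1e-3) -> BldcModel:
    """Class means and covariances with ridge regularization on the diagonal.

    The ridge is ``ridge`` times the mean diagonal of each class covariance
    — with more features than samples the raw covariance is singular and
    the discriminant requires invertibility.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = [ADENO, MESO]
    if priors is None:
        priors = {ADENO: 0.5, MESO: 0.5}
    total = sum(priors.values())
    means, inv_covs, logdets, log_priors = {}, {}, {}, {}
    for c in classes:
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise FitError(f"class {c!r} needs >= 2 training samples (got {rows.shape[0]})")
        mu = rows.mean(axis=0)
        centred = rows - mu
        cov = centred.T @ centred / rows.shape[0]
        eps = ridge * float(np.mean(np.diag(cov)))
        if eps <= 0:
            eps = ridge
        cov = cov + eps * np.eye(cov.shape[0])
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise FitError(f"covariance of class {c!r} is not positive definite")
        means[c] = mu
        inv_covs[c] = np.linalg.inv(cov)
        logdets[c] = float(logdet)
        log_priors[c] = math.log(priors[c] / total)
    return BldcModel(classes=classes, means=means, inv_covs=inv_covs,
                     logdets=logdets, log_priors=log_priors, ridge=ridge)


def bldc_discriminants(model: BldcModel, X) -> np.ndarray:
    """g_y(x) = -0.5 log|S_y| - 0.5 (x-mu_y)' S_y^-1 (x-mu_y) + log P(y), per class column."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dim = next(iter(model.means.values())).size
    if X.shape[1] != dim:
        raise PredictError(f"expected {dim} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise PredictError("non-finite feature values")
    out = np.empty((X.shape[0], len(model.classes)))
    for j, c in enumerate(model.classes):
        d = X - model.means[c]
        maha = np.einsum("ij,jk,ik->i", d, model.inv_covs[c], d)
        out[:, j] = -0.5 * model.logdets[c] - 0.5 * maha + model.log_priors[c]
    return out


def bldc_predict(model: BldcModel, x):
    """Argmax class for one feature vector, plus both discriminant values.

    Equal discriminants break toward Adeno (the majority class).
    """
    g = bldc_discriminants(model, np.atleast_2d(x))[0]
    values = dict(zip(model.classes, g))
    label = ADENO if values[ADENO] >= values[MESO] else MESO
    return label, values


# ---------------------------------------------------------------------------
# naive Bayes


@dataclass
class NbcModel:
    classes: list[str]
    means: dict
    variances: dict
    log_priors: dict
    smoothing: float


def nbc_fit(X, y, smoothing: float = 0.01, priors: dict | None = None) -> NbcModel:
    """Gaussian per-feature likelihoods with a variance floor.

    Each class/feature variance gets ``smoothing`` times the largest pooled
    feature variance added, so zero-variance features stay finite in the
    log-likelihood.
    """
    if smoothing <= 0:
        raise ConfigError("smoothing must be > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = [ADENO, MESO]
    if priors is None:
        n = y.size
        priors = {c: np.sum(y == c) / n for c in classes}
    total = sum(priors.values())
    floor = smoothing * float(np.max(X.var(axis=0)))
    if floor <= 0:
        floor = smoothing
    means, variances, log_priors = {}, {}, {}
    for c in classes:
        rows = X[y == c]
        if rows.shape[0] < 1:
            raise FitError(f"class {c!r} absent from training labels")
        means[c] = rows.mean(axis=0)
        variances[c] = rows.var(axis=0) + floor
        log_priors[c] = math.log(priors[c] / total)
    return NbcModel(classes=classes, means=means, variances=variances,
                    log_priors=log_priors, smoothing=smoothing)


def nbc_log_posterior(model: NbcModel, X) -> np.ndarray:
    """Unnormalized log posterior per class: sum of per-feature log-likelihoods + log prior."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], len(model.classes)))
    for j, c in enumerate(model.classes):
        var = model.variances[c]
        ll = -0.5 * (np.log(2 * np.pi * var) + (X - model.means[c]) ** 2 / var)
        out[:, j] = ll.sum(axis=1) + model.log_priors[c]
    if not np.all(np.isfinite(out)):
        raise PredictError("non-finite log posterior; check input scaling")
    return out


def nbc_predict(model: NbcModel, x):
    """Argmax class for one vector; equal posteriors break toward Adeno."""
    lp = nbc_log_posterior(model, np.atleast_2d(x))[0]
    values = dict(zip(model.classes, lp))
    label = ADENO if values[ADENO] >= values[MESO] else MESO
    return label, values


# ---------------------------------------------------------------------------
# tree / forest / kernel primitives (contracts for the delegated solvers)


def gini(counts) -> float:
    """Gini impurity 1 - sum p_i^2 of a node's class counts."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise InputError("gini needs non-negative counts, not all zero")
    p = counts / counts.sum()
    return float(1.0 - np.sum(p * p))


def entropy(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise InputError("entropy needs non-negative counts, not all zero")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def info_gain(parent_counts, partition_counts) -> float:
    """Entropy(S) minus the size-weighted entropy of the partition subsets."""
    parent_counts = np.asarray(parent_counts, dtype=float)
    n = parent_counts.sum()
    gain = entropy(parent_counts)
    for counts in partition_counts:
        counts = np.asarray(counts, dtype=float)
        gain -= counts.sum() / n * entropy(counts)
    return float(gain)


def majority_vote(predictions) -> str:
    """Forest aggregation: the most frequent predicted label; ties to Adeno."""
    preds = list(predictions)
    if not preds:
        raise InputError("no predictions to aggregate")
    n_adeno = sum(p == ADENO for p in preds)
    return ADENO if n_adeno >= len(preds) - n_adeno else MESO


def rbf_kernel(xi, xj, gamma: float) -> float:
    """K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2); equals 1 at zero distance."""
    d = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    return float(np.exp(-gamma * float(d @ d)))


# ---------------------------------------------------------------------------
# unified contract


class TrainedClassifier:
    """One fitted model with a label predictor and a continuous score.

    ``score_continuous`` maps the model's positive-class membership
    probability (or squashed margin) onto ``[t_meso, t_adeno]`` so Eq-style
    MSE monitoring sees outputs on the target scale.
    """

    def __init__(self, kind, impl, positive, t_meso, t_adeno):
        self.kind = kind
        self._impl = impl
        self.positive = positive
        self.negative = MESO if positive == ADENO else ADENO
        self.t_meso = t_meso
        self.t_adeno = t_adeno

    def _proba_positive(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "BLDC":
            g = bldc_discriminants(self._impl, X)
            lp = g - logsumexp(g, axis=1, keepdims=True)
            j = self._impl.classes.index(self.positive)
            return np.exp(lp[:, j])
        if self.kind == "NBC":
            lp = nbc_log_posterior(self._impl, X)
            lp = lp - logsumexp(lp, axis=1, keepdims=True)
            j = self._impl.classes.index(self.positive)
            return np.exp(lp[:, j])
        if self.kind in ("DTC", "RFC"):
            proba = self._impl.predict_proba(X)
            j = list(self._impl.classes_).index(self.positive)
            return proba[:, j]
        # SVMs: sigmoid-squashed signed margin
        df = self._impl.decision_function(X)
        if self._impl.classes_[1] != self.positive:
            df = -df
        return expit(df)

    def predict(self, X) -> np.ndarray:
        """Class labels; probability ties break toward Adeno."""
        p = self._proba_positive(X)
        pos = np.where(self.positive == ADENO, p >= 0.5, p > 0.5)
        return np.where(pos, self.positive, self.negative)

    def score_continuous(self, X) -> np.ndarray:
        """Positive-class membership mapped onto [t_meso, t_adeno]."""
        return self.t_meso + (self.t_adeno - self.t_meso) * self._proba_positive(X)


def _class_weight(positive: str, w: float) -> dict:
    # a single printed weight is read as the positive class's share
    other = MESO if positive == ADENO else ADENO
    return {positive: w, other: 1.0 - w}


def fit_classifier(
    kind: str,
    X,
    y,
    config: RunConfig | None = None,
    positive: str = ADENO,
    seed: int | None = None,
) -> TrainedClassifier:
    """Fit one member of the bank with its configured hyperparameters.

    ``positive`` selects the class whose membership the continuous score
    expresses (model I scores Adeno, model II scores Meso in the
    imbalance-handling CV scheme).
    """
    if kind not in CLASSIFIER_KINDS:
        raise ConfigError(f"unknown classifier {kind!r}")
    cfg = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise FitError("training set contains a single class")
    rs = seed if seed is not None else cfg.seed

    if kind == "BLDC":
        pri = {positive: cfg.bldc_prior, (MESO if positive == ADENO else ADENO): 1 - cfg.bldc_prior}
        impl = bldc_fit(X, y, priors=pri, ridge=cfg.bldc_ridge)
    elif kind == "NBC":
        pri = {MESO: cfg.nbc_prior_meso, ADENO: 1 - cfg.nbc_prior_meso}
        impl = nbc_fit(X, y, smoothing=cfg.nbc_smoothing, priors=pri)
    elif kind == "DTC":
        impl = DecisionTreeClassifier(
            max_depth=cfg.dt_max_depth, criterion="gini",
            class_weight=_class_weight(positive, cfg.dt_class_weight),
            random_state=rs,
        ).fit(X, y)
    elif kind == "RFC":
        # fraction -> absolute draw count to keep the bootstrap well-defined on
        # weighted samples (an absolute count can also be configured directly)
        n_boot = cfg.rf_bootstrap_absolute or max(2, round(cfg.rf_bootstrap_fraction * X.shape[0]))
        impl = RandomForestClassifier(
            n_estimators=cfg.rf_n_trees, max_depth=cfg.rf_max_depth,
            max_samples=n_boot, bootstrap=True,
            class_weight=_class_weight(positive, cfg.rf_class_weight),
            random_state=rs, n_jobs=1,
        ).fit(X, y)
    elif kind == "SVM_linear":
        impl = SVC(kernel="linear", C=cfg.svm_linear_c,
                   class_weight=_class_weight(positive, cfg.svm_linear_class_weight)).fit(X, y)
    elif kind == "SVM_poly":
        impl = SVC(kernel="poly", C=cfg.svm_poly_c, gamma=cfg.svm_poly_gamma,
                   degree=cfg.svm_poly_degree,
                   class_weight=_class_weight(positive, cfg.svm_poly_class_weight)).fit(X, y)
    else:  # SVM_rbf
        impl = SVC(kernel="rbf", C=cfg.svm_rbf_c, gamma=cfg.svm_rbf_gamma,
                   class_weight=_class_weight(positive, cfg.svm_rbf_class_weight)).fit(X, y)

    return TrainedClassifier(kind, impl, positive, cfg.t_meso, cfg.t_adeno)
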